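"""End-to-end orchestration with resumable, hash-cached stages.

Stages run in order: simulate -> preprocess -> train -> latent -> gblup ->
pc_predict -> report.  Each stage writes its outputs plus a ``manifest.json``
recording the config hash and seed it ran under; a stage is skipped when its
manifest matches the current config hash and its outputs still exist.
Intermediates are plain files (PNG/TIFF/CSV/JSON) for inspectability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .cnn import (
    CVScheme,
    ModelSpec,
    TrainConfig,
    build_model,
    extract_features,
    stack_inputs,
    train_model,
)
from .cnn.cv import evaluate_metrics
from .gblup import compute_grm, cv_gblup, filter_snps, impute_missing, summarize_cv
from .latent import AnnotatedWeights, annotation_graph, average_weights, fit_pca
from .pc_predict import sweep_components
from .preprocess import (
    TRAITS,
    augment_arrays,
    normalize_traits,
    standardize_geometry,
    vegetation_mask,
)
from .synthetic_data import SyntheticFieldConfig, simulate_field

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "latent", "gblup", "pc_predict", "report")


@dataclass
class RunConfig:
    """Whole-pipeline configuration; serialises losslessly to/from YAML."""

    seed: int = 0
    outdir: str = "lsp_run"
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    latent: dict = field(default_factory=dict)
    gblup: dict = field(default_factory=dict)
    pc_predict: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def stage_hash(self, stage: str) -> str:
        """Hash of the global seed plus every stage config up to ``stage``
        (so changing an upstream stage invalidates downstream caches)."""
        upto = STAGES[: STAGES.index(stage) + 1]
        payload = {"seed": self.seed}
        for s in upto:
            payload[s] = getattr(self, s, {})
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


#: upstream stages whose outputs each stage consumes
DEPS = {
    "simulate": (),
    "preprocess": ("simulate",),
    "train": ("preprocess",),
    "latent": ("train",),
    "gblup": ("simulate", "preprocess"),
    "pc_predict": ("simulate", "preprocess", "train"),
    "report": ("gblup", "pc_predict"),
}


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    return Path(cfg.outdir) / stage


def _outputs_digest(stage_dir: Path, outputs: list[str]) -> str:
    h = hashlib.sha256()
    for name in sorted(outputs):
        path = stage_dir / name
        h.update(name.encode())
        if path.exists():
            h.update(path.read_bytes())
        else:
            h.update(b"<missing>")
    return h.hexdigest()[:16]


def _current_digest(cfg: RunConfig, stage: str) -> str | None:
    """Digest of a stage's outputs as they exist on disk right now."""
    manifest = _stage_dir(cfg, stage) / "manifest.json"
    if not manifest.exists():
        return None
    meta = io.read_json(manifest)
    return _outputs_digest(_stage_dir(cfg, stage), meta.get("outputs", []))


def _fresh(cfg: RunConfig, stage: str) -> bool:
    """True when the stage's cached outputs are valid for the current config
    and the current (on-disk) outputs of its upstream stages."""
    manifest = _stage_dir(cfg, stage) / "manifest.json"
    if not manifest.exists():
        return False
    meta = io.read_json(manifest)
    if meta.get("config_hash") != cfg.stage_hash(stage):
        return False
    outputs = meta.get("outputs", [])
    if not all((_stage_dir(cfg, stage) / f).exists() for f in outputs):
        return False
    for dep in DEPS[stage]:
        if _current_digest(cfg, dep) != meta.get("upstream", {}).get(dep):
            return False
    return True


def _finish(cfg: RunConfig, stage: str, outputs: list[str], t0: float) -> None:
    stage_dir = _stage_dir(cfg, stage)
    io.write_json(
        {
            "stage": stage,
            "config_hash": cfg.stage_hash(stage),
            "seed": cfg.seed,
            "outputs": outputs,
            "outputs_digest": _outputs_digest(stage_dir, outputs),
            "upstream": {dep: _current_digest(cfg, dep) for dep in DEPS[stage]},
            "wall_time_s": round(time.time() - t0, 3),
        },
        stage_dir / "manifest.json",
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> None:
    t0 = time.time()
    out = _stage_dir(cfg, "simulate")
    out.mkdir(parents=True, exist_ok=True)
    field_cfg = SyntheticFieldConfig(rng_seed=cfg.seed, **cfg.simulate)
    ds = simulate_field(field_cfg)
    io.write_genotypes_vcf(ds.genotypes, out / "genotypes.vcf")
    io.write_traits_csv(ds.truth.plots, ds.truth.plot_traits, out / "traits.csv")
    ds.truth.breeding_values.to_csv(out / "breeding_values.csv", index_label="accession")
    img_dir = out / "images"
    files = ["genotypes.vcf", "traits.csv", "breeding_values.csv"]
    for scene in ds.render_all():
        names = io.write_pair(scene.pair, img_dir)
        files.extend(f"images/{n}" for n in names.values())
    _finish(cfg, "simulate", files, t0)


def stage_preprocess(cfg: RunConfig) -> None:
    t0 = time.time()
    sim = _stage_dir(cfg, "simulate")
    out = _stage_dir(cfg, "preprocess")
    (out / "images").mkdir(parents=True, exist_ok=True)
    p = cfg.preprocess
    threshold = p.get("threshold", 0.057)
    min_green = p.get("min_green", 10)

    plots, traits = io.read_traits_csv(sim / "traits.csv")
    kept, excluded = [], []
    files = []
    target_hw = p.get("target_hw")
    for plot_id in plots["plot_id"]:
        pair = io.read_pair(sim / "images", plot_id)
        res = vegetation_mask(pair.rgb, threshold=threshold, min_green=min_green)
        if res.excluded:
            excluded.append(plot_id)
            continue
        pair.mask = res.mask
        th, tw = target_hw or pair.shape
        std = standardize_geometry(pair, th, tw)
        names = io.write_pair(std, out / "images")
        files.extend(f"images/{n}" for n in names.values())
        kept.append(plot_id)

    plots_kept = plots[plots["plot_id"].isin(kept)].reset_index(drop=True)
    table = normalize_traits(traits.loc[kept])
    table.normalized.to_csv(out / "traits_normalized.csv", index_label="plot_id")
    plots_kept.to_csv(out / "plots.csv", index=False)
    io.write_json(
        {
            "norm_mean": dict(table.norm_mean),
            "norm_sd": dict(table.norm_sd),
            "excluded_plots": excluded,
            "threshold": threshold,
            "min_green": min_green,
        },
        out / "normalization.json",
    )
    files += ["traits_normalized.csv", "plots.csv", "normalization.json"]
    _finish(cfg, "preprocess", files, t0)


def _load_preprocessed(cfg: RunConfig):
    pre = _stage_dir(cfg, "preprocess")
    plots = pd.read_csv(pre / "plots.csv")
    traits = pd.read_csv(pre / "traits_normalized.csv", index_col="plot_id")
    pairs = [io.read_pair(pre / "images", pid) for pid in plots["plot_id"]]
    rgb = np.stack([p.rgb for p in pairs])
    dsm = np.stack([p.dsm for p in pairs])
    return plots, traits, rgb, dsm


def stage_train(cfg: RunConfig) -> None:
    t0 = time.time()
    out = _stage_dir(cfg, "train")
    out.mkdir(parents=True, exist_ok=True)
    tcfg = cfg.train
    variant = tcfg.get("variant", "rgb_dsm")

    plots, traits, rgb, dsm = _load_preprocessed(cfg)
    x = stack_inputs(rgb, dsm, variant, dsm_scale=tcfg.get("dsm_scale"))
    y = traits[list(TRAITS)].to_numpy(dtype=np.float32)

    rng = np.random.default_rng(cfg.seed)
    n = len(x)
    val_frac = tcfg.get("val_fraction", 0.1)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]

    x_tr, y_tr = augment_arrays(x[train_idx], y[train_idx])
    spec = ModelSpec(variant=variant)
    model = build_model(spec, input_hw=x.shape[2:], seed=cfg.seed)
    train_cfg = TrainConfig(
        epochs=tcfg.get("epochs", 10),
        lr=tcfg.get("lr", 1e-3),
        batch_size=tcfg.get("batch_size", 64),
        seed=cfg.seed,
    )
    result = train_model(model, (x_tr, y_tr), (x[val_idx], y[val_idx]), train_cfg)
    result.log.to_csv(out / "training_log.csv", index=False)

    feats = extract_features(result.model, x, reference=x[train_idx])
    pd.DataFrame(
        feats.X, index=plots["plot_id"], columns=[f"F{i + 1}" for i in range(feats.X.shape[1])]
    ).to_csv(out / "features.csv", index_label="plot_id")
    io.write_json(
        {
            "W": result.model.W,
            "b": result.model.b,
            "scaling_mean": feats.scaling_mean,
            "scaling_sd": feats.scaling_sd,
            "variant": variant,
            "best_epoch": result.best_epoch,
            "best_val_mse": result.best_val_mse,
            "n_parameters": result.model.n_parameters,
            "n_weighted_layers": result.model.n_weighted_layers,
        },
        out / "head.json",
    )
    _, est = result.model.forward(x, training=False)
    evaluate_metrics(y, est, plots["treatment"].to_numpy()).to_csv(
        out / "estimation_metrics.csv", index=False
    )
    _finish(
        cfg, "train", ["training_log.csv", "features.csv", "head.json", "estimation_metrics.csv"], t0
    )


def _load_features_head(cfg: RunConfig):
    tr = _stage_dir(cfg, "train")
    feats = pd.read_csv(tr / "features.csv", index_col="plot_id")
    head = io.read_json(tr / "head.json")
    return feats, np.array(head["W"]), np.array(head["b"]), head


def stage_latent(cfg: RunConfig) -> None:
    t0 = time.time()
    out = _stage_dir(cfg, "latent")
    out.mkdir(parents=True, exist_ok=True)
    n_pcs = cfg.latent.get("n_pcs", 3)

    feats, W, b, head = _load_features_head(cfg)
    X = feats.to_numpy(dtype=float)
    mean = np.array(head["scaling_mean"])
    sd = np.array(head["scaling_sd"])
    pca, scores = fit_pca((X - mean) / sd)
    W_prime = pca.E.T @ (sd[:, None] * W)

    pd.DataFrame(W_prime, columns=list(TRAITS)).to_csv(out / "w_prime.csv", index_label="pc")
    pd.DataFrame(
        {
            "explained_variance": pca.explained_variance,
            "proportion_of_variance": pca.proportion_of_variance,
        }
    ).to_csv(out / "variance.csv", index_label="pc")
    pd.DataFrame(scores, index=feats.index, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]).to_csv(
        out / "pc_scores.csv", index_label="plot_id"
    )
    io.write_json({"edges": annotation_graph(W_prime, n_pcs)}, out / "annotation_graph.json")
    _finish(cfg, "latent", ["w_prime.csv", "variance.csv", "pc_scores.csv", "annotation_graph.json"], t0)


def _load_grm(cfg: RunConfig):
    sim = _stage_dir(cfg, "simulate")
    geno = io.read_genotypes_vcf(sim / "genotypes.vcf")
    g = cfg.gblup
    filtered, _ = filter_snps(
        geno, maf_min=g.get("maf_min", 0.025), missing_max=g.get("missing_max", 0.05)
    )
    return compute_grm(impute_missing(filtered), center=g.get("grm_center", True))


def stage_gblup(cfg: RunConfig) -> None:
    t0 = time.time()
    out = _stage_dir(cfg, "gblup")
    out.mkdir(parents=True, exist_ok=True)
    g = cfg.gblup
    scheme = CVScheme(
        k=g.get("cv_k", 5), repetitions=g.get("cv_reps", 2), unit="accession", seed=cfg.seed
    )

    grm = _load_grm(cfg)
    pre = _stage_dir(cfg, "preprocess")
    plots = pd.read_csv(pre / "plots.csv")
    traits = pd.read_csv(pre / "traits_normalized.csv", index_col="plot_id").loc[
        plots["plot_id"]
    ]
    frames = []
    for trait in TRAITS:
        frames.append(
            cv_gblup(
                traits[trait].to_numpy(),
                plots["accession"].to_numpy(),
                grm,
                scheme,
                treatments=plots["treatment"].to_numpy(),
                target=trait,
            )
        )
    metrics = pd.concat(frames, ignore_index=True)
    metrics.to_csv(out / "gblup_metrics.csv", index=False)
    summarize_cv(metrics).to_csv(out / "gblup_summary.csv", index=False)
    _finish(cfg, "gblup", ["gblup_metrics.csv", "gblup_summary.csv"], t0)


def stage_pc_predict(cfg: RunConfig) -> None:
    t0 = time.time()
    out = _stage_dir(cfg, "pc_predict")
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.pc_predict
    scheme = CVScheme(
        k=cfg.gblup.get("cv_k", 5),
        repetitions=p.get("cv_reps", 1),
        unit="accession",
        seed=cfg.seed,
    )
    grm = _load_grm(cfg)
    pre = _stage_dir(cfg, "preprocess")
    plots = pd.read_csv(pre / "plots.csv")
    traits = pd.read_csv(pre / "traits_normalized.csv", index_col="plot_id").loc[
        plots["plot_id"]
    ]
    feats, W, b, _ = _load_features_head(cfg)
    sweep = sweep_components(
        feats.to_numpy(dtype=float),
        traits[list(TRAITS)].to_numpy(dtype=float),
        W,
        b,
        grm,
        plots["accession"].to_numpy(),
        scheme,
        treatments=plots["treatment"].to_numpy(),
        l_max=p.get("l_max", 10),
    )
    sweep.metrics.to_csv(out / "pc_metrics.csv", index=False)
    sweep.summary.to_csv(out / "pc_summary.csv", index=False)
    _finish(cfg, "pc_predict", ["pc_metrics.csv", "pc_summary.csv"], t0)


def stage_report(cfg: RunConfig) -> None:
    t0 = time.time()
    out = _stage_dir(cfg, "report")
    out.mkdir(parents=True, exist_ok=True)
    report = {"seed": cfg.seed, "stages": {}}
    for stage in STAGES[:-1]:
        manifest = _stage_dir(cfg, stage) / "manifest.json"
        if manifest.exists():
            report["stages"][stage] = io.read_json(manifest)
    gsum = _stage_dir(cfg, "gblup") / "gblup_summary.csv"
    if gsum.exists():
        report["gblup_summary"] = pd.read_csv(gsum).to_dict(orient="records")
    psum = _stage_dir(cfg, "pc_predict") / "pc_summary.csv"
    if psum.exists():
        report["pc_summary"] = pd.read_csv(psum).to_dict(orient="records")
    io.write_json(report, out / "report.json")
    _finish(cfg, "report", ["report.json"], t0)


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "latent": stage_latent,
    "gblup": stage_gblup,
    "pc_predict": stage_pc_predict,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, dry_run: bool = False) -> list[str]:
    """Execute all stages in order, skipping cached ones.

    Returns the list of stages that ran (or would run, when ``dry_run``).
    A stage failure propagates with the failing stage named; partial outputs
    are retained.
    """
    ran = []
    for stage in STAGES:
        if _fresh(cfg, stage):
            logger.info("stage %s: cached, skipping", stage)
            continue
        ran.append(stage)
        if dry_run:
            continue
        logger.info("stage %s: running", stage)
        t0 = time.time()
        try:
            _STAGE_FN[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return ran
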