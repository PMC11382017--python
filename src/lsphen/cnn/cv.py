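"""Cross-validated evaluation of the trait CNNs.

k-fold CV with repetitions; per fold the model is trained on the (optionally
flip-augmented) training plots and evaluated on held-out plots via Pearson
correlation per trait, overall and within each treatment subgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import UndefinedCorrelationError
from ..preprocess import TRAITS, augment_arrays
from .model import ModelSpec, TraitCNN, build_model, extract_features
from .train import TrainConfig, TrainResult, train_model

logger = logging.getLogger(__name__)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation.

    Raises :class:`UndefinedCorrelationError` for fewer than 3 points or zero
    variance in either vector, so undefined values cannot be confused with
    numeric results.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 points, got {a.size}")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


@dataclass
class CVScheme:
    """k-fold x repetitions fold assignment over plots or accessions."""

    k: int = 10
    repetitions: int = 20
    unit: str = "plot"  # or "accession"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unit not in ("plot", "accession"):
            raise ValueError(f"unit must be 'plot' or 'accession', got {self.unit!r}")
        if self.k < 2 or self.repetitions < 1:
            raise ValueError("need k >= 2 and repetitions >= 1")

    def assignments(self, units: list) -> list[dict]:
        """One {unit -> fold} map per repetition, folds sized within one unit."""
        rng = np.random.default_rng(self.seed)
        out = []
        n = len(units)
        base = np.arange(n) % self.k
        for _ in range(self.repetitions):
            folds = rng.permutation(base)
            out.append({u: int(f) for u, f in zip(units, folds)})
        return out


def stack_inputs(
    rgb: np.ndarray | None,
    dsm: np.ndarray | None,
    variant: str,
    dsm_scale: float | None = None,
) -> np.ndarray:
    """Assemble the (N, C, H, W) tensor for a model variant.

    RGB channels are scaled to [0, 1]; DSM heights are divided by
    ``dsm_scale`` (default: max height over the batch) so inputs are O(1).
    """
    parts = []
    if variant in ("rgb", "rgb_dsm"):
        if rgb is None:
            raise ValueError(f"variant {variant} needs rgb input")
        parts.append(np.asarray(rgb, dtype=np.float32).transpose(0, 3, 1, 2) / 255.0)
    if variant in ("dsm", "rgb_dsm"):
        if dsm is None:
            raise ValueError(f"variant {variant} needs dsm input")
        d = np.asarray(dsm, dtype=np.float32)
        if dsm_scale is None:
            dsm_scale = float(d.max()) or 1.0
        parts.append((d / dsm_scale)[:, None, :, :])
    return np.concatenate(parts, axis=1)


@dataclass
class CVResult:
    """Per-fold metrics plus (optionally) the trained fold models."""

    metrics: pd.DataFrame
    summary: pd.DataFrame
    models: list = field(default_factory=list)
    predictions: pd.DataFrame | None = None
    n_undefined: int = 0


def _subgroup_rows(
    y_obs: np.ndarray,
    y_est: np.ndarray,
    treatments: np.ndarray | None,
    rep: int,
    fold: int,
    trait_names,
) -> tuple[list[dict], int]:
    rows, undefined = [], 0
    groups = {"all": np.ones(len(y_obs), dtype=bool)}
    if treatments is not None:
        for tr in np.unique(treatments):
            groups[str(tr)] = treatments == tr
    for name, sel in groups.items():
        for t, trait in enumerate(trait_names):
            try:
                r = pearson(y_obs[sel, t], y_est[sel, t])
            except UndefinedCorrelationError:
                undefined += 1
                logger.info(
                    "undefined r: rep=%d fold=%d subgroup=%s trait=%s (n=%d)",
                    rep, fold, name, trait, int(sel.sum()),
                )
                continue
            rows.append(
                {
                    "repetition": rep,
                    "fold": fold,
                    "subgroup": name,
                    "trait": trait,
                    "r": r,
                    "n": int(sel.sum()),
                }
            )
    return rows, undefined


def crossvalidate(
    images: np.ndarray,
    targets: np.ndarray,
    spec: ModelSpec,
    train_cfg: TrainConfig,
    scheme: CVScheme,
    treatments: np.ndarray | None = None,
    accessions: np.ndarray | None = None,
    augment_train: bool = True,
    augment_before_split: bool = False,
    keep_models: bool = False,
    trait_names=TRAITS,
) -> CVResult:
    """Repeated k-fold CV of a CNN variant.

    ``images`` is the stacked (N, C, H, W) tensor, ``targets`` the normalised
    (N, 5) traits.  By default training folds are flip-augmented after the
    split (held-out plots never have flipped twins in training); set
    ``augment_before_split`` to replicate whole-dataset augmentation.
    Folds partition plots, or accessions when ``scheme.unit == 'accession'``
    (requires ``accessions``).
    """
    images = np.asarray(images, dtype=np.float32)
    targets = np.asarray(targets, dtype=np.float32)
    n = len(images)

    if scheme.unit == "accession":
        if accessions is None:
            raise ValueError("accession-wise CV needs the accession of each plot")
        units = sorted(set(accessions))
    else:
        units = list(range(n))

    if augment_before_split:
        images, targets = augment_arrays(images, targets)
        rep_idx = np.tile(np.arange(n), 4)
        if treatments is not None:
            treatments = np.tile(treatments, 4)
        if accessions is not None:
            accessions = np.tile(accessions, 4)
    else:
        rep_idx = np.arange(len(images))

    all_rows: list[dict] = []
    models = []
    n_undefined = 0
    for rep, fold_of in enumerate(scheme.assignments(units)):
        if scheme.unit == "accession":
            plot_fold = np.array([fold_of[a] for a in accessions])
        else:
            plot_fold = np.array([fold_of[i] for i in rep_idx])
        for fold in range(scheme.k):
            test = plot_fold == fold
            train = ~test
            x_tr, y_tr = images[train], targets[train]
            if augment_train and not augment_before_split:
                x_tr, y_tr = augment_arrays(x_tr, y_tr)
            model = build_model(
                spec, input_hw=images.shape[2:], seed=train_cfg.seed + 1000 * rep + fold
            )
            result = train_model(model, (x_tr, y_tr), (images[test], targets[test]), train_cfg)
            _, est = _forward_batched(result.model, images[test], train_cfg.batch_size)
            rows, und = _subgroup_rows(
                targets[test], est,
                None if treatments is None else np.asarray(treatments)[test],
                rep, fold, trait_names,
            )
            all_rows.extend(rows)
            n_undefined += und
            if keep_models:
                models.append(
                    {"repetition": rep, "fold": fold, "result": result, "test_mask": test}
                )

    metrics = pd.DataFrame(all_rows)
    summary = (
        metrics.groupby(["subgroup", "trait"])["r"]
        .agg(mean_r="mean", sd_r="std", n_folds="count")
        .reset_index()
        if len(metrics)
        else pd.DataFrame(columns=["subgroup", "trait", "mean_r", "sd_r", "n_folds"])
    )
    return CVResult(
        metrics=metrics, summary=summary, models=models, n_undefined=n_undefined
    )


def _forward_batched(model: TraitCNN, x: np.ndarray, batch_size: int):
    feats, ests = [], []
    for i in range(0, len(x), batch_size):
        f, e = model.forward(x[i : i + batch_size], training=False)
        feats.append(f)
        ests.append(e)
    return np.concatenate(feats), np.concatenate(ests)


def evaluate_metrics(
    y_obs: np.ndarray,
    y_est: np.ndarray,
    treatments: np.ndarray | None = None,
    trait_names=TRAITS,
) -> pd.DataFrame:
    """Pearson r per trait, overall and per treatment, for given predictions."""
    rows, _ = _subgroup_rows(
        np.asarray(y_obs, float), np.asarray(y_est, float), treatments, 0, 0, trait_names
    )
    return pd.DataFrame(rows)
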