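"""Synthetic field generator: genotypes -> breeding values -> plot traits ->
canopy imagery.

Provides the causal structure the downstream pipeline assumes so every stage
is testable without field data: an additive oligogenic architecture with
configurable heritability and genetic trait correlations, replicated plots
under two irrigation treatments (drought modelled as a multiplicative scaling
of the genetic + residual signal), and a procedural canopy renderer whose
outputs respect the vegetation-index segmentation rules used by
:mod:`lsphen.preprocess`.

Trait means/scales are arbitrary but documented defaults; nothing downstream
depends on their absolute values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .preprocess import TRAITS, PlotImagePair, vdvi

# ---------------------------------------------------------------------------
# palettes (config constants; soil VDVI stays below the 0.057 threshold with
# margin, canopy greens stay well above it, under brightness-only noise)
# ---------------------------------------------------------------------------

SOIL_PALETTE = (
    (130, 105, 85),
    (150, 125, 100),
    (120, 95, 75),
    (140, 115, 95),
)
CANOPY_PALETTE = (
    (70, 140, 60),
    (55, 120, 45),
    (80, 160, 70),
    (95, 170, 85),
)
DARK_PIXEL = (5, 8, 5)  # green < 10: exercises the dark-pixel filter

#: plausible raw-trait ranges used to clip values before rendering
RENDER_CLIP = {
    "DW": (1.0, 200.0),
    "SL": (10.0, 150.0),
    "NN": (2.0, 40.0),
    "NB": (0.0, 20.0),
    "PH": (0.0, 180.0),
}

_DEFAULT_H2 = {"DW": 0.6, "SL": 0.6, "NN": 0.7, "NB": 0.4, "PH": 0.7}
_DEFAULT_DROUGHT = {"DW": 0.55, "SL": 0.80, "NN": 0.85, "NB": 0.70, "PH": 0.75}
_DEFAULT_BASE_MEAN = {"DW": 60.0, "SL": 60.0, "NN": 15.0, "NB": 6.0, "PH": 70.0}
_DEFAULT_BASE_SD = {"DW": 18.0, "SL": 12.0, "NN": 3.0, "NB": 1.5, "PH": 14.0}


def _default_trait_cor() -> np.ndarray:
    cor = np.full((5, 5), 0.5)
    np.fill_diagonal(cor, 1.0)
    return cor


@dataclass
class SyntheticFieldConfig:
    """Configuration of the synthetic field experiment.

    Defaults mimic a realistic germplasm trial (198 accessions x 2
    treatments x 2 replicates = 792 plots) but with desk-scale imagery and a
    modest marker panel; all values are configurable.
    """

    n_accessions: int = 198
    n_reps: int = 2
    treatments: tuple[str, ...] = ("control", "drought")
    n_snps: int = 2000
    n_qtl: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_founders: int = 10
    recomb_rate: float = 0.003
    missing_rate: float = 0.02
    heritability: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_H2))
    trait_cor: np.ndarray = field(default_factory=_default_trait_cor)
    drought_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DROUGHT)
    )
    trait_base_mean: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_MEAN)
    )
    trait_base_sd: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_SD)
    )
    image_height: int = 96
    image_width: int = 128
    ground_level: float = 0.0
    n_dark_pixels: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.n_accessions < 2:
            raise ConfigError("n_accessions must be >= 2")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if not (1 <= self.n_qtl <= self.n_snps):
            raise ConfigError("n_qtl must be in [1, n_snps]")
        for t, h2 in self.heritability.items():
            if not (0.0 <= h2 <= 1.0):
                raise ConfigError(f"heritability[{t}] must be in [0, 1], got {h2}")
        if min(self.image_height, self.image_width) < 32:
            raise ConfigError("image dimensions must be >= 32 x 32")
        cor = np.asarray(self.trait_cor, dtype=float)
        if cor.shape != (5, 5):
            raise ConfigError("trait_cor must be 5 x 5")
        if not np.allclose(cor, cor.T):
            raise ConfigError("trait_cor must be symmetric")
        if not np.allclose(np.diag(cor), 1.0):
            raise ConfigError("trait_cor must have unit diagonal")
        self.trait_cor = cor

    def h2_vector(self) -> np.ndarray:
        return np.array([self.heritability[t] for t in TRAITS])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Accession x SNP score matrix with entries in {-1, 0, 1} or NaN (missing).

    Scores code homozygous reference as -1, heterozygous as 0 and homozygous
    alternative as 1.
    """

    scores: np.ndarray
    snp_ids: list[str]
    accession_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        obs = self.scores[~np.isnan(self.scores)]
        if obs.size and not np.isin(obs, (-1.0, 0.0, 1.0)).all():
            raise ValueError("non-missing genotype scores must be in {-1, 0, 1}")

    @property
    def n_accessions(self) -> int:
        return self.scores.shape[0]

    @property
    def n_snps(self) -> int:
        return self.scores.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Alternative-allele frequency per SNP from non-missing entries only."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return (np.nanmean(self.scores, axis=0) + 1.0) / 2.0

    @property
    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.scores).mean(axis=0)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.scores).any()

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            scores=self.scores[:, keep],
            snp_ids=[self.snp_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.snp_ids[i] for i in keep],
            accession_ids=list(self.accession_ids),
        )


def _founder_mosaic_haplotypes(
    rng: np.random.Generator, cfg: SyntheticFieldConfig, p: np.ndarray
) -> np.ndarray:
    """Allele-count matrix from recombination mosaics of founder haplotypes.

    A small founder pool plus low per-SNP switch probability gives the linkage
    disequilibrium and relatedness structure of a germplasm collection, which
    a genomic relationship matrix needs to be informative.
    """
    n_hap = 2 * cfg.n_founders
    founders = (rng.random((n_hap, cfg.n_snps)) < p[None, :]).astype(np.int8)
    counts = np.empty((cfg.n_accessions, cfg.n_snps), dtype=np.int8)
    for i in range(cfg.n_accessions):
        acc = np.zeros(cfg.n_snps, dtype=np.int8)
        for _ in range(2):  # two gametes, each a founder mosaic
            sources = rng.integers(0, n_hap, size=cfg.n_snps)
            switch = rng.random(cfg.n_snps) < cfg.recomb_rate
            switch[0] = True
            segment = np.maximum.accumulate(np.where(switch, np.arange(cfg.n_snps), -1))
            acc += founders[sources[segment], np.arange(cfg.n_snps)]
        counts[i] = acc
    return counts


def simulate_genotypes(cfg: SyntheticFieldConfig) -> GenotypeMatrix:
    """Draw biallelic genotypes.

    Per-SNP generating allele frequencies are uniform on ``cfg.maf_range``.
    With ``cfg.n_founders > 0`` (default) accessions are recombination
    mosaics of a founder haplotype pool — linked, related genotypes like a
    diversity panel; with ``n_founders = 0`` SNPs are independent
    Hardy-Weinberg draws.  Missing entries are inserted completely at random
    at ``cfg.missing_rate``.  Deterministic given ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    if cfg.n_founders > 0:
        counts = _founder_mosaic_haplotypes(rng, cfg, p)
    else:
        # allele count ~ Binomial(2, p) per accession => HWE; score = count - 1
        counts = rng.binomial(2, p[None, :], size=(cfg.n_accessions, cfg.n_snps))
    scores = counts.astype(float) - 1.0
    if cfg.missing_rate > 0:
        miss = rng.random(scores.shape) < cfg.missing_rate
        scores[miss] = np.nan
    return GenotypeMatrix(
        scores=scores,
        snp_ids=[f"SNP{i + 1:06d}" for i in range(cfg.n_snps)],
        accession_ids=[f"ACC{i + 1:04d}" for i in range(cfg.n_accessions)],
    )


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Simulated genetic truth: breeding values, plot phenotypes, QTL effects.

    ``plots`` holds one row per plot (plot_id, accession, treatment,
    replicate); ``plot_traits`` is indexed by plot_id with one column per
    trait.
    """

    breeding_values: pd.DataFrame
    plot_traits: pd.DataFrame
    qtl_effects: pd.DataFrame
    plots: pd.DataFrame


def _correlated_effect_sqrt(cor: np.ndarray) -> np.ndarray:
    """Symmetric square root of a correlation matrix, clipping negative
    eigenvalues at 0 (with a warning) for singular/indefinite inputs."""
    vals, vecs = np.linalg.eigh(cor)
    if vals.min() < -1e-10:
        warnings.warn(
            "trait_cor is not positive semi-definite; negative eigenvalues "
            "clipped at 0",
            stacklevel=3,
        )
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals)) @ vecs.T


def simulate_traits(geno: GenotypeMatrix, cfg: SyntheticFieldConfig) -> GroundTruth:
    """Simulate breeding values and replicated plot phenotypes.

    QTL effects are multivariate normal across the five traits with
    correlation ``cfg.trait_cor``.  Per trait, the genetic column is scaled to
    a documented base scale and residuals are scaled so the realised
    var(g) / (var(g) + var(e)) matches the configured heritability within
    sampling error; the regression of plot phenotype on breeding value has
    slope 1 under the control treatment.  Drought multiplies the whole
    genetic + residual signal.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    n_acc, n_snps = geno.scores.shape

    qtl_idx = np.sort(rng.choice(n_snps, size=cfg.n_qtl, replace=False))
    sqrt_cor = _correlated_effect_sqrt(cfg.trait_cor)
    raw_effects = rng.standard_normal((cfg.n_qtl, 5)) @ sqrt_cor.T

    # missing QTL genotypes mean-imputed for the generating model
    x = geno.scores[:, qtl_idx].copy()
    col_mean = np.nanmean(x, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]

    bv_raw = x @ raw_effects  # (n_acc, 5)
    base_mean = np.array([cfg.trait_base_mean[t] for t in TRAITS])
    base_sd = np.array([cfg.trait_base_sd[t] for t in TRAITS])
    h2 = cfg.h2_vector()

    bv_c = bv_raw - bv_raw.mean(axis=0)
    raw_sd = bv_c.std(axis=0, ddof=0)
    raw_sd[raw_sd == 0] = 1.0
    # genetic sd: base_sd * sqrt(h2); for h2 = 0 keep a reportable nonzero
    # breeding value that simply does not enter the phenotype
    gen_sd = np.where(h2 > 0, base_sd * np.sqrt(h2), base_sd)
    scale = gen_sd / raw_sd
    bv_scaled = bv_c * scale
    breeding_values = base_mean + bv_scaled  # (n_acc, 5), trait units

    # residual sd from realised genetic variance so the realised ratio
    # matches h2; h2 = 1 -> zero residual, h2 = 0 -> pure noise at base scale
    realized_g_sd = bv_scaled.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_sd = np.where(
            h2 >= 1.0,
            0.0,
            np.where(h2 > 0, realized_g_sd * np.sqrt((1 - h2) / h2), base_sd),
        )

    records = []
    values = []
    for treatment in cfg.treatments:
        mult = (
            np.array([cfg.drought_multipliers[t] for t in TRAITS])
            if treatment == "drought"
            else np.ones(5)
        )
        for rep in range(1, cfg.n_reps + 1):
            e = rng.standard_normal((n_acc, 5)) * e_sd
            genetic = np.where(h2 > 0, bv_scaled, 0.0)
            vals = mult * (base_mean + genetic + e)
            for i, acc in enumerate(geno.accession_ids):
                records.append(
                    {
                        "plot_id": f"{acc}_{treatment}_r{rep}",
                        "accession": acc,
                        "treatment": treatment,
                        "replicate": rep,
                    }
                )
            values.append(vals)

    plots = pd.DataFrame.from_records(records).set_index("plot_id")
    plot_traits = pd.DataFrame(
        np.vstack(values), index=plots.index, columns=list(TRAITS)
    )

    qtl_effects = pd.DataFrame(
        np.zeros((n_snps, 5)), index=geno.snp_ids, columns=list(TRAITS)
    )
    qtl_effects.iloc[qtl_idx] = raw_effects * scale

    return GroundTruth(
        breeding_values=pd.DataFrame(
            breeding_values, index=geno.accession_ids, columns=list(TRAITS)
        ),
        plot_traits=plot_traits,
        qtl_effects=qtl_effects,
        plots=plots.reset_index(),
    )


# ---------------------------------------------------------------------------
# scene renderer
# ---------------------------------------------------------------------------


@dataclass
class RenderedScene:
    """A rendered plot with the generator's own ground truth attached."""

    pair: PlotImagePair
    canopy_mask: np.ndarray  # ground-truth vegetation mask (dark pixels excluded)
    meta: dict


def render_plot_scene(
    traits: Mapping[str, float] | Sequence[float],
    cfg: SyntheticFieldConfig,
    seed: int,
    plot_id: str = "",
) -> RenderedScene:
    """Render a procedural canopy scene for one plot.

    Guarantees, by construction:

    * DSM maximum above the ground plane equals plant height (PH cm / 100 m);
    * vegetation-pixel count is strictly monotone in dry weight (within the
      documented clip range and unclipped canvas sizes);
    * sub-blob (texture patch) count is monotone in node + branch counts;
    * background pixels come from the soil palette with VDVI below the
      published segmentation threshold; a few dark pixels (G < 10) are
      injected inside the canopy.

    Deterministic given ``seed``.
    """
    if isinstance(traits, Mapping):
        tvec = np.array([traits[t] for t in TRAITS], dtype=float)
    else:
        tvec = np.asarray(traits, dtype=float)
    if tvec.shape != (5,) or not np.isfinite(tvec).all():
        raise ValueError("traits must be 5 finite values in DW,SL,NN,NB,PH order")
    clip_lo = np.array([RENDER_CLIP[t][0] for t in TRAITS])
    clip_hi = np.array([RENDER_CLIP[t][1] for t in TRAITS])
    dw, sl, nn, nb, ph = np.clip(tvec, clip_lo, clip_hi)

    rng = np.random.default_rng(seed)
    h, w = cfg.image_height, cfg.image_width

    # soil background (per-pixel palette choice + brightness-only noise, which
    # leaves the VDVI numerator unchanged)
    palette = np.array(SOIL_PALETTE, dtype=np.int16)
    choice = rng.integers(0, len(palette), size=(h, w))
    rgb = palette[choice]
    brightness = rng.integers(-12, 13, size=(h, w, 1))
    rgb = np.clip(rgb + brightness, 0, 255)

    # canopy ellipse: area from dry weight, elongation from main stem length
    area_frac = 0.05 + 0.45 * (dw - RENDER_CLIP["DW"][0]) / (
        RENDER_CLIP["DW"][1] - RENDER_CLIP["DW"][0]
    )
    area = area_frac * h * w
    elong = 1.0 + 1.5 * (sl - RENDER_CLIP["SL"][0]) / (
        RENDER_CLIP["SL"][1] - RENDER_CLIP["SL"][0]
    )
    a = np.sqrt(area * elong / np.pi)  # horizontal semi-axis (cols)
    b = np.sqrt(area / (elong * np.pi))  # vertical semi-axis (rows)
    shrink = min(1.0, 0.48 * w / a, 0.48 * h / b)
    a *= shrink
    b *= shrink

    cr = h / 2.0 + rng.uniform(-0.03, 0.03) * h
    cc = w / 2.0 + rng.uniform(-0.03, 0.03) * w
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    q = ((rows - cr) / b) ** 2 + ((cols - cc) / a) ** 2
    canopy = q <= 1.0

    # canopy fill + sub-blob texture (granularity tracks node + branch count)
    greens = np.array(CANOPY_PALETTE, dtype=np.int16)
    rgb[canopy] = np.clip(greens[0] + brightness[canopy], 0, 255)
    n_sub = int(np.clip(3 + round(0.5 * (nn + nb)), 3, 40))
    sub_r = max(1.5, 0.8 * min(a, b) / np.sqrt(n_sub))
    for i in range(n_sub):
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 0.9))
        scr = cr + rad * b * np.sin(ang)
        scc = cc + rad * a * np.cos(ang)
        patch = ((rows - scr) ** 2 + (cols - scc) ** 2 <= sub_r**2) & canopy
        color = greens[1 + (i % (len(greens) - 1))]
        rgb[patch] = np.clip(color + brightness[patch], 0, 255)

    # DSM: flat ground plane + elliptic dome whose peak equals plant height
    peak = ph / 100.0  # cm -> m
    dsm = np.full((h, w), cfg.ground_level, dtype=np.float32)
    if peak > 0 and canopy.any():
        dome = peak * np.sqrt(np.clip(1.0 - q, 0.0, None))
        dsm[canopy] = cfg.ground_level + dome[canopy].astype(np.float32)
        nearest = (int(round(cr)), int(round(cc)))
        if 0 <= nearest[0] < h and 0 <= nearest[1] < w and canopy[nearest]:
            dsm[nearest] = cfg.ground_level + peak  # exact maximum

    # inject a few dark pixels (G < 10) inside the canopy
    mask = canopy.copy()
    canopy_idx = np.flatnonzero(canopy)
    if cfg.n_dark_pixels > 0 and canopy_idx.size > cfg.n_dark_pixels:
        dark = rng.choice(canopy_idx, size=cfg.n_dark_pixels, replace=False)
        dr, dc = np.unravel_index(dark, (h, w))
        rgb[dr, dc] = DARK_PIXEL
        mask[dr, dc] = False  # G < 10 pixels are not vegetation by contract

    rgb8 = rgb.astype(np.uint8)
    pair = PlotImagePair(rgb=rgb8, dsm=dsm, mask=mask, plot_id=plot_id)
    meta = {
        "veg_pixels": int(mask.sum()),
        "canopy_pixels": int(canopy.sum()),
        "n_subblobs": n_sub,
        "dsm_peak": float(peak),
        "max_soil_vdvi": float(vdvi(rgb8[~canopy]).max()) if (~canopy).any() else None,
    }
    return RenderedScene(pair=pair, canopy_mask=canopy, meta=meta)


# ---------------------------------------------------------------------------
# whole-field convenience + rank-2 latent world (for leakage/plateau checks)
# ---------------------------------------------------------------------------


@dataclass
class FieldDataset:
    """Bundle of everything one synthetic field run produces (images lazy)."""

    cfg: SyntheticFieldConfig
    genotypes: GenotypeMatrix
    truth: GroundTruth

    def render(self, plot_id: str) -> RenderedScene:
        row = self.truth.plots.set_index("plot_id").loc[plot_id]
        traits = self.truth.plot_traits.loc[plot_id]
        seed = _plot_seed(self.cfg.rng_seed, plot_id)
        return render_plot_scene(traits, self.cfg, seed=seed, plot_id=plot_id)

    def render_all(self):
        for plot_id in self.truth.plots["plot_id"]:
            yield self.render(plot_id)


def _plot_seed(base_seed: int, plot_id: str) -> int:
    # stable, platform-independent per-plot seed
    digest = np.frombuffer(plot_id.encode(), dtype=np.uint8).astype(np.uint64)
    mix = np.uint64(base_seed % (2**32))
    for byte in digest:
        mix = (mix * np.uint64(1000003) + byte) % np.uint64(2**31 - 1)
    return int(mix)


def simulate_field(cfg: SyntheticFieldConfig) -> FieldDataset:
    """Generate genotypes + ground truth for a full synthetic field."""
    geno = simulate_genotypes(cfg)
    truth = simulate_traits(geno, cfg)
    return FieldDataset(cfg=cfg, genotypes=geno, truth=truth)


def simulate_rank2_latent_world(
    n_accessions: int = 150,
    n_snps: int = 1000,
    n_qtl: int = 40,
    n_features: int = 30,
    h2: float = 0.9,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> dict:
    """A world in which all genetic signal lies in a rank-2 latent subspace.

    Latent features are built from two genetically controlled drivers placed
    along orthonormal directions with large variance (so PCA ranks them
    first), plus isotropic noise in the remaining directions.  Traits are an
    exact linear function of the features.  Used to verify that the
    PC-mediated prediction accuracy plateaus once both signal directions are
    included.

    Returns a dict with geno, features, W, b, traits, accession_ids, drivers.
    """
    rng = np.random.default_rng(seed)
    cfg = SyntheticFieldConfig(
        n_accessions=n_accessions,
        n_snps=n_snps,
        n_qtl=n_qtl,
        missing_rate=0.0,
        rng_seed=seed,
    )
    geno = simulate_genotypes(cfg)

    drivers = []
    for d in range(2):
        qtl = rng.choice(n_snps, size=n_qtl, replace=False)
        beta = rng.standard_normal(n_qtl)
        g = geno.scores[:, qtl] @ beta
        g = (g - g.mean()) / g.std()
        e = rng.standard_normal(n_accessions) * np.sqrt((1 - h2) / h2)
        drivers.append(g + e)
    d1, d2 = (d / d.std() for d in drivers)

    basis = np.linalg.qr(rng.standard_normal((n_features, 2)))[0]
    v1, v2 = basis[:, 0], basis[:, 1]
    features = (
        3.0 * np.outer(d1, v1)
        + 2.0 * np.outer(d2, v2)
        + noise_sd * rng.standard_normal((n_accessions, n_features))
    )
    a1 = rng.standard_normal(5)
    a2 = rng.standard_normal(5)
    W = np.outer(v1, a1) + np.outer(v2, a2)  # (n_features, 5)
    b = rng.standard_normal(5)
    traits = features @ W + b
    return {
        "geno": geno,
        "features": features,
        "W": W,
        "b": b,
        "traits": traits,
        "accession_ids": list(geno.accession_ids),
        "drivers": np.column_stack([d1, d2]),
    }
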