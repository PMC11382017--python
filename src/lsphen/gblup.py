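"""Genomic prediction by GBLUP.

Pipeline: biallelic SNP scores in {-1, 0, 1} are filtered on minor allele
frequency and missing rate, modally imputed, and turned into a genomic
relationship matrix G = X X^T / c with the normalisation constant
c = 2 * sum_k p_k (1 - p_k).  The mixed model

    y = 1 mu + Z g + e,   g ~ MVN(0, G sg2),  e ~ MVN(0, I se2)

is fitted by REML with a one-dimensional search over the variance ratio on
the eigenbasis of Z G Z^T (deterministic, O(n^3) once).  Held-out accessions
are predicted through the joint MVN conditional, which is what fitting the
model with their phenotypes treated as missing computes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cnn.cv import CVScheme, pearson
from .exceptions import UndefinedCorrelationError
from .synthetic_data import GenotypeMatrix

logger = logging.getLogger(__name__)

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_dropped_maf: int
    n_dropped_missing: int


def filter_snps(
    geno: GenotypeMatrix, maf_min: float = 0.025, missing_max: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep SNPs with MAF >= ``maf_min`` and missing fraction < ``missing_max``."""
    p = geno.allele_freq
    maf = np.minimum(p, 1.0 - p)
    miss = geno.missing_fraction
    ok_maf = np.nan_to_num(maf, nan=-1.0) >= maf_min
    ok_miss = miss < missing_max
    keep = ok_maf & ok_miss
    if not keep.any():
        raise ValueError("all SNPs removed by MAF/missing-rate filtering")
    report = FilterReport(
        n_input=geno.n_snps,
        n_kept=int(keep.sum()),
        n_dropped_maf=int((~ok_maf).sum()),
        n_dropped_missing=int((~ok_miss).sum()),
    )
    return geno.subset_snps(keep), report


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing entries with the per-SNP modal score.

    A stand-in for LD-aware imputation, adequate for missing-completely-at-
    random gaps.  Never changes non-missing entries.  Raises for an entirely
    missing SNP (should have been filtered out).
    """
    scores = geno.scores.copy()
    for j in range(scores.shape[1]):
        col = scores[:, j]
        nan = np.isnan(col)
        if not nan.any():
            continue
        obs = col[~nan]
        if obs.size == 0:
            raise ValueError(f"SNP {geno.snp_ids[j]} is entirely missing")
        levels, counts = np.unique(obs, return_counts=True)
        col[nan] = levels[np.argmax(counts)]
    return GenotypeMatrix(
        scores=scores, snp_ids=list(geno.snp_ids), accession_ids=list(geno.accession_ids)
    )


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    """Genomic relationship matrix with its normalisation constant."""

    G: np.ndarray
    c: float
    accession_ids: list[str]
    allele_freq: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")


def compute_grm(geno: GenotypeMatrix, center: bool = True) -> GRM:
    """G = X X^T / c with c = 2 * sum_k p_k (1 - p_k).

    With ``center`` (default) each SNP column has its HWE mean 2p - 1 (on the
    {-1, 0, 1} coding) subtracted before the cross-product — the VanRaden
    construction matching the normalisation constant.  ``center=False``
    reproduces the literal uncentered formula.  Monomorphic SNPs contribute 0
    to c and are excluded with a warning.
    """
    if not geno.is_complete:
        raise ValueError("GRM needs a complete (imputed) score matrix")
    p = geno.allele_freq
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic SNP(s) excluded from the GRM",
            stacklevel=2,
        )
    x = geno.scores[:, poly]
    p = p[poly]
    if center:
        x = x - (2.0 * p - 1.0)
    c = 2.0 * float(np.sum(p * (1.0 - p)))
    if c <= 0:
        raise ValueError("normalisation constant c is zero: no polymorphic SNPs")
    return GRM(
        G=(x @ x.T) / c,
        c=c,
        accession_ids=list(geno.accession_ids),
        allele_freq=p,
    )


def make_incidence(plot_accessions, accession_ids: list[str]) -> np.ndarray:
    """n x m design matrix mapping each plot to its accession column."""
    index = {a: i for i, a in enumerate(accession_ids)}
    z = np.zeros((len(plot_accessions), len(accession_ids)))
    for row, acc in enumerate(plot_accessions):
        z[row, index[acc]] = 1.0
    return z


# ---------------------------------------------------------------------------
# REML fit
# ---------------------------------------------------------------------------


@dataclass
class GBLUPFit:
    """Fitted mixed-model components and breeding-value predictions."""

    mu: float
    sigma2_g: float
    sigma2_e: float
    g_hat: np.ndarray  # one entry per accession column of G
    Z: np.ndarray
    accession_ids: list[str] | None = None
    boundary: bool = False

    @property
    def h2(self) -> float:
        total = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / total if total > 0 else 0.0


def fit_gblup(
    y: np.ndarray, Z: np.ndarray, G: np.ndarray | GRM, lam: float | None = None
) -> GBLUPFit:
    """REML fit of y = 1 mu + Z g + e.

    The variance ratio lambda = sg2 / se2 is profiled on the eigenbasis of
    Z G Z^T (Brent search over log lambda); mu and the variances follow in
    closed form, and g_hat is the BLUP given the estimates — for every
    accession in G, observed or not.  Deterministic.  A flat likelihood
    driving lambda to the search boundary sets ``boundary``.

    Passing ``lam`` fixes the variance ratio and skips the REML search
    (useful for shared-shrinkage comparisons and speed).
    """
    grm = G if isinstance(G, GRM) else None
    Gmat = G.G if grm is not None else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    n = y.size
    if Z.shape[0] != n or Z.shape[1] != Gmat.shape[0]:
        raise ValueError(
            f"dimension mismatch: y {y.shape}, Z {Z.shape}, G {Gmat.shape}"
        )
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")

    evals = np.linalg.eigvalsh(Gmat)
    if evals.min() < -1e-8:
        warnings.warn(
            "G has negative eigenvalues; clipping to positive semi-definite",
            stacklevel=2,
        )
        vals, vecs = np.linalg.eigh(Gmat)
        Gmat = (vecs * np.clip(vals, 0.0, None)) @ vecs.T

    K = Z @ Gmat @ Z.T
    D, U = np.linalg.eigh(K)
    D = np.clip(D, 0.0, None)
    y_t = U.T @ y
    x_t = U.T @ np.ones(n)

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = lam * D + 1.0
        xtvx = np.sum(x_t * x_t / d)
        mu = np.sum(x_t * y_t / d) / xtvx
        r = y_t - mu * x_t
        rss = np.sum(r * r / d)
        return float(np.sum(np.log(d)) + np.log(xtvx) + (n - 1) * np.log(max(rss, 1e-300)))

    if lam is None:
        res = minimize_scalar(
            neg2_reml, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
            options={"xatol": 1e-8},
        )
        log_lam = float(res.x)
        boundary = (
            log_lam <= _LOG_LAMBDA_BOUNDS[0] + 1e-3
            or log_lam >= _LOG_LAMBDA_BOUNDS[1] - 1e-3
        )
        if boundary:
            logger.info("REML variance ratio at search boundary (log lambda=%.3f)", log_lam)
        lam = np.exp(log_lam)
    else:
        if lam <= 0:
            raise ValueError("fixed variance ratio must be positive")
        boundary = False
    d = lam * D + 1.0
    xtvx = np.sum(x_t * x_t / d)
    mu = float(np.sum(x_t * y_t / d) / xtvx)
    r = y_t - mu * x_t
    sigma2_e = float(np.sum(r * r / d) / (n - 1))
    sigma2_g = float(lam * sigma2_e)

    # BLUP: g_hat = lam * G Z^T (lam K + I)^{-1} (y - 1 mu)
    g_hat = lam * (Gmat @ (Z.T @ (U @ (r / d))))
    return GBLUPFit(
        mu=mu,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        g_hat=g_hat,
        Z=Z,
        accession_ids=grm.accession_ids if grm is not None else None,
        boundary=boundary,
    )


def predict_unobserved(fit: GBLUPFit, target_idx: np.ndarray) -> np.ndarray:
    """Predicted phenotypic values mu + g_hat for target accession columns.

    ``fit`` must come from a call whose G covered the targets (their
    phenotypes simply absent from y); the BLUP then already is the joint-MVN
    conditional mean given the training observations.
    """
    target_idx = np.asarray(target_idx)
    if target_idx.size and target_idx.max() >= fit.g_hat.size:
        raise ValueError("target accession index outside the fitted G")
    return fit.mu + fit.g_hat[target_idx]


# ---------------------------------------------------------------------------
# cross-validated accuracy
# ---------------------------------------------------------------------------


def cv_gblup(
    y: np.ndarray,
    plot_accessions: np.ndarray,
    grm: GRM,
    scheme: CVScheme,
    treatments: np.ndarray | None = None,
    target: str = "trait",
    lam: float | None = None,
) -> pd.DataFrame:
    """Repeated k-fold CV of GBLUP accuracy, run independently per treatment.

    Folds partition accessions (replicates of an accession move together);
    per fold the model is fitted on training plots with the full G and
    held-out plots are predicted as mu + g_hat[accession].  Rows: treatment,
    target, repetition, fold, r, n.  Folds with fewer than 3 held-out
    accessions are skipped with a log entry.
    """
    y = np.asarray(y, dtype=float).ravel()
    plot_accessions = np.asarray(plot_accessions)
    if treatments is None:
        treatments = np.array(["all"] * y.size)
    treatments = np.asarray(treatments)
    acc_index = {a: i for i, a in enumerate(grm.accession_ids)}

    rows = []
    for treat in np.unique(treatments):
        sel = treatments == treat
        y_s, acc_s = y[sel], plot_accessions[sel]
        units = sorted(set(acc_s))
        for rep, fold_of in enumerate(
            CVScheme(scheme.k, scheme.repetitions, unit="accession", seed=scheme.seed).assignments(units)
        ):
            plot_fold = np.array([fold_of[a] for a in acc_s])
            for fold in range(scheme.k):
                test = plot_fold == fold
                held_acc = set(acc_s[test])
                if len(held_acc) < 3:
                    logger.info(
                        "skipping fold %d rep %d (%s): only %d held-out accessions",
                        fold, rep, treat, len(held_acc),
                    )
                    continue
                train = ~test
                Z_train = make_incidence(acc_s[train], grm.accession_ids)
                fit = fit_gblup(y_s[train], Z_train, grm, lam=lam)
                t_idx = np.array([acc_index[a] for a in acc_s[test]])
                pred = predict_unobserved(fit, t_idx)
                try:
                    r = pearson(y_s[test], pred)
                except UndefinedCorrelationError:
                    logger.info("undefined r: fold %d rep %d (%s)", fold, rep, treat)
                    continue
                rows.append(
                    {
                        "treatment": str(treat),
                        "target": target,
                        "repetition": rep,
                        "fold": fold,
                        "r": r,
                        "n": int(test.sum()),
                    }
                )
    return pd.DataFrame(rows)


def summarize_cv(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of r per (treatment, target)."""
    return (
        metrics.groupby(["treatment", "target"])["r"]
        .agg(mean_r="mean", sd_r="std", n_folds="count")
        .reset_index()
    )
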