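"""Trait prediction from genomically predicted PC scores of latent features.

Per CV fold (accessions partitioned, run independently per treatment):

1. standardise the latent features on the training fold only;
2. fit PCA on the training-fold features only (fold-local, leakage-free);
3. fit one GBLUP per PC on the training-fold scores;
4. predict held-out accessions' PC scores;
5. Ytilde = Stilde[:, :l] W'[:l] + 1 b'^T with the fold's PC-space head;
6. Pearson r between predicted and observed traits, per trait.

Sweeping l = 1..l_max locates how many PCs carry the genetic signal.  Note
that a consistent per-PC sign flip of eigenvectors, scores and W' rows
cancels exactly in step 5, so no cross-trial sign alignment is needed for
prediction (it matters only for weight visualisation).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn.cv import CVScheme, pearson
from .exceptions import UndefinedCorrelationError
from .gblup import GRM, fit_gblup, make_incidence, predict_unobserved
from .latent import fit_pca, pc_regression_head
from .preprocess import TRAITS


def predict_traits_from_pcs(
    S_tilde: np.ndarray, W_prime: np.ndarray, b: np.ndarray, l: int
) -> np.ndarray:
    """Ytilde = Stilde[:, :l] W'[:l, :] + 1 b^T.

    Rows of W' beyond ``l`` are unused.  ``l`` must be >= 1 and no larger
    than the available PCs.
    """
    S_tilde = np.asarray(S_tilde, dtype=float)
    W_prime = np.asarray(W_prime, dtype=float)
    b = np.asarray(b, dtype=float)
    if l < 1:
        raise ValueError("l must be >= 1")
    if l > W_prime.shape[0] or l > S_tilde.shape[1]:
        raise ValueError(
            f"l={l} exceeds available PCs (scores {S_tilde.shape[1]}, "
            f"weights {W_prime.shape[0]})"
        )
    return S_tilde[:, :l] @ W_prime[:l] + b


@dataclass
class SweepResult:
    """Accuracy surface plus per-fold fitting records for leakage auditing."""

    metrics: pd.DataFrame  # treatment, trait, l, repetition, fold, r, n
    summary: pd.DataFrame  # treatment, trait, l, mean_r, sd_r
    fit_records: list = field(default_factory=list)
    scheme_seed: int = 0


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
    return h.hexdigest()


def sweep_components(
    features: np.ndarray,
    traits_obs: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    grm: GRM,
    plot_accessions: np.ndarray,
    scheme: CVScheme,
    treatments: np.ndarray | None = None,
    l_max: int = 10,
    lam: float | None = None,
    trait_names=TRAITS,
) -> SweepResult:
    """Accuracy surface (treatment x trait x l) of PC-mediated prediction.

    ``features`` are the raw bottleneck features as seen by the head (W, b);
    the fold-local standardisation + PCA + per-PC GBLUP pipeline above is run
    for every repetition/fold of ``scheme`` over accessions, independently
    per treatment.  Test-fold rows never enter scaling statistics, PCA, or
    GBLUP fitting; each fold's fitting inputs are checksummed into
    ``fit_records`` so tests can audit this.
    """
    features = np.asarray(features, dtype=float)
    traits_obs = np.asarray(traits_obs, dtype=float)
    plot_accessions = np.asarray(plot_accessions)
    n_traits = traits_obs.shape[1]
    if treatments is None:
        treatments = np.array(["all"] * len(features))
    treatments = np.asarray(treatments)
    l_max = min(l_max, features.shape[1])
    acc_index = {a: i for i, a in enumerate(grm.accession_ids)}

    rows: list[dict] = []
    fit_records: list[dict] = []
    for treat in np.unique(treatments):
        sel = treatments == treat
        X_s, Y_s, acc_s = features[sel], traits_obs[sel], plot_accessions[sel]
        units = sorted(set(acc_s))
        assignments = CVScheme(
            scheme.k, scheme.repetitions, unit="accession", seed=scheme.seed
        ).assignments(units)
        for rep, fold_of in enumerate(assignments):
            plot_fold = np.array([fold_of[a] for a in acc_s])
            for fold in range(scheme.k):
                test = plot_fold == fold
                train = ~test
                if len(set(acc_s[test])) < 3:
                    continue

                # fold-local standardisation and PCA (training rows only)
                mean = X_s[train].mean(axis=0)
                sd = X_s[train].std(axis=0, ddof=0)
                sd = np.where(sd > 0, sd, 1.0)
                Xs_train = (X_s[train] - mean) / sd
                pca, S_train = fit_pca(Xs_train)
                W_prime, b_prime = pc_regression_head(
                    pca, W, b, scaling_mean=mean, scaling_sd=sd
                )
                fit_records.append(
                    {
                        "treatment": str(treat),
                        "repetition": rep,
                        "fold": fold,
                        "train_checksum": _checksum(X_s[train], Y_s[train]),
                        "n_train": int(train.sum()),
                        "n_test": int(test.sum()),
                    }
                )

                # one GBLUP per PC on training scores; predict held-out accessions
                Z_train = make_incidence(acc_s[train], grm.accession_ids)
                t_idx = np.array([acc_index[a] for a in acc_s[test]])
                S_tilde = np.empty((int(test.sum()), l_max))
                for j in range(l_max):
                    fit = fit_gblup(S_train[:, j], Z_train, grm, lam=lam)
                    S_tilde[:, j] = predict_unobserved(fit, t_idx)

                for l in range(1, l_max + 1):
                    y_tilde = predict_traits_from_pcs(S_tilde, W_prime, b_prime, l)
                    for t in range(n_traits):
                        try:
                            r = pearson(Y_s[test, t], y_tilde[:, t])
                        except UndefinedCorrelationError:
                            continue
                        rows.append(
                            {
                                "treatment": str(treat),
                                "trait": trait_names[t],
                                "l": l,
                                "repetition": rep,
                                "fold": fold,
                                "r": r,
                                "n": int(test.sum()),
                            }
                        )

    metrics = pd.DataFrame(rows)
    summary = (
        metrics.groupby(["treatment", "trait", "l"])["r"]
        .agg(mean_r="mean", sd_r="std", n_folds="count")
        .reset_index()
        if len(metrics)
        else pd.DataFrame(columns=["treatment", "trait", "l", "mean_r", "sd_r", "n_folds"])
    )
    return SweepResult(
        metrics=metrics, summary=summary, fit_records=fit_records, scheme_seed=scheme.seed
    )


def compare_direct_vs_pc(
    direct_metrics: pd.DataFrame,
    sweep: SweepResult,
    direct_scheme_seed: int,
) -> pd.DataFrame:
    """Side-by-side table of direct GBLUP vs PC-mediated accuracy.

    ``direct_metrics`` comes from :func:`lsphen.gblup.cv_gblup` run with the
    same fold scheme (identical seed enforced).  Rows cover every
    (treatment, trait, method) with per-l rows for the PC route and the
    difference to the direct route.
    """
    if direct_scheme_seed != sweep.scheme_seed:
        raise ValueError(
            f"mismatched fold schemes: direct seed {direct_scheme_seed} vs "
            f"sweep seed {sweep.scheme_seed}"
        )
    direct = (
        direct_metrics.groupby(["treatment", "target"])["r"].mean().reset_index()
        .rename(columns={"target": "trait", "r": "mean_r"})
    )
    direct["method"] = "gblup_direct"
    direct["l"] = pd.NA

    pc = sweep.summary[["treatment", "trait", "l", "mean_r"]].copy()
    pc["method"] = "pc_mediated"

    merged = pc.merge(
        direct[["treatment", "trait", "mean_r"]].rename(columns={"mean_r": "direct_r"}),
        on=["treatment", "trait"],
        how="left",
    )
    merged["diff_vs_direct"] = merged["mean_r"] - merged["direct_r"]
    direct["direct_r"] = direct["mean_r"]
    direct["diff_vs_direct"] = 0.0
    cols = ["treatment", "trait", "method", "l", "mean_r", "direct_r", "diff_vs_direct"]
    return pd.concat([direct[cols], merged[cols]], ignore_index=True)
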