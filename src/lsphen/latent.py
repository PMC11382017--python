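"""Latent-space phenotypes: PCA of the bottleneck features and rotation of
the regression head into PC space.

With PC scores defined as S = X E (E the orthonormal eigenvectors of the
covariance of X, sorted by descending eigenvalue), the head's trait estimates
X W + 1 b^T equal S (E^T W) + 1 b^T exactly, so W' = E^T W annotates each PC
by its contribution to the five traits.  Eigenvector signs are arbitrary per
fit, so W' rows are sign-aligned to the modal pattern across CV trials before
averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ShapeError
from .preprocess import TRAITS


@dataclass
class PCAModel:
    """Eigendecomposition of the feature covariance.

    ``E`` has orthonormal eigenvector columns; scores are the uncentered
    projection S = X E so the reconstruction X = S E^T is exact.  ``center``
    records the fitting-set column means (diagnostic; ~0 for standardised
    features).
    """

    E: np.ndarray
    center: np.ndarray
    explained_variance: np.ndarray
    proportion_of_variance: np.ndarray

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.E

    def reconstruct(self, S: np.ndarray) -> np.ndarray:
        return np.asarray(S) @ self.E.T


def fit_pca(X: np.ndarray) -> tuple[PCAModel, np.ndarray]:
    """PCA of an n x p feature matrix (expected column-standardised).

    Returns the model and the score matrix S = X E.  Rank-deficient
    covariances have their negative eigenvalues clipped at 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1) if n > 1 else np.zeros((p, p))
    vals, vecs = np.linalg.eigh(cov)
    if n - 1 < p:
        warnings.warn(
            f"covariance of {n} x {p} matrix is rank-deficient; "
            "eigenvalues clipped at 0",
            stacklevel=2,
        )
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    total = vals.sum()
    prop = vals / total if total > 0 else np.full(p, 1.0 / p)
    model = PCAModel(
        E=vecs,
        center=center,
        explained_variance=vals,
        proportion_of_variance=prop,
    )
    return model, model.scores(X)


def transform_weights(W: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Rotate the head weights into PC space: W' = E^T W.

    With all PCs retained, S W' + 1 b^T reproduces X W + 1 b^T exactly.
    """
    W = np.asarray(W, dtype=float)
    E = np.asarray(E, dtype=float)
    if E.shape[0] != W.shape[0] or E.shape[0] != E.shape[1]:
        raise ShapeError(
            f"shape mismatch: E {E.shape} must be square and match W rows {W.shape}"
        )
    return E.T @ W


def pc_regression_head(
    pca: PCAModel,
    W: np.ndarray,
    b: np.ndarray,
    scaling_mean: np.ndarray | None = None,
    scaling_sd: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fold-local PC-space head (W', b') such that S W' + 1 b'^T equals the
    original head X W + 1 b^T exactly.

    When the PCA was fitted on standardised features Xs = (X - m) / s, the
    algebra X W + b = Xs (diag(s) W) + (m^T W + b) folds the scaling into the
    weights before rotation; pass the scaling statistics to account for it.
    """
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if scaling_sd is not None:
        W_eff = scaling_sd[:, None] * W
    else:
        W_eff = W
    b_eff = b if scaling_mean is None else b + W.T @ scaling_mean
    return transform_weights(W_eff, pca.E), b_eff


# ---------------------------------------------------------------------------
# sign alignment across CV trials
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedWeights:
    """One CV trial's PC-space weights plus its sign pattern."""

    W_prime: np.ndarray
    trial_id: str = ""
    proportion_of_variance: np.ndarray | None = None

    @property
    def sign_pattern(self) -> np.ndarray:
        return np.sign(self.W_prime).astype(int)


def align_sign_patterns(
    trials: list[AnnotatedWeights], n_pcs: int = 3
) -> tuple[list[AnnotatedWeights], np.ndarray, np.ndarray]:
    """Resolve per-PC eigenvector sign indeterminacy across trials.

    For each of the first ``n_pcs`` PCs (rows of W'), each trial's row may be
    globally negated; the flip maximising agreement with the running modal
    sign pattern is chosen, ties broken toward no flip.  PCs are matched
    across trials by explained-variance rank only (no permutation matching).

    Returns (aligned trials, modal pattern (n_pcs x 5) in {-1, 0, 1},
    flips (n_trials x n_pcs) in {-1, +1}).
    """
    if len(trials) < 2:
        raise ValueError("need >= 2 trials to align")
    n_traits = trials[0].W_prime.shape[1]
    flips = np.ones((len(trials), n_pcs), dtype=int)
    aligned: list[AnnotatedWeights] = []

    # running vote per PC row: sum of aligned sign vectors so far
    votes = np.zeros((n_pcs, n_traits))
    for t_idx, trial in enumerate(trials):
        W = trial.W_prime.copy()
        for pc in range(n_pcs):
            s = np.sign(W[pc])
            agree_keep = float(np.sum(np.sign(votes[pc]) * s))
            agree_flip = -agree_keep
            if agree_flip > agree_keep:  # strict: ties keep orientation
                W[pc] = -W[pc]
                flips[t_idx, pc] = -1
                s = -s
            votes[pc] += s
        aligned.append(replace(trial, W_prime=W))

    modal = np.sign(votes).astype(int)
    return aligned, modal, flips


def average_weights(
    aligned: list[AnnotatedWeights],
) -> tuple[np.ndarray, "np.ndarray | None", "np.ndarray | None"]:
    """Entry-wise mean of aligned W' matrices across trials.

    Also returns the mean and sd of the per-PC proportion of variance across
    trials when the trials carry it (else None, None).
    """
    stack = np.stack([t.W_prime for t in aligned])
    mean_w = stack.mean(axis=0)
    props = [t.proportion_of_variance for t in aligned]
    if all(p is not None for p in props):
        parr = np.stack(props)
        return mean_w, parr.mean(axis=0), parr.std(axis=0, ddof=0)
    return mean_w, None, None


def annotation_graph(mean_w_prime: np.ndarray, n_pcs: int) -> list[dict]:
    """Signed, weighted PC-trait edge list for visualisation.

    One edge per (PC, trait) pair for the first ``n_pcs`` PCs: weight is the
    W' entry, sign its sign (colour class), abs_weight the line width.
    """
    W = np.asarray(mean_w_prime, dtype=float)
    edges = []
    for pc in range(n_pcs):
        for t, trait in enumerate(TRAITS[: W.shape[1]]):
            w = float(W[pc, t])
            edges.append(
                {
                    "pc": pc + 1,
                    "trait": trait,
                    "weight": w,
                    "sign": int(np.sign(w)),
                    "abs_weight": abs(w),
                }
            )
    return edges
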