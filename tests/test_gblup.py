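import numpy as np
import pandas as pd
import pytest

from lsphen.cnn import CVScheme
from lsphen.gblup import (
    GRM,
    compute_grm,
    cv_gblup,
    filter_snps,
    fit_gblup,
    impute_missing,
    make_incidence,
    predict_unobserved,
    summarize_cv,
)
from lsphen.preprocess import TRAITS
from lsphen.synthetic_data import (
    GenotypeMatrix,
    SyntheticFieldConfig,
    simulate_genotypes,
    simulate_rank2_latent_world,
    simulate_traits,
)


def _geno(scores):
    scores = np.asarray(scores, dtype=float)
    return GenotypeMatrix(
        scores=scores,
        snp_ids=[f"S{j}" for j in range(scores.shape[1])],
        accession_ids=[f"A{i}" for i in range(scores.shape[0])],
    )


def _column_with_freq(n, p):
    """Score column whose alternative-allele frequency is exactly p."""
    n_alt = int(round(2 * n * p))
    hom_alt, het = divmod(n_alt, 2)
    col = np.full(n, -1.0)
    col[:hom_alt] = 1.0
    if het:
        col[hom_alt] = 0.0
    return col


# ---------------------------------------------------------------------------
# filtering and imputation
# ---------------------------------------------------------------------------


class TestFilterSnps:
    def test_low_maf_dropped(self):
        n = 100
        geno = _geno(np.column_stack([_column_with_freq(n, 0.01), _column_with_freq(n, 0.3)]))
        kept, report = filter_snps(geno)
        assert kept.snp_ids == ["S1"]
        assert report.n_dropped_maf == 1

    def test_high_missing_dropped(self):
        n = 100
        col = _column_with_freq(n, 0.3)
        missing = col.copy()
        missing[:6] = np.nan  # 6% missing
        geno = _geno(np.column_stack([col, missing]))
        kept, report = filter_snps(geno)
        assert kept.snp_ids == ["S0"]
        assert report.n_dropped_missing == 1

    def test_toy_frequencies(self):
        # freqs {0.5, 0.03, 0.02, 0.25, 0.024}: MAF >= 0.025 keeps 3
        n = 500
        cols = [_column_with_freq(n, p) for p in (0.5, 0.03, 0.02, 0.25, 0.024)]
        kept, report = filter_snps(_geno(np.column_stack(cols)))
        assert kept.snp_ids == ["S0", "S1", "S3"]
        assert report.n_kept == 3

    def test_all_filtered_raises(self):
        geno = _geno(_column_with_freq(100, 0.001)[:, None])
        with pytest.raises(ValueError, match="all SNPs"):
            filter_snps(geno)


class TestImputeMissing:
    def test_no_missing_identity(self):
        geno = _geno(_column_with_freq(10, 0.3)[:, None])
        out = impute_missing(geno)
        np.testing.assert_array_equal(out.scores, geno.scores)

    def test_mode_by_counting(self):
        geno = _geno(np.array([[1.0], [1.0], [-1.0], [np.nan]]))
        out = impute_missing(geno)
        assert out.scores[3, 0] == 1.0

    def test_nonmissing_unchanged(self):
        rng = np.random.default_rng(0)
        scores = rng.choice([-1.0, 0.0, 1.0], size=(30, 10))
        mask = rng.random((30, 10)) < 0.2
        with_missing = scores.copy()
        with_missing[mask] = np.nan
        out = impute_missing(_geno(with_missing))
        np.testing.assert_array_equal(out.scores[~mask], scores[~mask])
        assert out.is_complete

    def test_fully_missing_snp_raises(self):
        geno = _geno(np.full((4, 1), np.nan))
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(geno)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


class TestComputeGRM:
    def test_hand_computed_single_snp(self):
        # genotypes (-1, 1): p = 0.5, centering shift 2p-1 = 0,
        # c = 2 * 0.25 = 0.5, G = XX^T / c = [[2, -2], [-2, 2]]
        geno = _geno(np.array([[-1.0], [1.0]]))
        grm = compute_grm(geno)
        assert grm.c == pytest.approx(0.5)
        np.testing.assert_allclose(grm.G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_accessions(self):
        rng = np.random.default_rng(1)
        row = rng.choice([-1.0, 0.0, 1.0], size=50)
        other = rng.choice([-1.0, 0.0, 1.0], size=(3, 50))
        grm = compute_grm(_geno(np.vstack([row, row, other])))
        assert grm.G[0, 1] == pytest.approx(grm.G[0, 0])
        assert grm.G[1, 1] == pytest.approx(grm.G[0, 0])

    def test_psd_property(self):
        rng = np.random.default_rng(2)
        geno = _geno(rng.choice([-1.0, 0.0, 1.0], size=(20, 100)))
        grm = compute_grm(geno)
        assert np.linalg.eigvalsh(grm.G).min() > -1e-10

    def test_uncentered_literal_formula(self):
        rng = np.random.default_rng(3)
        x = rng.choice([-1.0, 0.0, 1.0], size=(10, 40))
        geno = _geno(x)
        grm = compute_grm(geno, center=False)
        p = geno.allele_freq
        poly = (p > 0) & (p < 1)
        c = 2 * np.sum(p[poly] * (1 - p[poly]))
        np.testing.assert_allclose(grm.G, x[:, poly] @ x[:, poly].T / c)

    def test_monomorphic_warns_and_excluded(self):
        x = np.column_stack([_column_with_freq(10, 0.3), np.full(10, 1.0)])
        with pytest.warns(UserWarning, match="monomorphic"):
            grm = compute_grm(_geno(x))
        assert grm.c == pytest.approx(2 * 0.3 * 0.7)

    def test_incomplete_rejected(self):
        x = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="complete"):
            compute_grm(_geno(x))


# ---------------------------------------------------------------------------
# REML fit + prediction
# ---------------------------------------------------------------------------


def _random_psd_grm(m, seed):
    rng = np.random.default_rng(seed)
    x = rng.choice([-1.0, 0.0, 1.0], size=(m, 200), p=[0.25, 0.5, 0.25])
    return compute_grm(_geno(x))


def _henderson_solve(y, Z, G, lam):
    """Mixed-model-equations oracle: direct linear solve for (mu, g)."""
    n, m = Z.shape
    ones = np.ones((n, 1))
    Ginv = np.linalg.inv(G + 1e-10 * np.eye(m))
    top = np.hstack([ones.T @ ones, ones.T @ Z])
    bottom = np.hstack([Z.T @ ones, Z.T @ Z + Ginv / lam])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([ones.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[0], sol[1:]


class TestFitGBLUP:
    def test_matches_henderson_equations(self):
        rng = np.random.default_rng(0)
        grm = _random_psd_grm(8, 0)
        L = np.linalg.cholesky(grm.G + 1e-8 * np.eye(8))
        g = L @ rng.standard_normal(8)
        Z = make_incidence([f"A{i}" for i in range(8)], grm.accession_ids)
        y = 2.0 + g + 0.5 * rng.standard_normal(8)
        fit = fit_gblup(y, Z, grm)
        lam = fit.sigma2_g / fit.sigma2_e
        mu_o, g_o = _henderson_solve(y, Z, grm.G, lam)
        assert fit.mu == pytest.approx(mu_o, abs=1e-8)
        np.testing.assert_allclose(fit.g_hat, g_o, atol=1e-8)

    def test_identity_grm_is_ridge_shrinkage(self):
        # G = I, one observation per accession: g_hat = lam/(1+lam) (y - mu)
        rng = np.random.default_rng(1)
        m = 40
        y = rng.standard_normal(m) * 2 + 1
        grm = GRM(G=np.eye(m), c=1.0, accession_ids=[f"A{i}" for i in range(m)],
                  allele_freq=np.array([0.5]))
        Z = np.eye(m)
        fit = fit_gblup(y, Z, grm)
        lam = fit.sigma2_g / fit.sigma2_e
        shrunk = fit.mu + lam / (1 + lam) * (y - fit.mu)
        np.testing.assert_allclose(fit.mu + fit.g_hat, shrunk, atol=1e-8)

    def test_noise_free_limit(self):
        # replicated plots with y = Zg exactly: identical replicates force
        # sigma2_e to the 0 boundary and mu + g_hat reproduces group means
        rng = np.random.default_rng(2)
        m = 15
        grm = _random_psd_grm(m, 2)
        L = np.linalg.cholesky(grm.G + 1e-8 * np.eye(m))
        g = L @ rng.standard_normal(m)
        accs = [f"A{i}" for i in range(m)] * 2  # two replicates each
        Z = make_incidence(accs, grm.accession_ids)
        y = 5.0 + Z @ g  # zero residual
        fit = fit_gblup(y, Z, grm)
        assert fit.h2 > 0.99
        assert fit.boundary
        np.testing.assert_allclose(fit.mu + fit.g_hat, 5.0 + g, atol=1e-3)

    def test_scale_invariance_of_predictions(self):
        rng = np.random.default_rng(3)
        grm = _random_psd_grm(20, 3)
        Z = make_incidence([f"A{i}" for i in range(20)], grm.accession_ids)
        L = np.linalg.cholesky(grm.G + 1e-8 * np.eye(20))
        # genuine genetic signal keeps the variance ratio off the boundary
        y = L @ rng.standard_normal(20) + 0.5 * rng.standard_normal(20)
        fit1 = fit_gblup(y, Z, grm)
        scaled = GRM(G=grm.G * 7.0, c=grm.c, accession_ids=grm.accession_ids,
                     allele_freq=grm.allele_freq)
        fit2 = fit_gblup(y, Z, scaled)
        # tolerance limited by the 1-D ratio search, not the algebra
        np.testing.assert_allclose(fit1.g_hat, fit2.g_hat, rtol=1e-3, atol=1e-4)
        assert fit2.sigma2_g * 7.0 == pytest.approx(fit1.sigma2_g, rel=1e-2)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            fit_gblup(np.zeros(3), np.eye(4), np.eye(4))

    def test_nonfinite_y(self):
        with pytest.raises(ValueError, match="finite"):
            fit_gblup(np.array([1.0, np.nan, 2.0]), np.eye(3), np.eye(3))


class TestPredictUnobserved:
    def test_duplicate_rows_predict_equally(self):
        rng = np.random.default_rng(0)
        x = rng.choice([-1.0, 0.0, 1.0], size=(6, 80))
        x[5] = x[0]  # accession 5 genetically identical to accession 0
        grm = compute_grm(_geno(x))
        y_train = rng.standard_normal(5)
        Z = make_incidence([f"A{i}" for i in range(5)], grm.accession_ids)
        fit = fit_gblup(y_train, Z, grm)
        pred = predict_unobserved(fit, np.array([0, 5]))
        assert pred[0] == pytest.approx(pred[1], abs=1e-8)

    def test_zero_genetic_variance_returns_mean(self):
        fit = fit_gblup(
            np.array([1.0, 1.1, 0.9, 1.0, 1.05, 0.95]),
            np.eye(6),
            np.eye(6) * 0.0 + np.eye(6),  # identity G, but y ~ constant
        )
        # predictions shrink almost entirely to the mean when sigma2_g ~ 0
        pred = predict_unobserved(fit, np.arange(6))
        assert np.abs(pred - fit.mu).max() <= np.abs(
            np.array([1.0, 1.1, 0.9, 1.0, 1.05, 0.95]) - fit.mu
        ).max()

    def test_conditional_mvn_matches_masked_refit(self):
        # two routes on an n = 6 instance: (a) fit with full G and targets
        # absent (package route); (b) explicit conditional-MVN formula
        rng = np.random.default_rng(1)
        grm = _random_psd_grm(6, 1)
        train = [0, 1, 2, 3]
        test = [4, 5]
        y = rng.standard_normal(4) + 1.0
        Z = make_incidence([f"A{i}" for i in train], grm.accession_ids)
        fit = fit_gblup(y, Z, grm)
        pred = predict_unobserved(fit, np.array(test))

        G = grm.G
        lam = fit.sigma2_g / fit.sigma2_e
        V = lam * G[np.ix_(train, train)] + np.eye(4)
        cond = fit.mu + lam * G[np.ix_(test, train)] @ np.linalg.solve(V, y - fit.mu)
        np.testing.assert_allclose(pred, cond, atol=1e-8)

    def test_target_outside_g_raises(self):
        fit = fit_gblup(np.array([1.0, 2.0, 3.0]), np.eye(3), np.eye(3))
        with pytest.raises(ValueError, match="outside"):
            predict_unobserved(fit, np.array([3]))


# ---------------------------------------------------------------------------
# cross-validated accuracy
# ---------------------------------------------------------------------------


def _simulated(h2, seed, n_acc=120):
    cfg = SyntheticFieldConfig(
        n_accessions=n_acc, n_reps=1, treatments=("control",), n_snps=600, n_qtl=30,
        heritability={t: h2 for t in TRAITS}, missing_rate=0.0, rng_seed=seed,
    )
    geno = simulate_genotypes(cfg)
    truth = simulate_traits(geno, cfg)
    grm = compute_grm(geno)
    return truth, grm


class TestCVGBLUP:
    def test_h2_one_high_accuracy(self):
        truth, grm = _simulated(1.0, 0)
        m = cv_gblup(
            truth.plot_traits["PH"].to_numpy(),
            truth.plots["accession"].to_numpy(),
            grm,
            CVScheme(k=5, repetitions=1, seed=0),
        )
        assert m["r"].mean() > 0.8

    def test_permuted_phenotypes_near_zero(self):
        rng = np.random.default_rng(1)
        truth, grm = _simulated(0.8, 1)
        y = truth.plot_traits["PH"].to_numpy()
        m = cv_gblup(
            rng.permutation(y),
            truth.plots["accession"].to_numpy(),
            grm,
            CVScheme(k=5, repetitions=2, seed=0),
        )
        assert abs(m["r"].mean()) < 0.15

    def test_accuracy_monotone_in_h2(self):
        means = []
        for h2 in (1.0, 0.5, 0.1):
            truth, grm = _simulated(h2, 7)
            m = cv_gblup(
                truth.plot_traits["DW"].to_numpy(),
                truth.plots["accession"].to_numpy(),
                grm,
                CVScheme(k=5, repetitions=2, seed=0),
            )
            means.append(m["r"].mean())
        assert means[0] > means[1] > means[2]

    def test_per_treatment_models(self):
        cfg = SyntheticFieldConfig(
            n_accessions=40, n_reps=2, n_snps=300, n_qtl=20, missing_rate=0.0, rng_seed=3
        )
        geno = simulate_genotypes(cfg)
        truth = simulate_traits(geno, cfg)
        grm = compute_grm(geno)
        m = cv_gblup(
            truth.plot_traits["PH"].to_numpy(),
            truth.plots["accession"].to_numpy(),
            grm,
            CVScheme(k=4, repetitions=1, seed=0),
            treatments=truth.plots["treatment"].to_numpy(),
        )
        assert set(m["treatment"]) == {"control", "drought"}
        s = summarize_cv(m)
        assert {"mean_r", "sd_r"} <= set(s.columns)

    def test_small_folds_skipped(self, caplog):
        truth, grm = _simulated(0.5, 4, n_acc=4)
        m = cv_gblup(
            truth.plot_traits["PH"].to_numpy(),
            truth.plots["accession"].to_numpy(),
            grm,
            CVScheme(k=2, repetitions=1, seed=0),
        )
        assert len(m) == 0  # every fold has < 3 held-out accessions

    def test_pc1_more_predictable_than_pc10_in_rank2_world(self):
        from lsphen.latent import fit_pca

        world = simulate_rank2_latent_world(n_accessions=120, n_snps=600, seed=5)
        X = world["features"]
        Xs = (X - X.mean(0)) / X.std(0, ddof=0)
        _, S = fit_pca(Xs)
        grm = compute_grm(world["geno"])
        accs = np.array(world["accession_ids"])
        scheme = CVScheme(k=5, repetitions=1, seed=1)
        r1 = cv_gblup(S[:, 0], accs, grm, scheme)["r"].mean()
        r10 = cv_gblup(S[:, 9], accs, grm, scheme)["r"].mean()
        assert r1 > r10 + 0.2
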