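"""PLS1 engine against closed-form, OLS and scikit-learn oracles."""

import numpy as np
import pytest

from mirdmi.features import fa_to_fat_proportion
from mirdmi.pls import (
    factors_for_variance,
    pls_fit,
    pls_predict,
    project_to_factors,
    vip_scores,
    vip_select,
)
from mirdmi.records import fa_slug, spectral_matrix
from mirdmi.synthetic import (
    FA_PANEL,
    SIGNAL_FAS,
    GeneratorConfig,
    generate_population,
)


@pytest.fixture(scope="module")
def random_fit():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 12))
    y = X @ rng.normal(size=12) + 0.5 * rng.normal(size=40)
    return X, y, pls_fit(X, y, A=6)


class TestAgainstOracles:
    def test_single_column_equals_ls_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(25, 1))
        y = 2.5 * x.ravel() + rng.normal(size=25)
        fit = pls_fit(x, y, A=1)
        slope = np.cov(x.ravel(), y)[0, 1] / np.var(x.ravel(), ddof=1)
        beta, intercept = fit.coefficients(1)
        assert beta[0] == pytest.approx(slope, abs=1e-12)
        assert intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-12)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        fit = pls_fit(X, y, A=5)
        Xd = np.column_stack([np.ones(30), X])
        ols = Xd @ np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(pls_predict(fit, X), ols, atol=1e-8)

    def test_matches_sklearn_plsregression(self, random_fit):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y, fit = random_fit
        for a in (1, 3, 6):
            sk = sklearn.PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(fit.coefficients(a)[0],
                                       sk.coef_.ravel(), atol=1e-10)

    def test_constant_y_gives_intercept_model(self):
        X = np.random.default_rng(2).normal(size=(20, 4))
        fit = pls_fit(X, np.full(20, 7.0), A=3)
        assert fit.n_factors == 0
        np.testing.assert_allclose(pls_predict(fit, X), 7.0)


class TestAlgebraicProperties:
    def test_training_rss_monotone_in_factor_count(self, random_fit):
        X, y, fit = random_fit
        rss = [np.sum((y - pls_predict(fit, X, a)) ** 2)
               for a in range(1, fit.n_factors + 1)]
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))

    def test_scale_equivariance(self, random_fit):
        X, y, fit = random_fit
        fit3 = pls_fit(X, 3.0 * y, A=6)
        np.testing.assert_allclose(fit3.coefficients(4)[0],
                                   3.0 * fit.coefficients(4)[0], atol=1e-10)

    def test_prediction_at_column_means_is_y_mean(self, random_fit):
        X, y, fit = random_fit
        for a in (1, 3, 6):
            assert pls_predict(fit, X.mean(axis=0)[None, :], a)[0] == \
                pytest.approx(y.mean(), abs=1e-10)

    def test_factor_counts_differ_unless_rank_one(self, random_fit):
        X, y, fit = random_fit
        assert not np.allclose(pls_predict(fit, X, 1), pls_predict(fit, X, 6))

    def test_errors(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            pls_fit(X, rng.normal(size=10), A=4)  # A > p
        with pytest.raises(ValueError):
            pls_fit(np.ones((10, 3)), rng.normal(size=10), A=2)


class TestVIP:
    def test_p_equals_one_gives_vip_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 1))
        fit = pls_fit(x, x.ravel() * 2 + rng.normal(size=30), A=1)
        assert vip_scores(fit, 1)[0] == pytest.approx(1.0, abs=1e-12)
        assert vip_select(fit, 1) == []  # strict inequality at the boundary

    def test_normalization_identity(self, random_fit):
        _, _, fit = random_fit
        for a in (1, 3, 6):
            v = vip_scores(fit, a)
            assert v @ v == pytest.approx(12, abs=1e-8)

    def test_duplicate_predictors_share_vip_noise_below_one(self):
        rng = np.random.default_rng(6)
        signal = rng.normal(size=200)
        X = np.column_stack([signal, signal, rng.normal(size=200)])
        y = 2 * signal + 0.3 * rng.normal(size=200)
        fit = pls_fit(X, y, A=2)
        v = vip_scores(fit, 2)
        assert v[0] == pytest.approx(v[1], rel=1e-9)
        assert v[2] < 1.0 < v[0]

    def test_threshold_zero_selects_all(self, random_fit):
        _, _, fit = random_fit
        assert len(vip_select(fit, 3, threshold=0.0)) == 12

    def test_signal_fa_panel_recovered(self):
        # the VIP > 1 screening of the MIR-predicted fatty acids, run on a
        # pooled all-country cohort, recovers the six FAs that carry signal
        hits = 0
        for seed in range(10):
            rec, _ = generate_population(
                GeneratorConfig(seed=seed, n_cows_per_country=100))
            X = np.column_stack([
                fa_to_fat_proportion(rec[fa_slug(n)], rec["pfat"])
                for n in FA_PANEL])
            fit = pls_fit(X, rec["dmi"].to_numpy(), A=10)
            fit.columns = list(FA_PANEL)
            if set(vip_select(fit)) == set(SIGNAL_FAS):
                hits += 1
        assert hits >= 9


@pytest.fixture(scope="module")
def spectra_fit(cleaned_small):
    clean, _, _ = cleaned_small
    X = spectral_matrix(clean)
    y = clean["dmi"].to_numpy()
    return X, pls_fit(X, y, A=20)


class TestFactorProjection:
    def test_rank_one_needs_one_factor(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=50)
        X = np.outer(t, rng.normal(size=8))
        fit = pls_fit(X, t + 0.1 * rng.normal(size=50), A=1)
        assert factors_for_variance(fit, 0.999) == 1

    def test_orthogonal_variance_bookkeeping(self):
        rng = np.random.default_rng(8)
        n = 400
        Z = rng.normal(size=(n, 3)) * np.array([3.0, np.sqrt(0.5), np.sqrt(0.5)])
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        X = Z @ Q
        y = Z[:, 0] + 0.05 * rng.normal(size=n)
        fit = pls_fit(X, y, A=3)
        assert factors_for_variance(fit, 0.85) == 1

    def test_unreachable_fraction_raises(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 10))
        fit = pls_fit(X, rng.normal(size=30), A=2)
        with pytest.raises(ValueError):
            factors_for_variance(fit, 0.999)

    def test_mean_spectrum_projects_to_zero(self, spectra_fit):
        X, fit = spectra_fit
        scores = project_to_factors(fit, X.mean(axis=0)[None, :], F=3)
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_projection_explains_spectral_variance(self, spectra_fit):
        X, fit = spectra_fit
        F = factors_for_variance(fit, 0.99)
        T = project_to_factors(fit, X, F)
        Xc = X - X.mean(axis=0)
        recon = T @ np.linalg.lstsq(T, Xc, rcond=None)[0]
        explained = 1 - np.sum((Xc - recon) ** 2) / np.sum(Xc**2)
        assert explained >= 0.99
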