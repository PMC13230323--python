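"""Linear genomic-prediction engines and the pluggable predictor interface."""

import numpy as np
import pytest

from flaxgs import simpop
from flaxgs.markerrep import snp_markers
from flaxgs.predict import (
    BayesianRidge,
    GBLUP,
    PredictError,
    RRBLUP,
    RegularizedRegression,
    StackingEnsemble,
    fit_gblup,
    fit_rrblup,
    make_model,
    predict_new,
    register_model,
)


def sim_xy(n=120, p=400, h2=0.8, seed=0, n_qtl=80):
    panel = simpop.simulate_founders(n, p, seed=seed)
    pop = simpop.population_from_panel(panel)
    trait = simpop.assign_trait(pop, min(n_qtl, panel.n_loci), h2=h2, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    y = pop.true_bv + rng.normal(0, np.sqrt(trait.sigma_e2), n)
    return pop.genotypes.dosage, y, pop


class TestRRBLUP:
    def test_one_marker_closed_form(self):
        # u = Z'y / (Z'Z + lambda) with centered single marker
        fit = RRBLUP(lambda_=1.0).fit(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]))
        assert fit.mu_ == pytest.approx(0.0, abs=1e-10)
        assert fit.u_[0] == pytest.approx(2 / 3, abs=1e-10)
        np.testing.assert_allclose(fit.train_gebv_, [2 / 3, -2 / 3], atol=1e-10)

    def test_noise_free_signal_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 1))
        y = 3.0 * x[:, 0] + 1.0
        fit = fit_rrblup(np.column_stack([x, rng.normal(size=(50, 3))]), y)
        r = np.corrcoef(fit.train_gebv_, y)[0, 1]
        assert r > 0.999

    def test_infinite_shrinkage_returns_mean(self):
        X, y, _ = sim_xy(60, 100, seed=2)
        fit = RRBLUP(lambda_=1e12).fit(X, y)
        np.testing.assert_allclose(fit.predict(X).gebv, np.mean(y), atol=1e-6)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(PredictError):
            fit_rrblup(np.eye(5), np.ones(5))

    def test_translation_and_scale_equivariance(self):
        X, y, _ = sim_xy(80, 150, seed=3)
        g0 = fit_rrblup(X, y).predict(X).gebv
        g1 = fit_rrblup(X, y + 7.0).predict(X).gebv
        np.testing.assert_allclose(g1, g0 + 7.0, atol=1e-5)
        g2 = fit_rrblup(X, y * 3.0).predict(X).gebv
        np.testing.assert_allclose(
            g2 - g2.mean(), 3.0 * (g0 - g0.mean()), atol=1e-5
        )


class TestGBLUP:
    @pytest.mark.parametrize("seed", range(5))
    def test_equivalent_to_rrblup(self, seed):
        X, y, _ = sim_xy(80, 300, seed=10 + seed)
        g_rr = fit_rrblup(X, y).predict(X).gebv
        g_gb = fit_gblup(X, y).predict(X).gebv
        scale = np.std(g_rr)
        np.testing.assert_allclose(g_gb / scale, g_rr / scale, atol=1e-6)

    def test_duplicate_samples_identical_gebv(self):
        X, y, _ = sim_xy(40, 100, seed=20)
        X2 = np.vstack([X, X[:1]])
        y2 = np.append(y, y[0])
        fit = fit_gblup(X2, y2)
        pred = fit.predict(X2).gebv
        assert pred[0] == pytest.approx(pred[-1], abs=1e-8)

    def test_g_diagonal_reflects_inbreeding(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.1, 0.5, 500)
        # Hardy-Weinberg panel: diag(G) ~ 1
        X_hwe = rng.binomial(2, p, size=(100, 500)).astype(float)
        fit = fit_gblup(X_hwe, rng.normal(size=100))
        assert np.mean(np.diag(fit.G_)) == pytest.approx(1.0, abs=0.1)
        # fully inbred panel: diag(G) ~ 1 + F = 2
        X_inbred, _, _ = sim_xy(100, 500, seed=22)
        fit2 = fit_gblup(X_inbred, rng.normal(size=100))
        assert np.mean(np.diag(fit2.G_)) == pytest.approx(2.0, abs=0.2)


class TestRegularized:
    def test_ridge_limit_matches_ols(self):
        rng = np.random.default_rng(30)
        X = rng.normal(size=(60, 5))
        beta = rng.normal(size=5)
        y = X @ beta + 0.01 * rng.normal(size=60)
        fit = RegularizedRegression(alpha=0.0, lambda_grid=[1e-10]).fit(X, y)
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(60), X]), y, rcond=None
        )[0]
        np.testing.assert_allclose(fit.u_, ols[1:], atol=1e-4)

    def test_lasso_saturation_zeroes_all(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        fit = RegularizedRegression(alpha=1.0, lambda_grid=[1e6]).fit(X, y)
        np.testing.assert_array_equal(fit.u_, 0.0)

    def test_ridge_splits_duplicated_features(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=50)
        y = 2.0 * x + 0.1 * rng.normal(size=50)
        X = np.column_stack([x, x])
        fit = RegularizedRegression(alpha=0.0, lambda_grid=[0.1]).fit(X, y)
        assert fit.u_[0] == pytest.approx(fit.u_[1], rel=1e-6)


class TestBayesianRidge:
    def test_fixed_variances_match_ridge(self):
        rng = np.random.default_rng(40)
        X = rng.normal(size=(80, 10))
        X = (X - X.mean(0)) / X.std(0)
        beta = rng.normal(size=10) * 0.5
        y = X @ beta + rng.normal(size=80) * 0.5
        su2, se2 = 0.25, 0.25
        lam = se2 / su2
        brr = BayesianRidge(
            iters=3000, burn_in=1000, seed=1, fix_variances=(su2, se2)
        ).fit(X, y)
        Xc = X - X.mean(0)
        ridge = np.linalg.solve(
            Xc.T @ Xc + lam * np.eye(10), Xc.T @ (y - y.mean())
        )
        np.testing.assert_allclose(brr.u_, ridge, atol=0.02)

    def test_seeded_determinism(self):
        X, y, _ = sim_xy(40, 60, seed=41)
        a = BayesianRidge(iters=300, burn_in=100, seed=7).fit(X, y)
        b = BayesianRidge(iters=300, burn_in=100, seed=7).fit(X, y)
        np.testing.assert_array_equal(a.u_, b.u_)

    def test_permuted_response_shrinks_effects(self):
        # posterior-mean effects collapse under a permuted h2=0.8 response
        ratios = []
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            X = rng.binomial(2, 0.3, size=(600, 30)).astype(float)
            g = X @ rng.normal(size=30)
            g -= g.mean()
            y = g + rng.normal(0, np.sqrt(g.var() * 0.25), 600)
            fit = BayesianRidge(iters=800, burn_in=300, seed=1).fit(X, y)
            null = BayesianRidge(iters=800, burn_in=300, seed=1).fit(
                X, rng.permutation(y)
            )
            ratios.append(np.mean(np.abs(fit.u_)) / np.mean(np.abs(null.u_)))
        assert np.mean(ratios) > 5


class TestStacking:
    def test_weight_concentrates_on_informative_base(self):
        class PureNoise(RRBLUP):
            """Base whose predictions carry no phenotype signal."""

            def __init__(self, seed):
                self._rng_seed = seed

            def fit(self, Xf, yf):
                self.feature_names = [f"f{j}" for j in range(Xf.shape[1])]
                return self

            def predict(self, Xf):
                rng = np.random.default_rng([self._rng_seed, Xf.shape[0]])
                from flaxgs.predict import PredictionResult

                return PredictionResult(
                    gebv=rng.normal(size=len(Xf)), model_kind="noise"
                )

        weights, pa_gap = [], []
        for seed in range(10):
            rng = np.random.default_rng(50 + seed)
            X = rng.normal(size=(100, 30))
            y = X @ rng.normal(size=30)  # noise-free: linear base is perfect
            st = StackingEnsemble(
                base_factories=[
                    lambda: RRBLUP(),
                    lambda s=seed: PureNoise(s),
                    lambda s=seed: PureNoise(s + 1000),
                ],
                seed=seed,
            ).fit(X, y)
            w = st.weights_ / max(st.weights_.sum(), 1e-12)
            weights.append(w[0])
            base_pa = np.corrcoef(RRBLUP().fit(X, y).predict(X).gebv, y)[0, 1]
            st_pa = np.corrcoef(st.predict(X).gebv, y)[0, 1]
            pa_gap.append(base_pa - st_pa)
        assert np.mean(weights) >= 0.9
        assert np.mean(pa_gap) < 0.02

    def test_duplicating_a_base_leaves_predictions_unchanged(self):
        X, y, _ = sim_xy(60, 100, seed=70)
        dup = StackingEnsemble(
            base_factories=[lambda: RRBLUP(), lambda: RRBLUP()], seed=1
        ).fit(X, y)
        single = StackingEnsemble(base_factories=[lambda: RRBLUP()], seed=1).fit(
            X, y
        )
        np.testing.assert_allclose(
            dup.predict(X).gebv, single.predict(X).gebv, atol=1e-6
        )
        # and the duplicated ensemble is a faithful (affine) image of the base
        base = RRBLUP().fit(X, y).predict(X).gebv
        assert np.corrcoef(dup.predict(X).gebv, base)[0, 1] > 1 - 1e-9

    def test_meta_fit_not_worse_than_best_base(self):
        X, y, _ = sim_xy(80, 120, seed=71)
        st = StackingEnsemble(seed=2).fit(X, y)
        train_mse = np.mean((st.predict(X).gebv - y) ** 2)
        assert train_mse <= st.oof_mse_.min() + 1e-8


class TestPredictNew:
    def test_training_matrix_reproduces_gebvs(self):
        X, y, _ = sim_xy(50, 80, seed=80)
        fit = fit_rrblup(X, y)
        np.testing.assert_allclose(
            predict_new(fit, X).gebv, fit.train_gebv_, atol=1e-10
        )

    def test_copied_row_gets_same_gebv(self):
        X, y, _ = sim_xy(50, 80, seed=81)
        fit = fit_gblup(X, y)
        single = predict_new(fit, X[3:4]).gebv[0]
        assert single == pytest.approx(predict_new(fit, X).gebv[3], abs=1e-10)

    def test_feature_identity_enforced_by_name(self, founder_panel):
        gm = founder_panel.to_genotype_matrix()
        ms = snp_markers(gm)
        y = np.random.default_rng(0).normal(size=gm.n_samples)
        fit = fit_rrblup(ms, y)
        wrong = snp_markers(gm.take_loci(np.arange(gm.n_loci - 1)))
        with pytest.raises(PredictError, match="feature mismatch"):
            predict_new(fit, wrong)

    def test_registry_and_custom_model(self):
        register_model("custom_mean", lambda: RRBLUP(lambda_=1e12))
        model = make_model("custom_mean")
        assert isinstance(model, RRBLUP)
        with pytest.raises(PredictError):
            make_model("no_such_model")


class TestNullBehaviour:
    def test_permutation_pa_centered_on_zero(self):
        X, y, _ = sim_xy(100, 200, h2=0.8, seed=90)
        rng = np.random.default_rng(91)
        pas = []
        for _ in range(25):
            yp = rng.permutation(y)
            fit = fit_rrblup(X[:70], yp[:70])
            pas.append(np.corrcoef(fit.predict(X[70:]).gebv, yp[70:])[0, 1])
        assert abs(np.mean(pas)) < 0.08
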