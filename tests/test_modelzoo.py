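import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers_oracles import sandwich_hc0
from slabspline.exceptions import (
    CollinearityError,
    InsufficientDataError,
    InvalidSpecError,
)
from slabspline.modelzoo import (
    ModelSpec,
    build_design,
    catalog_models,
    fit_model,
    fit_ols,
    robust_covariance,
)
from slabspline.simgen import draw_sample, scenario_config


def spec(n):
    return next(s for s in catalog_models() if s.strategy_id == n)


def semicontinuous_doses(rng, n, p_zero=0.25, scale=2.0):
    """Doses with a point mass at zero, as spike designs require."""
    x = scale * rng.random(n)
    x[rng.random(n) < p_zero] = 0.0
    return x


class TestCatalog:
    def test_nine_strategies(self):
        models = catalog_models()
        assert len(models) == 9
        assert [m.strategy_id for m in models] == list(range(1, 10))

    def test_strategy_details(self):
        models = {m.strategy_id: m for m in catalog_models()}
        assert not models[1].include_spike and models[1].exposure_form == "linear"
        assert models[2].include_spike and models[2].exposure_form == "linear"
        assert models[3].exposure_form == "quadratic" and models[3].include_spike
        assert models[4].breaks == (1 / 3, 2 / 3)
        assert models[5].knots.knots == (1 / 8, 1 / 2, 7 / 8) and not models[5].include_spike
        assert models[6].knots.knots == (1 / 8, 1 / 2, 7 / 8) and models[6].include_spike
        assert models[7].knots.knots == (1 / 3, 1 / 2, 2 / 3)
        # slab runs from dose 0+ up to the lower boundary knot; the spike
        # keeps the zero-dose group's own intercept
        assert models[8].exposure_form == "slab_spline"
        assert models[8].include_spike
        assert models[8].knots.lower_boundary == pytest.approx(7 / 16)
        assert models[9].exclude_zero_dose
        assert models[9].reference_rule == "minimum_observed_positive"
        assert sum(m.exclude_zero_dose for m in models.values()) == 1

    def test_knot_scale(self):
        m6 = next(s for s in catalog_models(knot_scale=2.0) if s.strategy_id == 6)
        assert m6.knots.knots == (2 / 8, 1.0, 7 / 4)

    def test_invalid_spec_combinations(self):
        with pytest.raises(InvalidSpecError):
            ModelSpec(99, "bad", "categorical", include_spike=True, breaks=(0.5,))
        with pytest.raises(InvalidSpecError):
            ModelSpec(99, "bad", "ncs")


class TestBuildDesign:
    def test_linear_spike_rows(self):
        d = build_design(spec(2), np.array([0.0, 1.0]))
        np.testing.assert_allclose(d.matrix, [[1, 0, 0], [1, 1, 1]])
        assert d.labels == ["intercept", "spike", "dose"]

    def test_categorical_zero_dose_is_reference(self):
        d = build_design(spec(4), np.array([0.0, 0.2, 0.5, 0.9]))
        assert list(d.matrix[0]) == [1, 0, 0, 0]  # only intercept active at dose 0

    def test_zero_exclusion_mask(self):
        x = np.array([0.0, 0.2, 0.0, 0.5, 0.9, 0.3, 0.7, 0.15])
        d = build_design(spec(9), x)
        np.testing.assert_array_equal(d.row_mask, x > 0)
        assert d.n_obs == 6

    def test_empty_category_dropped_and_reported(self):
        x = np.array([0.0, 0.1, 0.2, 0.25, 0.3, 0.15, 0.05, 0.9, 0.8, 0.95])
        d = build_design(spec(4), x)  # middle category (1/3, 2/3] unoccupied
        assert "cat2" in d.dropped_levels
        assert "cat2" not in d.labels
        assert d.category_counts["cat2"] == 0

    def test_all_zero_doses_flag_collinearity(self):
        with pytest.raises(CollinearityError) as err:
            build_design(spec(2), np.zeros(20))
        assert "spike" in str(err.value) or "dose" in str(err.value)

    def test_covariates_appended_last(self):
        import pandas as pd

        cov = pd.DataFrame({"age": np.arange(4.0), "parity": np.ones(4)})
        d = build_design(spec(2), np.array([0.0, 0.5, 1.0, 0.2]), covariates=cov)
        assert d.labels[-2:] == ["age", "parity"]


class TestFitOls:
    def test_noiseless_recovery(self, rng):
        d = build_design(spec(3), semicontinuous_doses(rng, 50))
        beta = np.array([10.0, 0.5, -2.4, 4.8])
        fit = fit_ols(d, d.matrix @ beta)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        from slabspline.modelzoo import Design

        d = Design(X, ["a", "b", "c"], np.ones(20, dtype=bool))
        fit = fit_ols(d, y)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-8)
        # residuals orthogonal to design columns
        assert np.max(np.abs(X.T @ fit.residuals)) / 20 < 1e-8

    def test_insufficient_data(self, rng):
        d = build_design(spec(3), np.array([0.0, 0.5, 1.0, 0.7]))
        with pytest.raises(InsufficientDataError):
            fit_ols(d, np.zeros(4))

    def test_spike_separability(self, rng):
        """With an anchored spike model, zero-dose rows are intercept-only:
        the fitted value at x=0 is the zero-group outcome mean and the
        positive-dose coefficients equal a positive-rows-only fit."""
        cfg = scenario_config(1, True, N=800, seed=5)
        s = draw_sample(cfg, rng)
        for sid in (2, 3, 6, 7):
            fit = fit_model(spec(sid), s.doses, s.outcomes)
            zero_mean = s.outcomes[s.doses == 0].mean()
            assert fit.coef("intercept") == pytest.approx(zero_mean, abs=1e-10)
            # positive-dose submodel: drop spike, fit positive rows alone
            pos = s.doses > 0
            sub = ModelSpec(
                90 + sid,
                "sub",
                spec(sid).exposure_form,
                include_spike=False,
                knots=spec(sid).knots,
            )
            d = build_design(sub, s.doses[pos])
            sub_fit = fit_ols(d, s.outcomes[pos])
            full_labels = fit.design_labels
            sub_beta = dict(zip(sub_fit.design_labels, sub_fit.coefficients))
            for lab in full_labels:
                if lab in ("intercept", "spike"):
                    continue
                assert fit.coef(lab) == pytest.approx(sub_beta[lab], abs=1e-8)
            # user-group intercept = intercept + spike
            assert fit.coef("intercept") + fit.coef("spike") == pytest.approx(
                sub_beta["intercept"], abs=1e-8
            )


class TestRobustCovariance:
    @given(st.integers(0, 10_000))
    def test_hc0_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        p = int(rng.integers(2, 5))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n) * (1 + rng.random(n))
        from slabspline.modelzoo import Design

        d = Design(X, [f"c{j}" for j in range(p)], np.ones(n, dtype=bool))
        fit = fit_ols(d, y)
        V = robust_covariance(fit, d, kind="HC0")
        np.testing.assert_allclose(V, sandwich_hc0(X, fit.residuals), atol=1e-10)

    def test_hc1_is_scaled_hc0(self, rng):
        d = build_design(spec(2), semicontinuous_doses(rng, 60))
        y = rng.normal(size=60)
        fit = fit_ols(d, y)
        v0 = robust_covariance(fit, d, kind="HC0")
        v1 = robust_covariance(fit, d, kind="HC1")
        np.testing.assert_allclose(v1, v0 * 60 / (60 - 3), rtol=1e-12)

    def test_singleton_clusters_equal_hc0(self, rng):
        d = build_design(spec(2), semicontinuous_doses(rng, 30))
        y = rng.normal(size=30)
        fit = fit_ols(d, y)
        v_plain = robust_covariance(fit, d, kind="HC0")
        v_clust = robust_covariance(fit, d, cluster_ids=np.arange(30), kind="HC0")
        np.testing.assert_allclose(v_clust, v_plain, atol=1e-14)

    def test_homoskedastic_sanity_band(self, rng):
        """Under homoskedastic errors the sandwich agrees with classical OLS
        standard errors to within sampling noise."""
        x = semicontinuous_doses(rng, 1000)
        d = build_design(spec(2), x)
        y = d.matrix @ np.array([1.0, 0.5, -1.0]) + rng.normal(0, 1, 1000)
        fit = fit_ols(d, y)
        V = robust_covariance(fit, d, kind="HC1")
        classical = fit.sigma_hat**2 * np.linalg.inv(d.matrix.T @ d.matrix)
        ratio = np.sqrt(np.diag(V)) / np.sqrt(np.diag(classical))
        assert np.all(np.abs(ratio - 1) < 0.15)

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        cfg = scenario_config(1, True, N=300, seed=9)
        s = draw_sample(cfg, rng)
        clusters = rng.integers(0, 60, size=300)
        d = build_design(spec(3), s.doses)
        fit = fit_ols(d, s.outcomes)

        res = sm.OLS(s.outcomes, d.matrix).fit()
        np.testing.assert_allclose(fit.coefficients, res.params, atol=1e-10)
        v1 = robust_covariance(fit, d, kind="HC1")
        np.testing.assert_allclose(v1, res.cov_HC1, rtol=1e-8, atol=1e-12)

        res_cl = sm.OLS(s.outcomes, d.matrix).fit(
            cov_type="cluster", cov_kwds={"groups": clusters}
        )
        v_cl = robust_covariance(fit, d, cluster_ids=clusters, kind="HC1")
        np.testing.assert_allclose(v_cl, res_cl.cov_params(), rtol=1e-8)
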