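"""Geographically weighted regression: kernels, local WLS, diagnostics,
model comparison and relative importance."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import climniche as cn
from climniche import gwr
from climniche.exceptions import (
    ConfigurationError,
    DegenerateInputError,
    DomainError,
)


class TestKernels:
    @pytest.mark.parametrize("d,b,expected", [
        (0.0, 2.0, 1.0), (2.0, 2.0, 0.0), (1.0, 2.0, 0.5625)])
    def test_bisquare_values(self, d, b, expected):
        assert cn.bisquare_weight(d, b) == expected

    def test_bisquare_rejects_bad_bandwidth(self):
        with pytest.raises(DomainError):
            cn.bisquare_weight(1.0, 0.0)

    @given(st.floats(0.01, 10), st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bisquare_decreasing_and_bounded(self, d, b):
        w = cn.bisquare_weight(d, b)
        assert 0 <= w <= 1
        assert cn.bisquare_weight(d * 1.01, b) <= w

    def test_kernel_spec_validation(self):
        with pytest.raises(ConfigurationError):
            cn.KernelSpec(fraction=0.0)
        with pytest.raises(ConfigurationError):
            cn.KernelSpec(fraction=0.5, fallback_fractions=(0.4,))
        with pytest.raises(ConfigurationError):
            cn.KernelSpec(kind="gaussian")


class TestAdaptiveBandwidth:
    def test_collinear_hand_enumeration(self):
        coords = np.column_stack([np.arange(11.0), np.zeros(11)])
        # k = ceil(0.3 * 10) = 3; third-nearest from x=0 is x=3
        assert cn.adaptive_bandwidth(coords, 0, 0.3) == 3.0

    def test_fraction_one_reaches_farthest(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5)])
        assert cn.adaptive_bandwidth(coords, 0, 1.0) == 4.0

    def test_two_points(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert cn.adaptive_bandwidth(coords, 0, 0.5) == 5.0


class TestLocalFit:
    def test_unit_weights_match_statsmodels_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        beta, _ = gwr.local_fit(X, y, np.ones(30))
        ref = sm.OLS(y, X).fit().params
        np.testing.assert_allclose(beta, ref, atol=1e-10)

    def test_exact_linear_response(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        truth = np.array([1.0, -2.0, 0.5])
        w = rng.uniform(0.1, 1.0, 20)
        beta, _ = gwr.local_fit(X, X @ truth, w)
        np.testing.assert_allclose(beta, truth, atol=1e-10)

    def test_random_systems_match_sqrt_weight_oracle(self):
        """The normal-equations solution agrees with an independent
        least-squares solve of sqrt(W) X b ~ sqrt(W) y."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
            y = rng.normal(size=12)
            w = rng.uniform(0.05, 1.0, 12)
            beta, _ = gwr.local_fit(X, y, w)
            sw = np.sqrt(w)
            oracle, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            np.testing.assert_allclose(beta, oracle, atol=1e-8)

    def test_weighted_residual_orthogonality(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        w = rng.uniform(0, 1, 40)
        beta, _ = gwr.local_fit(X, y, w)
        grad = X.T @ (w * (y - X @ beta))
        np.testing.assert_allclose(grad, 0, atol=1e-8)

    def test_collinear_design_raises_with_location(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(gwr.CollinearityError) as e:
            gwr.local_fit(X, np.zeros(10), np.ones(10), location=7)
        assert e.value.location == 7


class TestFitGwr:
    def _random_case(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10, (n, 2))
        X = rng.normal(size=(n, 3))
        y = 0.5 + X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.3, n)
        return X, y, coords

    def test_uniform_fraction_one_equals_ols(self):
        import statsmodels.api as sm
        X, y, coords = self._random_case()
        fit = cn.fit_gwr(X, y, coords,
                         cn.KernelSpec(kind="uniform", fraction=1.0,
                                       fallback_fractions=()))
        ref = sm.OLS(y, sm.add_constant(X)).fit().params
        np.testing.assert_allclose(fit.coef - ref[None, :], 0, atol=1e-8)

    def test_noiseless_constant_coefficients_recovered(self):
        rng = np.random.default_rng(5)
        n = 80
        coords = rng.uniform(0, 10, (n, 2))
        X = rng.normal(size=(n, 2))
        truth = np.array([0.3, 1.5, -0.7])
        y = truth[0] + X @ truth[1:]
        fit = cn.fit_gwr(X, y, coords, cn.KernelSpec(fraction=0.3))
        np.testing.assert_allclose(fit.coef, np.tile(truth, (n, 1)),
                                   atol=1e-6)

    def test_deterministic(self):
        X, y, coords = self._random_case(seed=9)
        a = cn.fit_gwr(X, y, coords)
        b = cn.fit_gwr(X, y, coords)
        np.testing.assert_array_equal(a.coef, b.coef)
        assert a.aicc == b.aicc

    def test_hat_diagonal_in_unit_interval(self, gradient_fit):
        _, _, fit = gradient_fit
        assert (fit.hat_diag >= 0).all() and (fit.hat_diag <= 1).all()

    def test_enp_between_p_and_n_and_shrinks_with_fraction(self):
        X, y, coords = self._random_case(n=100, seed=7)
        enps = []
        for frac in (0.2, 0.5, 1.0):
            fit = cn.fit_gwr(X, y, coords,
                             cn.KernelSpec(fraction=frac,
                                           fallback_fractions=()))
            enps.append(fit.enp)
            assert 4 <= fit.enp <= 100
        assert enps[0] > enps[1] > enps[2]

    def test_gradient_surface_recovery(self, gradient_fit):
        b, _, fit = gradient_fit
        for j, name in enumerate(b.truth.true_beta.columns):
            r = np.corrcoef(fit.coef[:, j + 1],
                            b.truth.true_beta[name].to_numpy())[0, 1]
            assert r >= 0.9


class TestStandardizeDesign:
    def _table(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        data = {name: rng.normal(size=n) for name in cn.ALL_PREDICTORS}
        data["lambda"] = rng.normal(size=n)
        return pd.DataFrame(data)

    def test_columns_are_zscored(self):
        X, y, _ = cn.standardize_design(self._table())
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1, atol=1e-12)
        assert abs(y.mean()) < 1e-12

    def test_raw_coefficient_round_trip(self):
        t = self._table(seed=3)
        X, y, rec = cn.standardize_design(t)
        beta_std, _ = gwr.local_fit(
            np.column_stack([np.ones(len(y)), X]), y, np.ones(len(y)))
        beta_raw = rec.raw_coefficients(beta_std)
        Xraw = np.column_stack([np.ones(len(t)),
                                t[list(cn.ALL_PREDICTORS)].to_numpy()])
        ref, _ = gwr.local_fit(Xraw, t["lambda"].to_numpy(),
                               np.ones(len(t)))
        np.testing.assert_allclose(beta_raw, ref, atol=1e-10)

    def test_constant_predictor_rejected(self):
        t = self._table()
        t["annual_temp"] = 5.0
        with pytest.raises(DegenerateInputError, match="annual_temp"):
            cn.standardize_design(t)


class TestInformationCriteria:
    def test_ols_enp_is_parameter_count(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        H_diag = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
        assert gwr.effective_parameters(H_diag) == pytest.approx(4, abs=1e-8)

    def test_identity_hat(self):
        assert gwr.effective_parameters(np.ones(17)) == 17

    def test_aicc_drop_for_halved_rss(self):
        n = 100
        a = cn.gwr_aicc(10.0, n, 5.0)
        b = cn.gwr_aicc(5.0, n, 5.0)
        assert a - b == pytest.approx(n * math.log(2), abs=1e-10)

    def test_aicc_penalty_increases_with_enp(self):
        assert cn.gwr_aicc(10.0, 100, 20.0) > cn.gwr_aicc(10.0, 100, 5.0)

    def test_aicc_domain(self):
        with pytest.raises(DomainError):
            cn.gwr_aicc(10.0, 10, 8.5)

    @pytest.mark.parametrize("deltas,expected", [
        ((0.0, 0.0), (0.5, 0.5)),
        ((0.0, 10.0), (0.99331, 0.00669)),
        ((0.0, 200.0), (1.0, 0.0)),
    ])
    def test_akaike_weights(self, deltas, expected):
        w = cn.akaike_weights(np.array(deltas) + 123.4)
        np.testing.assert_allclose(w, expected, atol=1e-4)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestRelativeImportance:
    def test_dominant_predictor_takes_all(self):
        df = pd.DataFrame({"a": [3.0, -4.0], "b": [0.1, 0.2]})
        imp = cn.relative_importance(df, {"a": "climatic", "b": "non-climatic"})
        assert imp.proportions == {"a": Fraction(1), "b": Fraction(0)}

    def test_hand_count_and_exact_sum(self):
        df = pd.DataFrame({"annual_temp": [2.0, 0.1],
                           "income_z": [0.5, -1.0]})
        imp = cn.relative_importance(df)
        assert imp.proportions["annual_temp"] == Fraction(1, 2)
        assert imp.proportions["income_z"] == Fraction(1, 2)
        assert sum(imp.proportions.values()) == 1
        assert sum(imp.group_proportions.values()) == 1

    def test_tie_goes_to_first_column_and_is_counted(self):
        df = pd.DataFrame({"a": [1.0], "b": [-1.0]})
        imp = cn.relative_importance(df, {"a": "g", "b": "g"})
        assert imp.counts == {"a": 1, "b": 0}
        assert imp.n_ties == 1


class TestCompareModels:
    def test_varying_climate_effects_select_full_gwr(self,
                                                     model_selection_case):
        _, _, comp = model_selection_case
        w = comp.table.set_index("model")["akaike_weight"]
        assert w["GWR_C+NC"] > 0.99
        assert comp.best() == "GWR_C+NC"

    def test_pure_noise_does_not_crown_gwr(self, model_selection_case):
        _, sub, _ = model_selection_case
        noisy = sub.copy()
        noisy["lambda"] = np.random.default_rng(7).standard_normal(len(sub))
        comp = cn.compare_models(noisy, noisy[["x", "y"]].to_numpy(float))
        w = comp.table.set_index("model")["akaike_weight"]
        assert w["GWR_C+NC"] < 0.99

    def test_nc_fraction_override_applied(self, model_selection_case):
        _, sub, comp = model_selection_case
        fit_nc = comp.fits["GWR_NC"]
        # first interval (t0=1900) uses the widened 50% bandwidth
        assert (fit_nc.fractions_used == 0.5).all()
        fit_full = comp.fits["GWR_C+NC"]
        assert (fit_full.fractions_used == 0.3).all()

    def test_deterministic(self, model_selection_case):
        _, sub, comp = model_selection_case
        again = cn.compare_models(sub, sub[["x", "y"]].to_numpy(float))
        pd.testing.assert_frame_equal(comp.table, again.table)
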