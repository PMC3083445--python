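"""Model arithmetic, fitter closures and the brute-force Morrison oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from looprigor import kinetics as kin

conc = st.floats(min_value=1e-4, max_value=1e4)


def morrison_oracle(enzyme_nM, inhibitor_nM, ki_app_nM):
    """Fractional velocity by numerically solving the binding isotherm:
    find the complex concentration x with (E-x)(I-x)/x = Ki_app."""
    E, I, K = enzyme_nM, inhibitor_nM, ki_app_nM
    if I == 0:
        return 1.0
    if K == 0:
        return max(E - min(E, I), 0.0) / E

    def f(x):
        return (E - x) * (I - x) - K * x

    x = brentq(f, 0.0, min(E, I), xtol=1e-15, rtol=1e-15)
    return (E - x) / E


class TestCompetitiveModel:
    def test_zero_inhibitor_reduces_to_michaelis_menten(self):
        v = kin.competitive_velocity(100.0, 0.0, vmax=50.0, km_uM=679.9, ki_nM=3.62)
        assert v == pytest.approx(50.0 * 100.0 / (679.9 + 100.0))

    def test_saturating_substrate_approaches_vmax_despite_inhibitor(self):
        v = kin.competitive_velocity(1e9, 1000.0, vmax=50.0, km_uM=679.9, ki_nM=3.62)
        assert v == pytest.approx(50.0, rel=1e-3)

    def test_hand_value_at_s_equals_km_and_i_equals_ki(self):
        v = kin.competitive_velocity(679.9, 3.62, vmax=100.0, km_uM=679.9, ki_nM=3.62)
        assert v == pytest.approx(100.0 * 679.9 / (679.9 * 2 + 679.9))
        assert round(v, 2) == 33.33

    def test_noiseless_fit_recovers_generating_ki(self):
        S, I = np.meshgrid([170.0, 340.0, 679.9, 1360.0, 2720.0],
                           [0.0, 1.0, 2.0, 4.0, 8.0, 16.0])
        v = kin.competitive_velocity(S.ravel(), I.ravel(), 100.0, 679.9, 3.62)
        df = pd.DataFrame({"substrate_uM": S.ravel(), "inhibitor_nM": I.ravel(),
                           "velocity": v})
        fit = kin.fit_competitive(df)
        assert fit.converged
        assert fit.params["ki_nM"] == pytest.approx(3.62, rel=1e-6)
        assert fit.params["km_uM"] == pytest.approx(679.9, rel=1e-6)

    def test_uninhibited_data_only_is_unidentifiable(self):
        S = np.array([100.0, 200.0, 400.0, 800.0])
        v = kin.competitive_velocity(S, 0.0, 100.0, 679.9, 3.62)
        df = pd.DataFrame({"substrate_uM": S, "inhibitor_nM": 0.0, "velocity": v})
        with pytest.raises(ValueError, match="unidentifiable"):
            kin.fit_competitive(df)

    def test_noisy_fit_recovers_within_3_se(self):
        gen = np.random.default_rng(42)
        S, I = np.meshgrid([170.0, 340.0, 679.9, 1360.0, 2720.0],
                           [0.0, 1.0, 2.0, 4.0, 8.0, 16.0])
        v = kin.competitive_velocity(S.ravel(), I.ravel(), 100.0, 679.9, 3.62)
        v_noisy = v + gen.normal(0.0, 0.02 * v.max(), size=v.shape)
        df = pd.DataFrame({"substrate_uM": S.ravel(), "inhibitor_nM": I.ravel(),
                           "velocity": v_noisy})
        fit = kin.fit_competitive(df)
        assert abs(fit.params["ki_nM"] - 3.62) < 3 * fit.stderr["ki_nM"]


class TestMorrison:
    def test_zero_inhibitor_gives_unit_fraction(self):
        assert kin.morrison_fraction(0.15, 0.0, 0.067) == pytest.approx(1.0)

    def test_stoichiometric_titration_limit(self):
        assert kin.morrison_fraction(1.0, 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert kin.morrison_fraction(1.0, 2.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_equals_equilibrium_solver_oracle(self):
        """Closed-form quadratic == numerical isotherm solution to 1e-9,
        including the assay conditions of the tight-binding variant
        (E = 0.15 nM, Ki_app from Ki = 0.0386 nM at S = 500 uM)."""
        ki_app_asn = 0.0386 * (1 + 500.0 / 679.9)
        grid = [(0.15, 0.15, ki_app_asn), (0.15, 0.015, ki_app_asn)]
        gen = np.random.default_rng(7)
        for _ in range(30):
            grid.append(tuple(10.0 ** gen.uniform(-3, 1, size=3)))
        for E, I, K in grid:
            closed = float(kin.morrison_fraction(E, I, K))
            assert closed == pytest.approx(morrison_oracle(E, I, K), abs=1e-9)

    def test_low_enzyme_limit_is_classical_isotherm(self):
        """As E -> 0 the Morrison fraction approaches 1/(1 + I/Ki_app)."""
        I, K = 2.0, 0.5
        classical = 1.0 / (1.0 + I / K)
        errors = [abs(float(kin.morrison_fraction(E, I, K)) - classical) for E in (1e-2, 1e-4, 1e-6)]
        assert errors[0] < 1e-2 * classical
        assert errors[1] < 1e-4 * classical
        assert errors[2] < 1e-6 * classical  # error shrinks linearly in E

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(E=conc, I=conc, K=conc)
    def test_fraction_bounded_and_matches_oracle_everywhere(self, E, I, K):
        frac = float(kin.morrison_fraction(E, I, K))
        assert 0.0 <= frac <= 1.0
        assert frac == pytest.approx(morrison_oracle(E, I, K), abs=1e-7)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(E=conc, K=conc, i1=conc, factor=st.floats(min_value=1.0, max_value=100.0))
    def test_fraction_monotone_decreasing_in_inhibitor(self, E, K, i1, factor):
        assert float(kin.morrison_fraction(E, i1 * factor, K)) <= float(
            kin.morrison_fraction(E, i1, K)
        ) + 1e-12

    def test_noiseless_fit_recovers_tight_binding_ki(self):
        I = np.geomspace(0.0015, 1.5, 8)
        frac = kin.morrison_fraction(0.15, I, 0.0386 * (1 + 500.0 / 679.9))
        fit = kin.fit_morrison(I, frac, enzyme_nM=0.15, substrate_uM=500.0, km_uM=679.9)
        assert fit.converged
        assert fit.params["ki_nM"] == pytest.approx(0.0386, rel=1e-6)

    def test_noiseless_fit_recovers_moderate_ki(self):
        I = np.geomspace(0.1, 100.0, 10)
        ki_app = 3.89 * (1 + 100.0 / 679.9)
        frac = kin.morrison_fraction(1.5, I, ki_app)
        fit = kin.fit_morrison(I, frac, enzyme_nM=1.5, substrate_uM=100.0, km_uM=679.9)
        assert fit.params["ki_nM"] == pytest.approx(3.89, rel=1e-6)

    def test_titration_regime_warns(self):
        I = np.geomspace(1.0, 300.0, 10)
        frac = kin.morrison_fraction(100.0, I, 1e-4)
        with pytest.warns(UserWarning, match="titration"):
            kin.fit_morrison(I, frac, enzyme_nM=100.0, substrate_uM=100.0, km_uM=679.9)

    def test_no_inhibition_is_unidentifiable(self):
        I = np.array([0.001, 0.002, 0.003, 0.004])
        with pytest.raises(ValueError, match="unidentifiable"):
            kin.fit_morrison(I, np.full(4, 0.99), enzyme_nM=0.15,
                             substrate_uM=500.0, km_uM=679.9)


class TestIC50:
    def test_noiseless_logistic_recovers_ic50(self):
        I = np.geomspace(0.05, 500.0, 9)
        act = 1.0 / (1.0 + I / 6.07)
        fit = kin.fit_ic50(I, act)
        assert fit.params["ic50_nM"] == pytest.approx(6.07, rel=1e-6)
        assert fit.params["hill"] == pytest.approx(1.0, rel=1e-6)

    def test_flat_activity_errors(self):
        I = np.geomspace(0.1, 100.0, 6)
        with pytest.raises(ValueError, match="transition"):
            kin.fit_ic50(I, np.ones_like(I))

    def test_tight_binding_ic50_approximates_half_enzyme_plus_ki_app(self):
        """Under titration conditions the descriptive IC50 lands near
        E/2 + Ki_app, checked against a grid search of the Morrison curve."""
        E, ki_app = 1.5, 0.1
        I = np.geomspace(0.01, 100.0, 25)
        act = kin.morrison_fraction(E, I, ki_app)
        fit = kin.fit_ic50(I, act, hill=None)
        grid = np.geomspace(0.01, 100.0, 20001)
        ic50_grid = grid[np.argmin(np.abs(kin.morrison_fraction(E, grid, ki_app) - 0.5))]
        assert fit.params["ic50_nM"] == pytest.approx(ic50_grid, rel=0.15)
        assert ic50_grid == pytest.approx(E / 2 + ki_app, rel=0.05)


class TestSlowBinding:
    def test_no_lag_when_rates_equal(self):
        t = np.linspace(0.0, 100.0, 11)
        np.testing.assert_allclose(
            kin.slow_binding_progress(t, v0=0.2, vs=0.2, k_obs=0.01), 0.2 * t
        )

    def test_limiting_rates(self):
        dt = 1e-6
        p0 = kin.slow_binding_progress([0.0, dt], 1.0, 0.2, 0.01)
        assert (p0[1] - p0[0]) / dt == pytest.approx(1.0, rel=1e-6)
        t_inf = 1e6
        p_inf = kin.slow_binding_progress([t_inf, t_inf + 1.0], 1.0, 0.2, 0.01)
        assert p_inf[1] - p_inf[0] == pytest.approx(0.2, rel=1e-9)

    def test_hand_value(self):
        p = kin.slow_binding_progress(100.0, v0=1.0, vs=0.2, k_obs=0.01)
        assert round(float(p), 2) == 70.57

    def test_koff_recovery_from_three_curve_design(self):
        """Noiseless curves generated from kon = 8.03e8 M^-1 s^-1 and
        koff = 0.031 s^-1 under the low-enzyme assay design give the
        primary estimator within 5%, and both estimators agree."""
        kon, koff, I_nM, S_uM, km_uM, v0 = 8.03e8, 0.031, 0.5, 500.0, 679.9, 1.0
        k_obs = koff + kon * I_nM * 1e-9 / (1 + S_uM / km_uM)
        vs = v0 * koff / k_obs
        t = np.linspace(0.0, 300.0, 121)
        fit = kin.fit_koff(
            t,
            uninhibited=v0 * t,
            coadd=kin.slow_binding_progress(t, v0, vs, k_obs),
            preformed=kin.slow_binding_progress(t, 0.0, vs, k_obs),
        )
        assert fit.params["k_off"] == pytest.approx(koff, rel=0.05)
        assert fit.params["k_off_intercept"] == pytest.approx(fit.params["k_off"], rel=0.10)

    def test_no_inhibition_is_degenerate(self):
        t = np.linspace(0.0, 100.0, 21)
        with pytest.raises(ValueError, match="no inhibition"):
            kin.fit_koff(t, uninhibited=1.0 * t, coadd=1.0 * t + 1e-9,
                         preformed=1.0 * t - 1e-9)


class TestRateArithmetic:
    def test_second_order_kon_from_published_constants(self):
        kon = kin.second_order_kon(0.031, 0.0386)
        assert float(f"{kon:.3g}") == pytest.approx(8.03e8)

    def test_unit_arithmetic(self):
        assert kin.second_order_kon(1e-3, 1.0) == pytest.approx(1e6)
        assert kin.second_order_kon(0.0, 1.0) == 0.0

    def test_linearity(self):
        base = kin.second_order_kon(0.02, 2.0)
        assert kin.second_order_kon(0.04, 2.0) == pytest.approx(2 * base)
        assert kin.second_order_kon(0.02, 4.0) == pytest.approx(base / 2)

    def test_zero_ki_errors(self):
        with pytest.raises(ValueError):
            kin.second_order_kon(0.031, 0.0)

    @pytest.mark.parametrize(
        "reference, improved, expected",
        [(7.97, 0.0635, 126.0), (1506.0, 251.0, 6.00), (3.3, 3.3, 1.00)],
    )
    def test_fold_change_to_3_significant_figures(self, reference, improved, expected):
        assert kin.fold_change(reference, improved) == pytest.approx(expected)

    def test_fold_change_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            kin.fold_change(1.0, 0.0)


class TestHalfLife:
    def test_noiseless_decay_recovers_half_life(self):
        t = np.linspace(0.0, 240.0, 10)
        values = np.exp(-math.log(2) / 56.3 * t)
        fit = kin.fit_half_life(t, values)
        assert fit.params["t_half"] == pytest.approx(56.3, rel=1e-6)
        assert fit.params["decay_rate"] * fit.params["t_half"] == pytest.approx(math.log(2))

    def test_exact_halving_at_one_half_life_steps(self):
        t = np.array([0.0, 1.0, 2.0])
        fit = kin.fit_half_life(t, np.array([8.0, 4.0, 2.0]))
        assert fit.params["t_half"] == pytest.approx(1.0, rel=1e-9)
        assert fit.params["a0"] == pytest.approx(8.0, rel=1e-9)

    def test_constant_series_warns_and_reports_infinite_half_life(self):
        t = np.linspace(0.0, 10.0, 5)
        with pytest.warns(UserWarning, match="does not decay"):
            fit = kin.fit_half_life(t, np.ones(5))
        assert math.isinf(fit.params["t_half"]) or fit.params["decay_rate"] <= 0

    def test_scale_invariance(self):
        t = np.linspace(0.0, 100.0, 8)
        values = 3.0 * np.exp(-0.02 * t)
        a = kin.fit_half_life(t, values)
        b = kin.fit_half_life(t, 10.0 * values)
        assert a.params["t_half"] == pytest.approx(b.params["t_half"], rel=1e-9)
        assert b.params["a0"] == pytest.approx(10.0 * a.params["a0"], rel=1e-9)
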