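"""Two-state model evaluation, truncation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_valid_params
from fluorstab.synthetic import GeneratorSpec, generate_curve, sample_ground_truth
from fluorstab.twostate import (DEFAULT_WINDOW, R_GAS, TwoStateParams,
                                UnfoldingCurve, celsius_to_kelvin,
                                equilibrium_constant, fit_two_state,
                                fraction_unfolded, global_fit_shared_enthalpy,
                                truncate_curve, two_state_intensity)


def make_params(**kw):
    base = dict(I_N=1000.0, a=-2.0, I_D=3000.0, b=-5.0, Tm=353.0, dHvh=400e3)
    base.update(kw)
    return TwoStateParams(**base)


class TestEquilibriumAndFraction:
    def test_unity_at_midpoint(self):
        p = make_params()
        assert equilibrium_constant(p, p.Tm) == pytest.approx(1.0)
        assert fraction_unfolded(p, p.Tm) == pytest.approx(0.5)

    def test_direct_evaluation_two_kelvin_below_midpoint(self):
        # K = exp[(4e5/8.314)(1/353.15 − 1/351.15)] ≈ 0.4603
        p = make_params(Tm=353.15, dHvh=400e3)
        assert equilibrium_constant(p, 351.15) == pytest.approx(0.460, abs=5e-4)
        assert fraction_unfolded(p, 351.15) == pytest.approx(0.315, abs=5e-4)

    def test_high_temperature_limit(self):
        p = make_params()
        limit = np.exp(p.dHvh / (R_GAS * p.Tm))
        assert equilibrium_constant(p, 1e9) == pytest.approx(limit, rel=1e-4)

    def test_cold_limit_fully_folded(self):
        p = make_params(dHvh=800e3)
        assert fraction_unfolded(p, 300.0) < 1e-10

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_constant(make_params(), 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_midpoint_and_monotonicity_for_random_params(self, seed):
        """f(Tm)=1/2 and f strictly increasing, for any valid parameters."""
        p = random_valid_params(np.random.default_rng(seed))
        assert fraction_unfolded(p, p.Tm) == pytest.approx(0.5, abs=1e-12)
        grid = np.linspace(p.Tm - 30, p.Tm + 30, 200)
        f = fraction_unfolded(p, grid)
        assert np.all(np.diff(f) > 0)


class TestIntensity:
    def test_midpoint_is_baseline_average(self):
        p = make_params()  # Tm=353: native 294, denatured 1235
        assert two_state_intensity(p, 353.0) == pytest.approx(764.5)

    def test_native_baseline_limit(self):
        p = make_params(dHvh=900e3)
        T = 320.0
        assert two_state_intensity(p, T) == pytest.approx(p.I_N + p.a * T,
                                                          rel=1e-9)

    def test_matches_noiseless_generator(self, default_spec):
        """Forward model and the zero-noise generator agree on the grid."""
        cond = default_spec.conditions()[17]
        p = sample_ground_truth(cond, default_spec, 340.0)
        temps_c = default_spec.temperatures_c
        curve = generate_curve(p, temps_c, noise_cv=0.0)
        np.testing.assert_allclose(
            curve, two_state_intensity(p, celsius_to_kelvin(temps_c)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_continuity_in_temperature(self, seed):
        p = random_valid_params(np.random.default_rng(seed))
        grid = np.linspace(p.Tm - 20, p.Tm + 20, 4000)
        vals = two_state_intensity(p, grid)
        # no jumps beyond what the local slope allows
        assert np.max(np.abs(np.diff(vals))) < 1.0 + np.max(np.abs(vals)) * 1e-2


class TestTruncate:
    def make_curve(self, t0=293.0, t1=363.0, step=2.0):
        t = np.arange(t0, t1 + 1e-9, step)
        y = two_state_intensity(make_params(), t)
        return UnfoldingCurve(t, y)

    def test_default_window_on_293_to_363_grid(self):
        """A 36-point 293–363 K curve keeps the 17 points at 331…363 K."""
        out = truncate_curve(self.make_curve())
        assert len(out) == 17
        assert out.temperatures[0] == 331.0
        assert out.temperatures[-1] == 363.0

    def test_unbounded_window_is_identity(self):
        c = self.make_curve()
        out = truncate_curve(c, (0.0, np.inf))
        np.testing.assert_array_equal(out.temperatures, c.temperatures)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            truncate_curve(self.make_curve(), (1000.0, 2000.0))

    def test_underdetermined_window_errors(self):
        with pytest.raises(ValueError):
            truncate_curve(self.make_curve(), (358.9, 363.1))  # 3 points

    def test_inverted_window_errors(self):
        with pytest.raises(ValueError):
            truncate_curve(self.make_curve(), (363.0, 330.0))


class TestFit:
    def test_noiseless_round_trip(self, sharp_params):
        t = np.arange(293.15, 363.15 + 1e-9, 2.0)
        curve = UnfoldingCurve(t, two_state_intensity(sharp_params, t))
        fit = fit_two_state(curve)
        assert fit.converged
        assert fit.params.Tm == pytest.approx(sharp_params.Tm, abs=1e-3)
        assert fit.params.dHvh == pytest.approx(sharp_params.dHvh, rel=1e-3)

    def test_noisy_recovery_unbiased(self, sharp_params):
        """Monte-Carlo: mean recovered Tm consistent with the truth."""
        rng = np.random.default_rng(42)
        t_c = np.arange(20.0, 90.0 + 1e-9, 2.0)
        tms = []
        for _ in range(60):
            y = generate_curve(sharp_params, t_c, noise_cv=0.015, seed=rng)
            fit = fit_two_state(UnfoldingCurve(celsius_to_kelvin(t_c), y))
            tms.append(fit.params.Tm)
        tms = np.array(tms)
        se = tms.std(ddof=1) / np.sqrt(len(tms))
        assert abs(tms.mean() - sharp_params.Tm) < 3 * se + 1e-6

    def test_pure_line_is_flagged_unidentifiable(self):
        t = np.arange(293.15, 363.15 + 1e-9, 2.0)
        curve = UnfoldingCurve(t, 5000.0 - 3.0 * (t - 293.15))
        fit = fit_two_state(curve)
        assert (not fit.converged) or fit.standard_errors["Tm"] > 5.0

    def test_fit_never_worsens_initialization(self, sharp_params):
        rng = np.random.default_rng(3)
        t_c = np.arange(20.0, 90.0 + 1e-9, 2.0)
        y = generate_curve(sharp_params, t_c, noise_cv=0.015, seed=rng)
        curve = UnfoldingCurve(celsius_to_kelvin(t_c), y)
        init = TwoStateParams(I_N=y[0], a=-1.0, I_D=2 * y[0], b=-1.0,
                              Tm=350.0, dHvh=400e3)
        fit = fit_two_state(curve, init=init)
        work = truncate_curve(curve)
        rss0 = float(np.sum((two_state_intensity(init, work.temperatures)
                             - work.intensities) ** 2))
        assert fit.residual_sum_of_squares <= rss0 + 1e-9


class TestGlobalFit:
    def synthetic_curves(self, dhvhs, tms, seed=None):
        t = np.arange(293.15, 363.15 + 1e-9, 2.0)
        rng = np.random.default_rng(seed) if seed is not None else None
        curves = []
        for i, (dh, tm) in enumerate(zip(dhvhs, tms)):
            p = TwoStateParams(I_N=8000.0 + 500 * i, a=-25.0,
                               I_D=14000.0 + 500 * i, b=-35.0,
                               Tm=tm, dHvh=dh)
            y = two_state_intensity(p, t)
            if rng is not None:
                y = y * (1 + rng.normal(0, 0.01, y.shape))
            curves.append(UnfoldingCurve(t, y, wavelength=330.0 + i))
        return curves

    def test_single_curve_reduces_to_plain_fit(self):
        (curve,) = self.synthetic_curves([500e3], [352.0])
        fits, shared, _ = global_fit_shared_enthalpy([curve])
        solo = fit_two_state(curve)
        assert shared == pytest.approx(solo.params.dHvh, rel=1e-6)
        assert fits[0].params.Tm == pytest.approx(solo.params.Tm, rel=1e-6)

    def test_shared_enthalpy_round_trip(self):
        curves = self.synthetic_curves([600e3] * 3, [351.0, 353.0, 355.0])
        fits, shared, _ = global_fit_shared_enthalpy(curves)
        assert shared == pytest.approx(600e3, rel=1e-3)
        for fit, tm in zip(fits, [351.0, 353.0, 355.0]):
            assert fit.params.Tm == pytest.approx(tm, abs=1e-3)

    def test_constraint_cannot_beat_independent_fits(self):
        """Pooled RSS under a shared enthalpy ≥ sum of free-fit RSS when the
        curves genuinely differ in enthalpy."""
        curves = self.synthetic_curves([400e3, 650e3, 900e3],
                                       [351.0, 353.0, 355.0], seed=7)
        fits, _, _ = global_fit_shared_enthalpy(curves)
        pooled = sum(f.residual_sum_of_squares for f in fits)
        free = sum(fit_two_state(c).residual_sum_of_squares for c in curves)
        assert pooled > free
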