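"""DSF melt-curve analysis and 1:1 Langmuir SPR kinetics."""

import numpy as np
import pytest

from baddisplay.biophys import dsf, spr
from baddisplay.errors import ConfigError, NoTransitionError


class TestMeltSimulation:
    def test_single_transition_inflects_at_tm(self):
        curve = dsf.simulate_melt_curve([dsf.Transition(70.0, 1000.0, 1.5)])
        deriv = np.gradient(curve.fluorescence, curve.temperatures)
        t_peak = curve.temperatures[np.argmax(deriv)]
        assert abs(t_peak - 70.0) <= 0.2  # within one grid step

    def test_zero_amplitude_is_flat_baseline(self):
        curve = dsf.simulate_melt_curve(
            [dsf.Transition(70.0, 0.0, 1.5)], baseline_slope=2.0, baseline_intercept=5.0
        )
        expected = 5.0 + 2.0 * curve.temperatures
        assert np.allclose(curve.fluorescence, expected)

    def test_two_transitions_two_derivative_maxima(self):
        curve = dsf.simulate_melt_curve(
            [dsf.Transition(70.0, 1000.0, 1.5), dsf.Transition(82.0, 600.0, 1.5)]
        )
        deriv = np.gradient(curve.fluorescence, curve.temperatures)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(deriv, prominence=0.1 * deriv.max())
        assert len(peaks) == 2
        assert np.allclose(
            sorted(curve.temperatures[peaks]), [70.0, 82.0], atol=0.21
        )

    def test_transition_outside_grid_rejected(self):
        with pytest.raises(ConfigError):
            dsf.simulate_melt_curve([dsf.Transition(150.0, 100.0, 1.0)])

    def test_seeded_noise_reproducible(self):
        args = dict(noise_sd=5.0, seed=42)
        a = dsf.simulate_melt_curve([dsf.Transition(70, 100, 1.5)], **args)
        b = dsf.simulate_melt_curve([dsf.Transition(70, 100, 1.5)], **args)
        assert np.array_equal(a.fluorescence, b.fluorescence)


class TestExtractTransitions:
    def test_noiseless_recovery_within_grid_step(self):
        for tm in (69.4, 75.1, 62.3):
            curve = dsf.simulate_melt_curve([dsf.Transition(tm, 1000.0, 1.8)])
            result = dsf.extract_transitions(curve)
            assert abs(result.assigned_fab_tm - tm) <= 0.2

    def test_recovery_with_one_percent_noise(self):
        curve = dsf.simulate_melt_curve(
            [dsf.Transition(69.4, 1000.0, 1.8)], noise_sd=10.0, seed=7
        )
        result = dsf.extract_transitions(curve)
        assert abs(result.assigned_fab_tm - 69.4) < 0.3

    def test_delta_tm_between_wild_type_and_stabilized_variant(self):
        """Planted 5.7 degC stability gain is recovered from separate curves."""
        wt = dsf.simulate_melt_curve([dsf.Transition(69.4, 1000, 1.8)], noise_sd=10, seed=1)
        var = dsf.simulate_melt_curve([dsf.Transition(75.1, 1000, 1.8)], noise_sd=10, seed=2)
        d_tm = (
            dsf.extract_transitions(var).assigned_fab_tm
            - dsf.extract_transitions(wt).assigned_fab_tm
        )
        assert abs(d_tm - 5.7) < 0.4

    def test_fab_assigned_to_largest_amplitude(self):
        """Fab unfolding dwarfs the CH2/CH3 transitions and takes the assignment."""
        curve = dsf.simulate_melt_curve(
            [
                dsf.Transition(69.4, 1000.0, 1.8),
                dsf.Transition(82.0, 400.0, 1.5),
            ],
            baseline_slope=1.0,
            noise_sd=5.0,
            seed=3,
        )
        result = dsf.extract_transitions(curve)
        assert len(result.transitions) == 2
        assert result.assigned_fab_tm == pytest.approx(69.4, abs=0.3)
        fab = max(result.transitions, key=lambda t: t.amplitude)
        assert result.assigned_fab_tm == fab.tm

    def test_pure_baseline_raises(self):
        grid = dsf.default_temperature_grid()
        curve = dsf.MeltCurve(grid, 5.0 + 0.5 * grid)
        with pytest.raises(NoTransitionError):
            dsf.extract_transitions(curve)


IL13_SERIES = spr.il13_injection_series()
VEGF_SERIES = spr.vegf_injection_series()


class TestSensorgramModel:
    def test_high_concentration_plateau_approaches_rmax(self):
        params = spr.LangmuirParams(ka=1e6, kd=1e-4, rmax=100.0)
        series = spr.InjectionSeries(
            mode="multi_cycle", concentrations=(1e-3,), t_assoc=300.0, t_dissoc=10.0
        )
        gram = spr.simulate_sensorgram(params, series)
        assert gram.response.max() == pytest.approx(100.0, rel=1e-3)

    def test_plateau_is_half_rmax_at_kd(self):
        params = spr.LangmuirParams(ka=1e6, kd=1e-3, rmax=100.0)
        kD = params.kD_molar
        series = spr.InjectionSeries(
            mode="multi_cycle", concentrations=(kD,), t_assoc=20_000.0, t_dissoc=10.0
        )
        gram = spr.simulate_sensorgram(params, series)
        assert gram.response.max() == pytest.approx(50.0, rel=1e-3)

    def test_single_cycle_matches_piecewise_closed_form(self):
        """Each segment obeys the carried-R0 exponential solution."""
        params = spr.LangmuirParams(ka=4.48e4, kd=5.92e-4, rmax=80.0)
        gram = spr.simulate_sensorgram(params, VEGF_SERIES, dt=1.0)
        kD = params.kD_molar
        r0 = 0.0
        idx = 0
        n_assoc, n_dissoc = 120, 300
        for conc in VEGF_SERIES.concentrations:
            t = np.arange(n_assoc)
            req = params.rmax * conc / (conc + kD)
            expected = req + (r0 - req) * np.exp(-(params.ka * conc + params.kd) * t)
            assert np.allclose(gram.response[idx : idx + n_assoc], expected)
            r0 = req + (r0 - req) * np.exp(-(params.ka * conc + params.kd) * n_assoc)
            idx += n_assoc
            t = np.arange(n_dissoc)
            expected = r0 * np.exp(-params.kd * t)
            assert np.allclose(gram.response[idx : idx + n_dissoc], expected)
            r0 = r0 * np.exp(-params.kd * n_dissoc)
            idx += n_dissoc

    def test_single_cycle_response_non_decreasing_at_injection_starts(self):
        params = spr.LangmuirParams(ka=3e4, kd=5e-4, rmax=60.0)
        gram = spr.simulate_sensorgram(params, VEGF_SERIES)
        starts = np.flatnonzero(
            (gram.phase == "assoc") & (np.roll(gram.phase, 1) != "assoc")
        )
        levels = gram.response[starts]
        assert np.all(np.diff(levels) >= 0)

    def test_multi_cycle_each_cycle_starts_at_zero(self):
        params = spr.LangmuirParams(ka=1.13e6, kd=4.26e-5, rmax=50.0)
        gram = spr.simulate_sensorgram(params, IL13_SERIES)
        starts = np.flatnonzero(
            (gram.phase == "assoc") & (np.roll(gram.phase, 1) != "assoc")
        )
        assert np.allclose(gram.response[starts], 0.0)


class TestFitLangmuir:
    def test_noise_free_recovery_of_printed_rates(self):
        """The simulate-then-fit loop returns the generating constants to <1%."""
        cases = [
            # (params, series, printed KD in nM, unit of its last printed digit)
            (spr.params_from_table(11.3, 4.26, rmax=50.0), IL13_SERIES, 0.038, 1e-3),
            (spr.params_from_table(0.346, 47.1, rmax=80.0), VEGF_SERIES, 13.6, 0.1),
        ]
        for true_params, series, expected_kd_nm, digit in cases:
            gram = spr.simulate_sensorgram(true_params, series)
            fit = spr.fit_langmuir(gram)
            assert fit.params.ka == pytest.approx(true_params.ka, rel=0.01)
            assert fit.params.kd == pytest.approx(true_params.kd, rel=0.01)
            assert abs(round(fit.params.kD_nM / digit) * digit - expected_kd_nm) <= digit

    def test_noisy_recovery_of_kd(self):
        true_params = spr.params_from_table(11.3, 4.26, rmax=50.0)
        gram = spr.simulate_sensorgram(true_params, IL13_SERIES, noise_sd=1.0, seed=5)
        fit = spr.fit_langmuir(gram)
        assert abs(np.log(fit.params.kD_nM / true_params.kD_nM)) < 0.05

    def test_too_few_concentrations_rejected(self):
        params = spr.LangmuirParams(ka=1e5, kd=1e-3, rmax=50.0)
        series = spr.InjectionSeries(mode="multi_cycle", concentrations=(1e-8,))
        gram = spr.simulate_sensorgram(params, series)
        with pytest.raises(ConfigError):
            spr.fit_langmuir(gram)


class TestUnits:
    @pytest.mark.parametrize(
        "ka_e5,kd_em5,expected_nm,digit",
        [
            (13.0, 4.43, 0.034, 1e-3),  # anti-IL-13 F27L
            (0.457, 50.6, 11.1, 0.1),  # anti-VEGF E6Q.V48L
        ],
    )
    def test_kd_equilibrium_matches_printed_values(self, ka_e5, kd_em5, expected_nm, digit):
        params = spr.params_from_table(ka_e5, kd_em5)
        assert abs(spr.kd_equilibrium(params) - expected_nm) <= digit

    def test_equal_rates_give_one_molar(self):
        params = spr.LangmuirParams(ka=123.0, kd=123.0, rmax=1.0)
        assert spr.kd_equilibrium(params) == pytest.approx(1e9)  # 1 M in nM

    def test_table_scaling_round_trip(self):
        params = spr.params_from_table(11.3, 4.26)
        assert spr.params_to_table(params) == (
            pytest.approx(11.3),
            pytest.approx(4.26),
        )
        assert params.ka == pytest.approx(11.3e5)
        assert params.kd == pytest.approx(4.26e-5)

    def test_kd_derived_exactly(self):
        params = spr.LangmuirParams(ka=2.0e5, kd=5.0e-4, rmax=10.0)
        assert params.kD_molar == params.kd / params.ka
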