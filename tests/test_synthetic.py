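import math

import numpy as np
import pytest
from scipy import integrate, stats

from ecmturnover import (
    MrnaInterpolant,
    SyntheticScenario,
    generate_embryo_traces,
    generate_fdap_trace,
    generate_mrna_series,
    generate_pulse_chase_trace,
    solve_protein_ode,
)
from ecmturnover.synthetic import (
    COLLAGEN_REGIME,
    PERL_REGIME,
    collagen_scenario,
    logistic_consistent_program,
    perl_scenario,
)

LN2 = math.log(2.0)


class TestScenarioValidation:
    @pytest.mark.parametrize("kwargs", [
        {"d_p_true": 0.0},
        {"dt": -0.1},
        {"t_start": 5.0, "t_end": 5.0},
        {"n_embryos": 0},
        {"noise_sd": -0.01},
        {"n_controls": 3},
        {"dt": 0.7},  # does not divide the window
    ])
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticScenario(**kwargs)


class TestMrnaSeriesGeneration:
    def test_constant_program_gives_constant_bins(self):
        sc = SyntheticScenario(mrna_program=50.0)
        series = generate_mrna_series(sc)
        assert np.all(series.M == 50.0)

    def test_single_gaussian_peak_at_stage15_bin(self):
        prog = MrnaInterpolant(a1=100.0, b1=0.0, c1=5.0, a2=0.0, b2=0.0,
                               c2=1.0, d2=0.0, ramp_lo=100.0, ramp_hi=200.0)
        series = generate_mrna_series(SyntheticScenario(mrna_program=prog))
        idx = series.labels.index("embryo 10-12h")  # t = 0 h
        assert series.M[idx] == pytest.approx(100.0)

    def test_deterministic_given_scenario(self):
        sc = perl_scenario(7.0, seed=5)
        a, b = generate_mrna_series(sc), generate_mrna_series(sc)
        assert a.labels == b.labels
        assert np.array_equal(a.M, b.M)


class TestEmbryoTraceGeneration:
    def test_noise_free_trace_is_curve_plus_autofluorescence(self):
        sc = perl_scenario(7.0, noise_sd=0.0, n_embryos=2,
                           autofluorescence=12.0, record_from=None)
        ds = generate_embryo_traces(sc)
        for tr in ds.embryos:
            assert np.array_equal(tr.intensity,
                                  ds.ground_truth.noise_free_curve + 12.0)

    def test_controls_are_autofluorescence_plus_noise(self):
        sc = perl_scenario(7.0, noise_sd=0.0, autofluorescence=9.0)
        ds = generate_embryo_traces(sc)
        assert len(ds.controls) >= 5
        for c in ds.controls:
            assert np.all(c.intensity == 9.0)

    def test_seed_fixes_all_outputs_exactly(self):
        sc = perl_scenario(7.0, seed=77)
        a, b = generate_embryo_traces(sc), generate_embryo_traces(sc)
        for x, y in zip(a.embryos + a.controls, b.embryos + b.controls):
            assert np.array_equal(x.intensity, y.intensity)

    def test_recording_window_starts_at_stage15(self):
        ds = generate_embryo_traces(perl_scenario(7.0))
        assert ds.embryos[0].time_h[0] == 0.0
        assert ds.ground_truth.t[0] == -10.0  # ODE still starts at embryo birth

    def test_constant_program_approaches_steady_state(self):
        sc = SyntheticScenario(mrna_program=40.0, s_p_true=0.3,
                               d_p_true=LN2 / 2.0, noise_sd=0.0, n_embryos=1,
                               autofluorescence=0.0, t_end=40.0)
        ds = generate_embryo_traces(sc)
        assert ds.ground_truth.noise_free_curve[-1] == pytest.approx(
            0.3 * 40.0 / (LN2 / 2.0), rel=1e-6)

    def test_noise_free_curve_matches_quadrature_oracle(self):
        """Generator ODE solution vs independent integrating-factor quadrature."""
        sc = perl_scenario(7.0)
        prog, s, d = sc.mrna_program, sc.s_p_true, sc.d_p_true
        ds = generate_embryo_traces(sc)
        t_grid, curve = ds.ground_truth.t, ds.ground_truth.noise_free_curve
        for t_chk in (-5.0, 0.0, 6.0, 12.0, 16.0):
            val, _ = integrate.quad(
                lambda u: float(prog(u)) * math.exp(-d * (t_chk - u)),
                -10.0, t_chk, limit=200)
            expected = s * val
            got = curve[np.argmin(np.abs(t_grid - t_chk))]
            assert got == pytest.approx(expected, rel=1e-6)

    def test_ensemble_mean_consistent_with_noise_free_curve(self):
        """Law of large numbers: per-point t-interval contains the truth."""
        sc = perl_scenario(7.0, noise_sd=0.02, n_embryos=50, seed=9)
        ds = generate_embryo_traces(sc)
        stack = np.array([tr.intensity for tr in ds.embryos])
        rec = ds.ground_truth.t >= 0.0
        truth = ds.ground_truth.noise_free_curve[rec] + sc.autofluorescence
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / math.sqrt(stack.shape[0])
        z = np.abs(mean - truth) / sem
        # pointwise within 3 SEM for essentially all samples (multiplicity)
        assert np.mean(z < 3.0) > 0.99
        tcrit = stats.t.ppf(0.9995, stack.shape[0] - 1)
        assert np.all(z < tcrit + 1.0)

    def test_interembryo_jitter_draws_are_recorded(self):
        sc = perl_scenario(7.0, cv_sp=0.2, cv_dp=0.2, n_embryos=6, seed=3)
        ds = generate_embryo_traces(sc)
        sp = [p["s_p"] for p in ds.ground_truth.per_embryo_params]
        assert len(set(sp)) == 6  # distinct draws
        assert np.std(sp) > 0.0


class TestRegimePrograms:
    def test_program_consistent_with_logistic_closed_form(self):
        reg = PERL_REGIME
        prog = logistic_consistent_program(**reg)
        t = np.linspace(-10.0, 38.0, 300)
        P = reg["k"] / (1.0 + np.exp(reg["r"] * (reg["t_i"] - t)))
        M = ((reg["r"] + reg["d_p"]) * reg["k"] * P - reg["r"] * P**2) / (
            reg["s_p"] * reg["k"])
        assert np.max(np.abs(prog(t) - M)) / np.max(M) < 0.03
        assert np.all(prog(t) > -1e-6)

    def test_collagen_regime_is_stronger_and_earlier(self):
        assert COLLAGEN_REGIME["k"] == pytest.approx(2.0 * PERL_REGIME["k"])
        assert COLLAGEN_REGIME["t_i"] < PERL_REGIME["t_i"]
        assert collagen_scenario().d_p_true == pytest.approx(LN2 / 10.0)


class TestPulseChaseGeneration:
    def test_post_peak_is_exact_exponential_without_tail(self):
        d = LN2 / 14.0
        tr = generate_pulse_chase_trace(100.0, d, t_peak=12.0)
        post = tr.time_h >= 12.0
        expected = 100.0 * np.exp(-d * (tr.time_h[post] - 12.0))
        assert np.allclose(tr.intensity[post], expected, rtol=1e-12)

    def test_zero_rate_gives_flat_post_peak(self):
        tr = generate_pulse_chase_trace(100.0, 0.0)
        assert np.all(tr.intensity[tr.time_h >= 12.0] == 100.0)

    def test_residual_synthesis_raises_late_levels(self):
        plain = generate_pulse_chase_trace(100.0, LN2 / 14.0)
        tailed = generate_pulse_chase_trace(100.0, LN2 / 14.0, synthesis_tail=2.0)
        assert tailed.intensity[-1] > plain.intensity[-1]

    @pytest.mark.parametrize("kwargs", [
        {"p0": -1.0}, {"p0": 100.0, "d_p": -0.1},
        {"p0": 100.0, "d_p": 0.1, "noise_sd": -0.5},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_pulse_chase_trace(**{"d_p": 0.1, **kwargs})


class TestFdapGeneration:
    def test_half_life_definition_at_four_hours(self):
        tr = generate_fdap_trace(100.0, LN2 / 4.0, t_grid=np.array([0.0, 4.0]))
        assert tr.intensity[1] == pytest.approx(50.0)

    def test_zero_rate_constant(self):
        tr = generate_fdap_trace(80.0, 0.0)
        assert np.all(tr.intensity == 80.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_fdap_trace(80.0, 0.1, noise_sd=-0.01)
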