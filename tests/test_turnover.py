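import math

import numpy as np
import pytest

from ecmturnover import (
    FitError,
    FluorescenceTrace,
    fit_anterograde,
    fit_logistic,
    fit_retrograde,
    half_life,
    mstar_retrograde,
    perturbation_scan,
    simulate_anterograde,
    solve_protein_ode,
)
from ecmturnover.logistic import LogisticFit
from ecmturnover.synthetic import perl_scenario
from ecmturnover.turnover import ANTERO_GRID, time_grid

S_P, D_P = 0.4, math.log(2) / 7.0


def make_logistic(k=100.0, r=0.4, t_i=6.0, b=0.0):
    return LogisticFit(k=k, r=r, t_i=t_i, b=b, hill_span=k,
                       hill_slope=r / math.log(10), hill_logec50=t_i,
                       hill_bottom=b, sse=0.0)


class TestSimulation:
    def test_constant_mrna_matches_closed_form(self):
        M0 = 50.0
        sim = simulate_anterograde(M0, S_P, D_P)
        closed = (S_P * M0 / D_P) * (1.0 - np.exp(-D_P * (sim.t + 10.0)))
        assert np.max(np.abs(sim.value - closed)) / np.max(closed) < 1e-4

    def test_plateau_reaches_steady_state_balance(self):
        # long window so the transient has fully decayed at the end
        M0, d = 50.0, math.log(2) / 2.0
        sim = simulate_anterograde(M0, 0.3, d, grid=(-10.0, 40.0, 1.0 / 30.0))
        assert sim.value[-1] == pytest.approx(0.3 * M0 / d, rel=1e-4)

    def test_zero_synthesis_stays_zero(self):
        sim = simulate_anterograde(50.0, 0.0, D_P)
        assert np.all(sim.value == 0.0)

    def test_fixed_step_matches_adaptive_oracle(self):
        prog = perl_scenario(7.0).mrna_program
        sim = simulate_anterograde(prog, S_P, D_P)
        oracle = solve_protein_ode(prog, S_P, D_P, sim.t)
        err = np.max(np.abs(sim.value - oracle)) / np.max(np.abs(oracle))
        assert err < 0.005

    def test_scale_equivariance_in_mrna_units(self):
        """M -> cM with s_p -> s_p/c leaves P* unchanged (units absorbed)."""
        prog = perl_scenario(7.0).mrna_program
        c = 37.5
        a = simulate_anterograde(prog, S_P, D_P)
        b = simulate_anterograde(lambda t: c * prog(t), S_P / c, D_P)
        assert np.allclose(a.value, b.value, rtol=1e-12)

    def test_negative_rate_and_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_anterograde(50.0, S_P, -0.1)
        with pytest.raises(ValueError):
            time_grid((0.0, 10.0, -1.0))
        with pytest.raises(ValueError):
            time_grid((10.0, 0.0, 0.1))


class TestRetrogradeClosedForm:
    def test_value_at_inflection(self):
        lf = make_logistic()
        m = mstar_retrograde(lf, S_P, D_P, [lf.t_i]).value[0]
        expected = lf.k * (lf.r + 2.0 * D_P) / (4.0 * S_P)
        assert m == pytest.approx(expected, rel=1e-12)

    def test_late_limit_is_steady_state_balance(self):
        lf = make_logistic()
        m = mstar_retrograde(lf, S_P, D_P, [1e4]).value[0]
        assert m == pytest.approx(lf.k * D_P / S_P, rel=1e-9)

    def test_zero_synthesis_rejected(self):
        with pytest.raises(ValueError):
            mstar_retrograde(make_logistic(), 0.0, D_P, [0.0])

    def test_consistency_with_constant_mrna_simulation(self):
        """Logistic fit of a constant-M simulation inverts back to ~M0.

        The fit uses the recorded window (t >= 0, as for measured
        embryos); the pre-recording part of a saturating curve has no
        inflection and is outside the logistic family.
        """
        M0, d = 50.0, math.log(2) / 4.0
        sim = simulate_anterograde(M0, S_P, d, grid=(-10.0, 40.0, 1.0 / 30.0))
        rec = sim.t >= 0.0
        tr = FluorescenceTrace("sim", sim.t[rec], sim.value[rec], stage="subtracted")
        lf = fit_logistic(tr, fix_bottom=0.0)  # simulated curve has no background
        plateau_t = sim.t[sim.t > 25.0]
        m = mstar_retrograde(lf, S_P, d, plateau_t).value
        assert np.all(np.abs(m - M0) / M0 < 0.02)


class TestHalfLife:
    def test_definition(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)
        assert half_life(0.1) == pytest.approx(6.9315, abs=1e-4)

    @pytest.mark.parametrize("d", [0.0, -0.2])
    def test_nonpositive_rate_rejected(self, d):
        with pytest.raises(ValueError):
            half_life(d)


class TestFitting:
    def test_zero_mrna_unidentifiable(self):
        with pytest.raises(FitError, match="unidentifiable"):
            fit_anterograde(0.0, make_logistic())

    def test_raw_target_noise_free_bias_below_one_percent(self):
        sc = perl_scenario(7.0, noise_sd=0.0, n_embryos=1,
                           autofluorescence=0.0, record_from=None)
        t = time_grid(ANTERO_GRID)
        curve = solve_protein_ode(sc.mrna_program, sc.s_p_true, sc.d_p_true, t)
        tr = FluorescenceTrace("e", t, curve, stage="subtracted")
        tf = fit_anterograde(sc.mrna_program, tr)
        assert abs(tf.s_p - sc.s_p_true) / sc.s_p_true < 0.01
        assert abs(tf.d_p - sc.d_p_true) / sc.d_p_true < 0.01

    def test_retrograde_noise_free_bias_below_one_percent(self):
        lf = make_logistic()
        program = perl_scenario(7.0).mrna_program
        tf = fit_retrograde(lf, program)
        assert abs(tf.s_p - S_P) / S_P < 0.01
        assert abs(tf.d_p - D_P) / D_P < 0.01

    def test_anterograde_idempotent_on_its_own_output(self):
        """Refitting the simulation of the returned estimates reproduces them."""
        program = perl_scenario(7.0).mrna_program
        tf = fit_anterograde(program, make_logistic())
        sim = simulate_anterograde(program, tf.s_p, tf.d_p)
        refit = fit_anterograde(program, sim.value)
        assert refit.s_p == pytest.approx(tf.s_p, rel=1e-5)
        assert refit.d_p == pytest.approx(tf.d_p, rel=1e-5)

    def test_retrograde_idempotent_on_its_own_output(self):
        lf = make_logistic()
        program = perl_scenario(7.0).mrna_program
        tf = fit_retrograde(lf, program)
        mstar = mstar_retrograde(lf, tf.s_p, tf.d_p, time_grid(tf.grid))
        refit = fit_retrograde(lf, lambda t: np.interp(t, mstar.t, mstar.value))
        assert refit.s_p == pytest.approx(tf.s_p, rel=1e-6)
        assert refit.d_p == pytest.approx(tf.d_p, rel=1e-6)

    def test_half_life_field_consistent_with_rate(self, recovery_ensembles):
        _, antero, retro = recovery_ensembles[7.0]
        for tf in antero + retro:
            assert tf.half_life_h == math.log(2) / tf.d_p
            assert tf.ci95_dp[0] <= tf.d_p <= tf.ci95_dp[1]

    def test_ensemble_recovery_against_generator_truth(self, recovery_ensembles):
        sc, antero, retro = recovery_ensembles[7.0]
        truth = math.log(2) / sc.d_p_true
        assert np.median([tf.half_life_h for tf in antero]) == pytest.approx(truth, rel=0.10)
        assert np.median([tf.half_life_h for tf in retro]) == pytest.approx(truth, rel=0.10)


class TestPerturbationScan:
    def test_identity_factor_reproduces_baseline(self):
        program = perl_scenario(7.0).mrna_program
        df = perturbation_scan((S_P, D_P), program, d_p_factors=[1.0])
        sim = simulate_anterograde(program, S_P, D_P)
        tr = FluorescenceTrace("sim", sim.t, sim.value, stage="subtracted")
        lf = fit_logistic(tr)
        row = df.iloc[0]
        assert row["K"] == pytest.approx(lf.k, rel=1e-9)
        assert row["r"] == pytest.approx(lf.r, rel=1e-9)
        assert row["t_i"] == pytest.approx(lf.t_i, rel=1e-9)

    def test_empty_factor_list_rejected(self):
        with pytest.raises(ValueError):
            perturbation_scan((S_P, D_P), perl_scenario(7.0).mrna_program,
                              d_p_factors=[])

    def test_synthesis_factor_scales_capacity_only(self):
        program = perl_scenario(7.0).mrna_program
        df = perturbation_scan((S_P, D_P), program, d_p_factors=[1.0],
                               s_p_factors=[1.0, 2.0])
        assert df.iloc[1]["K"] == pytest.approx(2.0 * df.iloc[0]["K"], rel=1e-6)
        assert df.iloc[1]["r"] == pytest.approx(df.iloc[0]["r"], rel=1e-6)
        assert df.iloc[1]["t_i"] == pytest.approx(df.iloc[0]["t_i"], rel=1e-6)


class TestSteadyStateConservation:
    def test_terminal_window_balance(self):
        """Where M is constant late, the plateau obeys s_p M = d_p P."""
        def program(t):
            return np.where(np.asarray(t, dtype=float) < 0.0, 5.0, 25.0)

        d = math.log(2) / 2.0
        sim = simulate_anterograde(program, S_P, d, grid=(-10.0, 40.0, 1.0 / 30.0))
        assert sim.value[-1] == pytest.approx(S_P * 25.0 / d, rel=1e-4)
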