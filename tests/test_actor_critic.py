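"""Lever-press SMDP tests: average reward, relative values, TD traces."""

import logging

import numpy as np
import pytest

from ramplab.actor_critic_smdp import (
    CommunicationMode,
    TaskSpec,
    cycle_average_reward,
    efference_transient,
    simulate_experiment,
    solve_relative_values,
    td_trace,
)
from ramplab.signal_kernels import AsymmetryRule
from ramplab.timing_models import DeterministicTiming, GammaTiming

INDIRECT = CommunicationMode("indirect")
DIRECT = CommunicationMode("direct_and_indirect", epsilon=0.1, k_scalar=0.1)


class TestCycleAverageReward:
    def test_deterministic_renewal_examples(self):
        # (r + a/tau + b) / (tau + tau_post + tau_I), lump renewal-reward ratio
        spec = TaskSpec(a=-1, b=0, r=1, tau_post=0.5, tau_I=30)
        assert cycle_average_reward(spec, DeterministicTiming(1.0)) == pytest.approx(0.0)
        assert cycle_average_reward(spec, DeterministicTiming(2.0)) == pytest.approx(
            0.5 / 32.5, rel=1e-12
        )

    def test_zero_utilities_zero_rate(self):
        spec = TaskSpec(a=0, b=0, r=0)
        assert cycle_average_reward(spec, GammaTiming(2, 1)) == 0.0

    def test_gamma21_cost_expectation(self):
        # E[1/T] = 1 for G(2,1), so E[u] = r + a = 0 with a=-1, r=1; the
        # cost truncation at dt leaves only a sub-percent positive residue
        spec = TaskSpec(a=-1, b=0, r=1)
        rho = cycle_average_reward(spec, GammaTiming(2, 1))
        rho_reward = cycle_average_reward(spec, GammaTiming(2, 1), include_costs=False)
        assert abs(rho) < 0.01 * rho_reward

    def test_divergent_cost_truncation_logged(self, caplog):
        spec = TaskSpec(a=-1, b=0, r=1)
        with caplog.at_level(logging.WARNING, logger="ramplab.actor_critic_smdp"):
            rho = cycle_average_reward(spec, GammaTiming(1, 1))
        assert any("diverges" in r.message for r in caplog.records)
        assert np.isfinite(rho)

    def test_reward_only_stream(self):
        spec = TaskSpec(a=-1, b=0, r=1)
        rho = cycle_average_reward(spec, GammaTiming(2, 1), include_costs=False)
        assert rho == pytest.approx(1.0 / 32.5, rel=1e-12)


class TestRelativeValues:
    def test_zero_utilities_zero_values(self):
        spec = TaskSpec(a=0, b=0, r=0, cost_in_stream=True)
        table = solve_relative_values(spec, GammaTiming(2, 1), INDIRECT)
        assert table.rho == 0.0
        np.testing.assert_allclose(table.v1, 0.0, atol=1e-12)
        assert table.v2 == 0.0 and table.v3 == 0.0

    def test_flat_hazard_gives_constant_v1(self):
        """Memorylessness: identical continuation at every waiting time."""
        table = solve_relative_values(TaskSpec(), GammaTiming(1, 1), INDIRECT)
        sel = table.t_grid <= 10.0
        v = table.v1[sel]
        assert v.max() - v.min() < 1e-6

    def test_recursion_residual(self):
        """Plugging v1 back into the waiting recursion: residual < 1e-8."""
        spec = TaskSpec()
        timing = GammaTiming(2, 1)
        table = solve_relative_values(spec, timing, INDIRECT)
        surv = timing.survival(table.t_grid)
        res = table.recursion_residual(surv)
        assert np.abs(res).max() < 1e-8

    def test_monte_carlo_value_oracle(self):
        """v1(t) = E[r - rho (T - t + tau_post) | T > t] (anchor v3 = 0).

        Independent route: rejection-sample the conditional waiting time.
        """
        spec = TaskSpec()
        timing = GammaTiming(2, 1)
        table = solve_relative_values(spec, timing, INDIRECT)
        rng = np.random.default_rng(123)
        for t_hat in (0.5, 2.0, 6.0):
            draws = timing.rvs(400_000, rng)
            cond = draws[draws > t_hat]
            mc = np.mean(spec.r - table.rho * (cond - t_hat + spec.tau_post))
            se = np.std(spec.r - table.rho * (cond - t_hat)) / np.sqrt(cond.size)
            assert table.v1_at(t_hat) == pytest.approx(mc, abs=3 * se + 2e-4)

    def test_mean_residual_life_oracle(self):
        """Efference transient equals rho * mean residual waiting time.

        For G(2,1) the mean residual life is (2+t)/(1+t) in closed form.
        """
        table = solve_relative_values(TaskSpec(), GammaTiming(2, 1), INDIRECT)
        for t in (1.0, 3.0, 10.0):
            expected = table.rho * (2 + t) / (1 + t)
            assert efference_transient(table, t) == pytest.approx(expected, rel=2e-2)

    def test_grid_refinement_stability(self):
        spec_c = TaskSpec(dt=0.01)
        spec_f = TaskSpec(dt=0.005)
        timing = GammaTiming(2, 1)
        tc = solve_relative_values(spec_c, timing, INDIRECT)
        tf = solve_relative_values(spec_f, timing, INDIRECT)
        sel = tc.t_grid <= 15.0
        diff = np.abs(np.interp(tc.t_grid[sel], tf.t_grid, tf.v1) - tc.v1[sel])
        assert diff.max() < 0.01 * np.abs(tc.v1[sel]).max()


class TestTdTrace:
    def test_flat_hazard_waiting_signal_constant(self):
        spec = TaskSpec()
        table = solve_relative_values(spec, GammaTiming(1, 1), INDIRECT)
        tr = td_trace(spec, table, T=8.0, mode=INDIRECT)
        t = tr.delta_p.times
        wait = tr.delta_p.values[(t > 0.5) & (t < 7.5)]
        assert wait.max() - wait.min() < 1e-6

    def test_efference_transient_constant_under_flat_hazard(self):
        table = solve_relative_values(TaskSpec(), GammaTiming(1, 1), INDIRECT)
        vals = [efference_transient(table, T) for T in (1.0, 3.0, 10.0)]
        assert np.ptp(vals) < 1e-6
        assert vals[0] > 0

    def test_efference_transient_decreases_with_increasing_hazard(self):
        table = solve_relative_values(TaskSpec(), GammaTiming(2, 1), INDIRECT)
        v1, v3, v10 = (efference_transient(table, T) for T in (1.0, 3.0, 10.0))
        assert v1 > v3 > v10 > 0

    def test_direct_mode_press_transient_increases_with_latency(self):
        """Timing uncertainty grows with tau, so later presses surprise more."""
        spec = TaskSpec()
        table = solve_relative_values(
            spec, GammaTiming(2, 1), DIRECT, tau_grid=np.array([1.0, 3.0, 10.0])
        )
        v1, v3, v10 = (efference_transient(table, T, tau=T) for T in (1.0, 3.0, 10.0))
        assert 0 < v1 < v3 < v10

    def test_direct_report_transient_nonincreasing_in_tau(self):
        """The report of a long latency is bad news (low relative value)."""
        spec = TaskSpec()
        taus = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0])
        table = solve_relative_values(spec, GammaTiming(2, 1), DIRECT, tau_grid=taus)
        steps = [
            table.v1_at(DIRECT.epsilon, tau) - (table.v10 + table.rho * DIRECT.epsilon)
            for tau in taus
        ]
        assert np.all(np.diff(steps) < 0)
        assert steps[-1] < 0  # long choices produce a pronounced negative error

    def test_events_and_latency_class(self):
        spec = TaskSpec()
        table = solve_relative_values(spec, GammaTiming(2, 1), INDIRECT)
        tr = td_trace(spec, table, T=2.0, mode=INDIRECT)
        assert tr.events["press"] == pytest.approx(2.5)
        assert tr.latency_class == "short"
        assert td_trace(spec, table, T=6.0, mode=INDIRECT).latency_class == "long"
        with pytest.raises(ValueError):
            td_trace(spec, table, T=100.0, mode=INDIRECT)

    def test_unbiasedness_over_session(self):
        """Time-average of delta^p approximates rho (full error averages ~0).

        Uses the lumped-interval convention, where all value changes are
        event impulses and the per-cycle impulse sum telescopes to the
        cycle's reward.
        """
        spec = TaskSpec(track_intervals=False)
        timing = GammaTiming(2, 1)
        table = solve_relative_values(spec, timing, INDIRECT)
        rng = np.random.default_rng(99)
        total, duration = 0.0, 0.0
        for T in timing.rvs(300, rng):
            T = min(T, spec.horizon - 1)
            tr = td_trace(spec, table, T=T, mode=INDIRECT)
            t = tr.delta_p.times
            sel = (t >= -tr.delta_p.dt / 2) & (t < tr.press_time + tr.delta_p.dt / 2)
            total += tr.delta_p.values[sel].sum() * tr.delta_p.dt
            duration += T + spec.tau_post + spec.tau_I
        assert total / duration == pytest.approx(table.rho, rel=0.02)


class TestSimulateExperiment:
    def test_bitwise_determinism(self):
        kwargs = dict(
            spec=TaskSpec(), timing=GammaTiming(2, 1), mode=DIRECT,
            asym=AsymmetryRule(), n=40, seed=7,
        )
        a = simulate_experiment(**kwargs)
        b = simulate_experiment(**kwargs)
        np.testing.assert_array_equal(a["trials"]["T"], b["trials"]["T"])
        np.testing.assert_array_equal(
            a["cue_aligned"].mean.values, b["cue_aligned"].mean.values
        )
        np.testing.assert_array_equal(
            a["trials"]["press_peak"], b["trials"]["press_peak"]
        )

    def test_structure_and_classes(self):
        out = simulate_experiment(
            TaskSpec(), GammaTiming(2, 1), DIRECT, n=60, seed=3
        )
        assert out["cue_aligned"].n <= 60
        summary = {(r["class"], r["window"]): r for r in out["peak_summary"]}
        assert len(summary) == 4
        ns = {r["n"] for r in out["peak_summary"]}
        assert sum(sorted(ns)) in (60, 60 + min(ns))  # classes partition trials
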