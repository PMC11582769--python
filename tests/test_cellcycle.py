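import numpy as np
import pytest

from estrocycle.params import CellCycleParams
from estrocycle.cellcycle import (
    classify_phases,
    cycle_rhs,
    detect_oscillation,
    find_limit_cycle,
    phase_durations_insilico,
    sample_initial_states,
    simulate_cycle,
    simulate_coupled,
)
from estrocycle.signaling import E2Input


def base_rhs_oracle(c, a, p):
    """Independent transcription of the base oscillator equations."""
    dc = (
        p.a1
        - p.b1 * c * a ** p.n1 / (p.K1 ** p.n1 + a ** p.n1)
        + p.a3 * (1 - c) * c ** p.n3 / (p.K3 ** p.n3 + c ** p.n3)
    )
    da = p.a2 * (1 - a) * c ** p.n2 / (p.K2 ** p.n2 + c ** p.n2) - p.b2 * a
    return np.array([dc, da])


class TestCycleRhs:
    def test_reduces_to_base_model(self):
        """k_GREB1 = 0 and r*E2_ER*PR = 1 reproduce the uncoupled oscillator
        exactly at sampled states."""
        p = CellCycleParams.base()
        rng = np.random.default_rng(0)
        for _ in range(25):
            c, a = rng.uniform(0, 1.2), rng.uniform(0, 1)
            got = cycle_rhs((c, a), p, GREB1=0.0, E2_ER=1.0, PR=1.0)
            want = base_rhs_oracle(c, a, p)
            assert np.allclose(got, want, rtol=1e-13, atol=1e-16)

    def test_apc_saturation_blocks_further_activation(self):
        p = CellCycleParams.base()
        dc, da = cycle_rhs((0.5, 1.0), p, GREB1=0.0, E2_ER=1.0, PR=1.0)
        assert da <= 0.0

    def test_apc_stays_in_unit_interval_and_cdk1_nonnegative(self):
        p = CellCycleParams.base()
        traj = simulate_cycle(p, np.linspace(0, 100, 2001), y0=(0.9, 0.99))
        assert traj["APC"].min() >= -1e-9 and traj["APC"].max() <= 1.0 + 1e-9
        assert traj["CDK1"].min() >= -1e-9

    def test_no_estrogen_drive_arrests_with_cdk1_low(self):
        # E2_ER * PR = 0: APC saturates, CDK1 settles low, no recurrent spikes
        p = CellCycleParams.base()
        t = np.linspace(0, 300, 3001)
        traj = simulate_cycle(p, t, y0=(0.6, 0.3), inputs=(0.0, 0.0, 0.0))
        osc = detect_oscillation(traj.times, traj["CDK1"])
        assert not osc.oscillates
        tail = traj["CDK1"][t > 200]
        assert tail.max() < 0.25


class TestDetectOscillation:
    def test_constant_series_does_not_oscillate(self):
        t = np.linspace(0, 100, 200)
        res = detect_oscillation(t, np.ones_like(t))
        assert not res.oscillates and res.period is None

    def test_synthetic_sinusoid_period(self):
        t = np.arange(0, 240.0, 1.0)
        res = detect_oscillation(t, np.sin(2 * np.pi * t / 48.0) + 1.0, t_tail=240.0)
        assert res.oscillates
        assert res.period == pytest.approx(48.0, abs=0.5)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            detect_oscillation(np.arange(5.0), np.arange(5.0))


class TestTimeRescaling:
    def test_elevenfold_slowdown_multiplies_period_by_eleven(self):
        base = CellCycleParams.base()
        _, p_base = find_limit_cycle(base, period_guess=5.0)
        _, p_slow = find_limit_cycle(base.slowed(11.0), period_guess=11 * p_base)
        assert p_slow / p_base == pytest.approx(11.0, rel=0.01)
        assert 45.0 < p_slow < 55.0


class TestOscillationBounds:
    """The coupled oscillator loses its limit cycle when the GREB1 drive is
    too strong or the APC inactivation drive leaves a finite band."""

    def _oscillates(self, params, inputs):
        t = np.linspace(0, 800, 8001)
        traj = simulate_cycle(params, t, inputs=inputs)
        return detect_oscillation(traj.times, traj["CDK1"]).oscillates

    def test_default_drive_oscillates(self, cyc_params, culture_state):
        inputs = (culture_state["GREB1"], culture_state["E2_ER"], culture_state["PR"])
        assert self._oscillates(cyc_params, inputs)

    def test_large_greb1_drive_kills_oscillation(self, cyc_params, culture_state):
        strong = cyc_params.replace(k_GREB1=0.01)
        inputs = (culture_state["GREB1"], culture_state["E2_ER"], culture_state["PR"])
        assert not self._oscillates(strong, inputs)

    @pytest.mark.parametrize("factor", [0.02, 20.0])
    def test_apc_drive_outside_band_kills_oscillation(
        self, cyc_params, culture_state, factor
    ):
        inputs = (culture_state["GREB1"], culture_state["E2_ER"], culture_state["PR"])
        tweaked = cyc_params.replace(r=cyc_params.r * factor)
        assert not self._oscillates(tweaked, inputs)


class TestCoupling:
    def test_one_way_coupling_leaves_signaling_untouched(self, sig_params, cyc_params):
        t = np.linspace(0, 50, 101)
        a = simulate_coupled(sig_params, cyc_params, E2Input.clamp(0.156), t,
                             y0_cyc=(0.2, 0.1))
        b = simulate_coupled(sig_params, cyc_params, E2Input.clamp(0.156), t,
                             y0_cyc=(0.9, 0.6))
        n_sig = a.states.shape[1] - 2
        assert np.array_equal(a.states[:, :n_sig], b.states[:, :n_sig])

    def test_e2_free_steady_state_means_arrest(self, sig_params, cyc_params):
        t = np.linspace(0, 300, 3001)
        traj = simulate_coupled(sig_params, cyc_params, E2Input.clamp(0.0), t)
        assert not detect_oscillation(traj.times, traj["CDK1"]).oscillates


class TestClassifyPhases:
    @staticmethod
    def _triangle(times, t_min, v_min, t_max, v_max, v_edge):
        v = np.empty_like(times)
        for i, t in enumerate(times):
            if t <= t_min:
                v[i] = v_edge + (v_min - v_edge) * t / t_min
            elif t <= t_max:
                v[i] = v_min + (v_max - v_min) * (t - t_min) / (t_max - t_min)
            else:
                v[i] = v_max - (v_max - v_edge * 0.9) * (t - t_max) / (times[-1] - t_max)
        return v

    def test_threshold_is_minimum_plus_five_percent_of_rise(self):
        t = np.linspace(0, 20, 201)
        apc = self._triangle(t, 6.0, 0.2, 14.0, 1.0, 0.9)
        cdk1 = self._triangle(t, 10.0, 0.1, 16.0, 0.8, 0.6)
        seq = classify_phases(t, cdk1, apc)
        assert seq.apc_threshold == pytest.approx(0.2 + 0.05 * 0.8, abs=1e-6)

    def test_transitions_at_constructed_crossings(self):
        t = np.linspace(0, 20, 2001)
        apc = self._triangle(t, 6.0, 0.2, 14.0, 1.0, 0.9)
        cdk1 = self._triangle(t, 10.0, 0.1, 16.0, 0.8, 0.6)
        seq = classify_phases(t, cdk1, apc)
        thr = 0.24
        # analytic crossings of the triangle APC wave
        down = 6.0 * (0.9 - thr) / (0.9 - 0.2)
        up = 6.0 + 8.0 * (thr - 0.2) / (1.0 - 0.2)
        kinds = dict(zip(seq.transition_kinds, seq.transition_times))
        assert kinds["g1_to_g1s"] == pytest.approx(down, abs=0.02)
        assert kinds["g1s_to_sg2m"] == pytest.approx(up, abs=0.02)
        assert kinds["division"] == pytest.approx(10.0, abs=0.02)

    def test_monotone_cdk1_after_minimum_reads_as_arrest(self):
        t = np.linspace(0, 50, 501)
        cdk1 = 0.05 + 0.001 * t
        apc = np.full_like(t, 0.98)
        seq = classify_phases(t, cdk1, apc)
        assert seq.arrest and set(seq.phases) == {"G1"}


class TestPhaseDurations:
    def _classified_cycle(self, cyc_params, culture_state, n_cycles=4):
        inputs = (culture_state["GREB1"], culture_state["E2_ER"], culture_state["PR"])
        traj, period = find_limit_cycle(cyc_params, inputs=inputs)
        return traj, period

    def test_full_cycle_durations_sum_to_period(self, cyc_params, culture_state):
        traj, period = self._classified_cycle(cyc_params, culture_state)
        # classify the settled tail (the APC threshold is frozen from the
        # first minimum, which must lie on the limit cycle, not the transient)
        sel = traj.times >= traj.times[-1] - 5 * period
        seq = classify_phases(traj.times[sel], traj["CDK1"][sel], traj["APC"][sel])
        recs = phase_durations_insilico(seq)
        by_cycle = {}
        for r in recs:
            by_cycle.setdefault(r.cycle_index, {})[r.phase] = r.duration_h
        full = [v for v in by_cycle.values() if set(v) == {"G1", "G1S", "SG2M"}]
        assert full, "expected at least one complete cycle"
        grid = float(np.diff(traj.times).max())
        for cycle in full:
            assert sum(cycle.values()) == pytest.approx(period, abs=2 * grid)

    def test_truncated_leading_and_trailing_phases_not_reported(self):
        t = np.linspace(0, 20, 2001)
        apc = TestClassifyPhases._triangle(t, 6.0, 0.2, 14.0, 1.0, 0.9)
        cdk1 = TestClassifyPhases._triangle(t, 10.0, 0.1, 16.0, 0.8, 0.6)
        seq = classify_phases(t, cdk1, apc)
        recs = phase_durations_insilico(seq)
        # every record is bounded by two interior events
        assert all(r.start_h > t[0] and r.end_h < t[-1] for r in recs)


class TestInitialStateSampling:
    def test_seed_contract(self, cyc_params, culture_state):
        inputs = (culture_state["GREB1"], culture_state["E2_ER"], culture_state["PR"])
        traj, period = find_limit_cycle(cyc_params, inputs=inputs)
        a = sample_initial_states(traj, period, 10, seed=1)
        b = sample_initial_states(traj, period, 10, seed=1)
        c = sample_initial_states(traj, period, 10, seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_samples_lie_on_the_cycle(self, cyc_params, culture_state):
        inputs = (culture_state["GREB1"], culture_state["E2_ER"], culture_state["PR"])
        traj, period = find_limit_cycle(cyc_params, inputs=inputs)
        pts = sample_initial_states(traj, period, 50, seed=3)
        tail = traj.states[traj.times >= traj.times[-1] - period]
        for pt in pts:
            d = np.min(np.linalg.norm(tail - pt, axis=1))
            assert d < 0.02

    def test_no_limit_cycle_rejected(self, cyc_params, culture_state):
        inputs = (culture_state["GREB1"], culture_state["E2_ER"], culture_state["PR"])
        traj, period = find_limit_cycle(cyc_params, inputs=inputs)
        with pytest.raises(ValueError):
            sample_initial_states(traj, 0.0, 5, seed=0)
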