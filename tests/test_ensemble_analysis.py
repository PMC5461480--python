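"""Photobleaching motor counting and stall-force analysis, checked
against the binomial-bleaching and saw-tooth generators."""

import numpy as np
import pytest

from myovasim.ensemble_analysis import (
    BleachTrace,
    detect_peak_forces,
    intensity_per_fluorophore,
    motor_count,
    stall_mixture,
)
from myovasim.synthetic_data import gen_bleach_traces, gen_trap_trace


class TestIntensityPerFluorophore:
    def test_binomial_oracle_recovery(self):
        t, I = gen_bleach_traces(n_fluorophores=20, v=100.0, tau=10.0,
                                 n_traces=200, duration=40.0, seed=0)
        v = intensity_per_fluorophore(BleachTrace(t, I))
        assert v == pytest.approx(100.0, rel=0.10)

    def test_constant_trace_rejected(self):
        t, I = gen_bleach_traces(n_fluorophores=5, v=50.0, tau=float("inf"),
                                 n_traces=20, duration=10.0, seed=1)
        with pytest.raises(ValueError):
            intensity_per_fluorophore(BleachTrace(t, I))

    def test_zero_variance_rejected(self):
        t = np.arange(0, 10, 0.1)
        I = np.tile(100 * np.exp(-t / 3.0), (5, 1))
        with pytest.raises(ValueError):
            intensity_per_fluorophore(BleachTrace(t, I))


class TestMotorCount:
    def test_formula(self):
        t = np.arange(0, 20, 0.1)
        I = np.tile(500.0 * np.exp(-t / 5.0), (3, 1))
        n = motor_count(BleachTrace(t, I), v=100.0)
        assert n == pytest.approx(10.0)

    def test_scale_invariance(self):
        t, I = gen_bleach_traces(n_fluorophores=20, v=100.0, tau=10.0,
                                 n_traces=150, seed=2)
        n1 = motor_count(BleachTrace(t, I))
        n2 = motor_count(BleachTrace(t, 7.3 * I))
        assert n2 == pytest.approx(n1, rel=1e-6)

    def test_count_recovers_generated_fluorophore_number(self):
        """On an N-fluorophore ensemble the published formula returns
        2N (I0 = N v), so the generated truth is recovered exactly up to
        the v-estimation error."""
        t, I = gen_bleach_traces(n_fluorophores=20, v=100.0, tau=10.0,
                                 n_traces=300, duration=40.0, seed=3)
        n = motor_count(BleachTrace(t, I))
        assert n == pytest.approx(40.0, rel=0.15)


class TestDetectPeakForces:
    def test_recovers_synthetic_event_count_exactly(self):
        t, f = gen_trap_trace(stall_mean=1.9, n_events=8, noise_sd=0.0, seed=0)
        events = detect_peak_forces(t, f, trap_stiffness=0.019)
        assert len(events) == 8
        assert all(e.peak_force == pytest.approx(1.9, abs=1e-9)
                   for e in events)

    def test_noisy_peak_means_within_five_percent(self):
        t, f = gen_trap_trace(stall_mean=4.0, n_events=12, noise_sd=0.1,
                              frame_interval=0.002, seed=1)
        events = detect_peak_forces(t, f, trap_stiffness=0.019)
        assert len(events) >= 10
        mean = np.mean([e.peak_force for e in events])
        assert mean == pytest.approx(4.0, rel=0.05)

    def test_monotone_rising_trace_has_no_events(self):
        t = np.arange(0, 5, 0.02)
        f = 0.019 * 100.0 * t
        assert detect_peak_forces(t, f, 0.019) == []

    def test_subthreshold_ramp_ignored(self):
        t, f = gen_trap_trace(stall_mean=1.9, n_events=3, ramp_v=30.0, seed=2)
        assert detect_peak_forces(t, f, 0.019) == []

    def test_offset_invariance(self):
        t, f = gen_trap_trace(stall_mean=2.5, n_events=6, seed=3)
        e0 = detect_peak_forces(t, f, 0.019)
        e1 = detect_peak_forces(t, f + 3.0, 0.019)
        assert len(e0) == len(e1)
        for a, b in zip(e0, e1):
            assert b.peak_force - a.peak_force == pytest.approx(3.0)

    def test_event_count_non_increasing_in_threshold(self):
        t, f = gen_trap_trace(stall_mean=2.0, n_events=6, ramp_v=80.0, seed=4)
        n_low = len(detect_peak_forces(t, f, 0.019, v_threshold=30.0))
        n_high = len(detect_peak_forces(t, f, 0.019, v_threshold=70.0))
        assert n_high <= n_low

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_peak_forces(np.arange(3) * 0.02, np.zeros(3), 0.019)


class TestStallMixture:
    @staticmethod
    def _three_component_sample(seed, n=400):
        rng = np.random.default_rng(seed)
        parts = [rng.normal(1.9, 0.7, int(0.4 * n)),
                 rng.normal(4.1, 0.6, int(0.35 * n)),
                 rng.normal(5.9, 0.4, n - int(0.4 * n) - int(0.35 * n))]
        return np.concatenate(parts)

    def test_recovers_three_components_at_printed_parameters(self):
        x = self._three_component_sample(0)
        k, comps, _ = stall_mixture(x, seed=0)
        assert k == 3
        means = [m for m, _, _ in comps]
        assert means[0] == pytest.approx(1.9, abs=0.3)
        assert means[1] == pytest.approx(4.1, abs=0.3)
        assert means[2] == pytest.approx(5.9, abs=0.3)

    def test_single_gaussian_selects_one(self):
        rng = np.random.default_rng(1)
        k, comps, _ = stall_mixture(rng.normal(3.0, 0.5, 300), seed=0)
        assert k == 1
        assert comps[0][0] == pytest.approx(3.0, abs=0.1)

    def test_component_mean_bias_below_point_two(self):
        """Bias of the recovered lowest/highest component means over
        replicates stays under 0.2 pN at n=400."""
        lows, highs = [], []
        for rep in range(20):
            x = self._three_component_sample(100 + rep)
            k, comps, _ = stall_mixture(x, seed=0)
            if k == 3:
                lows.append(comps[0][0])
                highs.append(comps[2][0])
        assert len(lows) >= 15
        assert abs(np.mean(lows) - 1.9) < 0.2
        assert abs(np.mean(highs) - 5.9) < 0.2

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            stall_mixture(np.ones(10))
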