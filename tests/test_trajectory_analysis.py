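"""Measurement procedures: helix fit, approach angle, filament
separation, outcome classification, Kaplan-Meier run lengths, heatmap."""

import math
import warnings

import numpy as np
import pytest

from myovasim import SimConfig, make_intersection, run_intersection
from myovasim.synthetic_data import NoiseModel, gen_filament_cloud, \
    gen_helical_trajectory
from myovasim.trajectory_analysis import (
    RunRecord,
    approach_angle,
    classify_outcome,
    filament_separation,
    fit_helix,
    km_run_length,
    straight_turn_heatmap,
)
from myovasim.transport_simulator import OutcomeRecord


class TestFitHelix:
    def test_noiseless_recovery_exact(self):
        t, c = gen_helical_trajectory(pitch=2000.0, radius=200.0,
                                      velocity=400.0, handedness="left",
                                      duration=30.0,
                                      noise=NoiseModel(0, 0, 0), seed=0)
        fit = fit_helix(c, t)
        assert fit.handedness == "left"
        assert fit.pitch == pytest.approx(2000.0, abs=1.0)
        assert fit.velocity == pytest.approx(400.0, rel=1e-3)

    def test_noisy_recovery_within_ten_percent(self):
        t, c = gen_helical_trajectory(pitch=2160.0, radius=225.0,
                                      velocity=423.0, handedness="left",
                                      duration=30.0, noise=NoiseModel(),
                                      seed=4)
        fit = fit_helix(c, t)
        assert fit.handedness == "left"
        assert fit.pitch == pytest.approx(2160.0, rel=0.10)

    def test_handedness_flips_with_generator(self):
        for hand in ("left", "right"):
            t, c = gen_helical_trajectory(pitch=2000.0, handedness=hand,
                                          duration=25.0,
                                          noise=NoiseModel(5, 5, 5), seed=1)
            assert fit_helix(c, t).handedness == hand

    def test_straight_line_is_non_helical(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 20, 0.1)
        c = np.column_stack([rng.normal(0, 17, len(t)),
                             400 * t + rng.normal(0, 18, len(t)),
                             rng.normal(0, 30, len(t))])
        fit = fit_helix(c, t)
        assert fit.handedness == "non_helical"
        assert fit.velocity == pytest.approx(400.0, rel=0.02)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_helix(np.zeros((5, 3)), np.arange(5.0))


class TestApproachAngle:
    def _traj(self, alpha_deg, n=30):
        """Straight approach at a fixed azimuth about the original filament
        (0 deg = intersecting side = +z)."""
        a = math.radians(alpha_deg)
        t = np.arange(n) * 0.1
        y = -2000.0 + 450.0 * t
        x = 204.0 * math.sin(a) * np.ones(n)
        z = 204.0 * math.cos(a) * np.ones(n)
        return np.column_stack([x, y, z])

    @pytest.mark.parametrize("alpha", [0.0, 90.0, 180.0, 270.0])
    def test_cardinal_angles(self, alpha):
        inter = make_intersection(100.0, 1)
        got = approach_angle(self._traj(alpha), inter)
        diff = (got - alpha + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-6

    def test_mirror_reflection_negates_angle(self):
        inter = make_intersection(100.0, 1)
        traj = self._traj(73.0)
        mirrored = traj.copy()
        mirrored[:, 0] *= -1.0
        a = approach_angle(traj, inter)
        am = approach_angle(mirrored, inter)
        assert am == pytest.approx((360.0 - a) % 360.0, abs=1e-6)

    def test_insufficient_frames_rejected(self):
        inter = make_intersection(100.0, 1)
        with pytest.raises(ValueError):
            approach_angle(self._traj(0.0, n=5), inter)


class TestFilamentSeparation:
    def test_noiseless_difference(self):
        a = gen_filament_cloud(100.0, sigma_z=0.0, n_points=50, seed=0)
        b = gen_filament_cloud(30.0, sigma_z=0.0, n_points=50, seed=1)
        d, flagged = filament_separation(a, b)
        assert d == pytest.approx(70.0, abs=1e-9)
        assert not flagged

    def test_noisy_within_standard_error(self):
        a = gen_filament_cloud(150.0, sigma_z=5.0, n_points=200, seed=2)
        b = gen_filament_cloud(80.0, sigma_z=5.0, n_points=200, seed=3)
        d, _ = filament_separation(a, b)
        assert d == pytest.approx(70.0, abs=1.5)  # ~3 * sqrt(2)*5/sqrt(200)

    def test_cloud_against_itself_is_zero(self):
        a = gen_filament_cloud(100.0, seed=4)
        d, _ = filament_separation(a, a)
        assert d == 0.0

    def test_beyond_cutoff_flagged(self):
        a = gen_filament_cloud(300.0, sigma_z=0.0, n_points=20, seed=5)
        b = gen_filament_cloud(0.0, sigma_z=0.0, n_points=20, seed=6)
        _, flagged = filament_separation(a, b)
        assert flagged

    def test_small_clouds_rejected(self):
        with pytest.raises(ValueError):
            filament_separation(np.zeros((3, 3)), np.zeros((20, 3)))


class TestClassifyOutcome:
    def test_agrees_with_simulator_record(self):
        agree, total = 0, 0
        for seed in (3, 11, 19, 27, 35, 43):
            inter = make_intersection(90.0 + 10 * (seed % 3), 1)
            traj, rec = run_intersection(SimConfig(seed=seed, geometry=inter,
                                                   max_time=20.0))
            if not rec.reached:
                continue
            got = classify_outcome(traj, inter)
            total += 1
            if got == rec.outcome:
                agree += 1
        assert total >= 3
        assert agree >= total - 1  # measurement-vs-truth consistency

    def test_far_away_track_not_applicable(self):
        inter = make_intersection(100.0, 1)
        t = np.arange(20) * 0.1
        c = np.column_stack([np.zeros(20), -3000 + 100 * t,
                             200 * np.ones(20)])
        assert classify_outcome(c, inter) == "not_applicable"


class TestKaplanMeier:
    def test_uncensored_reduces_to_sample_mean(self):
        _, s = km_run_length([RunRecord(1000.0), RunRecord(2000.0),
                              RunRecord(3000.0)])
        assert s["mean"] == pytest.approx(2000.0, rel=1e-6)

    def test_hand_computed_product_limit(self):
        """{1000 observed, 2000 censored}: S(1000)=0.5 and survival beyond
        2000 unresolved, so the restricted mean is 1000 + 0.5*1000."""
        kmf, s = km_run_length([RunRecord(1000.0),
                                RunRecord(2000.0, censored=True)])
        assert float(kmf.predict(1000.0)) == pytest.approx(0.5)
        assert float(kmf.predict(1500.0)) == pytest.approx(0.5)
        assert s["mean"] == pytest.approx(1500.0, rel=1e-6)

    def test_survival_monotone_non_increasing(self):
        kmf, _ = km_run_length([RunRecord(float(x), censored=(x % 3 == 0))
                                for x in range(500, 4000, 250)])
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        assert all(b <= a + 1e-12 for a, b in zip(surv, surv[1:]))

    def test_all_censored_warns_lower_bound(self):
        with pytest.warns(UserWarning):
            _, s = km_run_length([RunRecord(1000.0, censored=True),
                                  RunRecord(2000.0, censored=True)])
        assert s["lower_bound_only"]


class TestHeatmap:
    def _rec(self, alpha, d, outcome):
        return OutcomeRecord(alpha=alpha, d=d, outcome=outcome,
                             dwell_at_intersection=1.0)

    def test_ratio_arithmetic(self):
        recs = [self._rec(30, 50, "straight")] * 10 + \
               [self._rec(30, 50, "turn_left")] * 5
        hm = straight_turn_heatmap(recs)
        assert hm["low_alpha_low_d"]["ratio"] == pytest.approx(2.0)
        assert hm["low_alpha_low_d"]["n"] == 15

    def test_zero_turn_regime_reports_infinity_with_counts(self):
        recs = [self._rec(100, 50, "straight")] * 4
        hm = straight_turn_heatmap(recs)
        assert hm["high_alpha_low_d"]["ratio"] == float("inf")
        assert hm["high_alpha_low_d"]["straight"] == 4

    def test_empty_regime_is_missing(self):
        hm = straight_turn_heatmap([])
        assert all(cell["ratio"] is None for cell in hm.values())

    def test_mirrored_angles_fold_into_same_regime(self):
        hm = straight_turn_heatmap([self._rec(330, 50, "straight"),
                                    self._rec(30, 50, "turn_left")])
        assert hm["low_alpha_low_d"]["n"] == 2
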