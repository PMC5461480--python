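"""Single-motor elastics, load-dependent kinetics, and the quasi-static
pose relaxation (checked against a brute-force grid oracle)."""

import math

import numpy as np
import pytest

from myovasim.actin_geometry import ActinFilament, site_position
from myovasim.motor_mechanics import (
    CargoPose,
    Motor,
    MotorParams,
    detachment_rate,
    equilibrate_pose,
    linkage_force,
    net_step_velocity,
    pose_energy,
    step_rates,
    torsion_energy,
)
from myovasim.actin_geometry import BindingSite

R = 175.0  # cargo radius at defaults


class TestLinkage:
    def test_zero_at_rest_length(self, motor_params):
        f = linkage_force([0, 0, 50.0], [0, 0, 0], motor_params)
        assert np.allclose(f, 0.0)

    def test_one_piconewton_per_nanometre(self, motor_params):
        f = linkage_force([0, 0, 52.0], [0, 0, 0], motor_params)
        assert np.linalg.norm(f) == pytest.approx(2.0)

    def test_slack_under_compression(self, motor_params):
        f = linkage_force([0, 0, 30.0], [0, 0, 0], motor_params)
        assert np.allclose(f, 0.0)


class TestTorsion:
    def _motor_on(self, fil, ref):
        site = BindingSite(0, 0, site_position(fil, 0), fil.site_azimuth(0))
        return Motor(head=site, bound_azimuth_ref=ref)

    def test_zero_at_reference(self, long_filament, motor_params):
        m = self._motor_on(long_filament, 0.0)
        pose = CargoPose(center=np.array([0.0, -5000.0, 200.0]))
        assert torsion_energy(m, pose, long_filament, motor_params) == \
            pytest.approx(0.0, abs=1e-12)

    def test_quarter_ktor_at_one_radian(self, long_filament, motor_params):
        m = self._motor_on(long_filament, 0.0)
        a = math.degrees(1.0)
        pose = CargoPose(center=np.array(
            [200 * math.sin(math.radians(a)), -5000.0,
             200 * math.cos(math.radians(a))]))
        e = torsion_energy(m, pose, long_filament, motor_params)
        assert e == pytest.approx(0.5 * motor_params.k_tor, rel=1e-9)

    def test_even_in_angle(self, long_filament, motor_params):
        m = self._motor_on(long_filament, 0.0)
        for s in (+1, -1):
            pose = CargoPose(center=np.array(
                [s * 200 * math.sin(0.7), -5000.0, 200 * math.cos(0.7)]))
            if s > 0:
                e_plus = torsion_energy(m, pose, long_filament, motor_params)
            else:
                e_minus = torsion_energy(m, pose, long_filament, motor_params)
        assert e_plus == pytest.approx(e_minus, rel=1e-9)

    def test_unbound_motor_rejected(self, long_filament, motor_params):
        with pytest.raises(ValueError):
            torsion_energy(Motor(), CargoPose(center=np.zeros(3)),
                           long_filament, motor_params)


class TestDetachment:
    def test_unloaded_rate(self, motor_params):
        assert detachment_rate(0.0, motor_params) == pytest.approx(0.35)

    def test_doubling_force_resistive(self, motor_params):
        f2 = motor_params.kBT * math.log(2.0) / motor_params.detach_distance
        assert detachment_rate(f2, motor_params) == pytest.approx(0.70)

    def test_assisting_load_detaches_faster(self, motor_params):
        assert detachment_rate(2.0, motor_params, assisting=True) > \
            detachment_rate(2.0, motor_params, assisting=False)

    def test_monotone_increasing(self, motor_params):
        rates = [detachment_rate(f, motor_params) for f in np.linspace(0, 10, 30)]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_negative_load_rejected(self, motor_params):
        with pytest.raises(ValueError):
            detachment_rate(-1.0, motor_params)


class TestStepping:
    def test_unloaded_velocity_matches_single_motor_transport(self, motor_params):
        v0 = net_step_velocity(0.0, motor_params)
        assert 400.0 < v0 < 560.0

    def test_velocity_vanishes_at_stall(self, motor_params):
        assert abs(net_step_velocity(motor_params.stall_force, motor_params)) \
            < 1e-6

    def test_net_negative_beyond_stall(self, motor_params):
        assert net_step_velocity(motor_params.stall_force + 0.5,
                                 motor_params) < 0

    def test_velocity_strictly_decreasing(self, motor_params):
        v = [net_step_velocity(f, motor_params) for f in np.linspace(0, 5, 40)]
        assert all(b < a for a, b in zip(v, v[1:]))

    def test_forward_down_backward_up_with_load(self, motor_params):
        l0, s0, b0 = step_rates(0.0, motor_params)
        l2, s2, b2 = step_rates(2.0, motor_params)
        assert l2 < l0 and b2 > b0

    def test_assisting_load_treated_as_unloaded(self, motor_params):
        assert step_rates(-3.0, motor_params) == step_rates(0.0, motor_params)


class TestEquilibratePose:
    def test_already_minimal_pose_unchanged(self, long_filament, motor_params):
        head = site_position(long_filament, 1818)
        c0 = head + np.array([0.0, 0.0, R + motor_params.rest_length])
        ref = long_filament.azimuth_of(c0)  # torsion-neutral at the start
        pose = equilibrate_pose(c0, [(head, ref, long_filament)],
                                [long_filament], R, motor_params)
        assert np.linalg.norm(pose.center - c0) < 1.0
        assert pose.energy < 1e-6

    def test_two_symmetric_motors_centre_equidistant(self, long_filament,
                                                     motor_params):
        # heads far enough apart that the slack regions do not intersect,
        # so both linkages are taut at equilibrium
        h1 = long_filament.axis_point(-200.0)
        h2 = long_filament.axis_point(200.0)
        c0 = np.array([0.0, 10.0, 260.0])  # off-centre start
        bound = [(h1, 0.0, long_filament), (h2, 0.0, long_filament)]
        pose = equilibrate_pose(c0, bound, [long_filament], R, motor_params)
        d1 = np.linalg.norm(pose.center - h1)
        d2 = np.linalg.norm(pose.center - h2)
        assert d1 == pytest.approx(d2, rel=1e-3)

    def test_never_increases_energy(self, long_filament, motor_params):
        rng = np.random.default_rng(5)
        for _ in range(10):
            heads = [long_filament.axis_point(float(rng.uniform(-150, 150)))
                     for _ in range(2)]
            bound = [(h, float(rng.uniform(0, 360)), long_filament)
                     for h in heads]
            c0 = np.array([rng.uniform(-100, 100), rng.uniform(-100, 100),
                           rng.uniform(180, 300)])
            e0, _ = pose_energy(c0, bound, [long_filament], R, motor_params)
            pose = equilibrate_pose(c0, bound, [long_filament], R, motor_params)
            assert pose.energy <= e0 + 1e-9

    def test_matches_brute_force_grid_on_two_motor_instances(
            self, long_filament, motor_params):
        """Relaxed energy within 1% (or 0.01 pN nm) of a dense grid search
        refined by local descent -- the independent oracle."""
        rng = np.random.default_rng(17)
        for _ in range(4):
            heads = [long_filament.axis_point(float(rng.uniform(-120, 120)))
                     for _ in range(2)]
            bound = [(h, float(rng.uniform(-40, 40)), long_filament)
                     for h in heads]
            c0 = np.array([rng.uniform(-80, 80), rng.uniform(-80, 80),
                           rng.uniform(200, 280)])
            pose = equilibrate_pose(c0, bound, [long_filament], R, motor_params)
            # brute force: coarse grid then a fine grid around the best cell
            best = None
            grid = np.linspace(-300, 300, 25)
            zs = np.linspace(150, 320, 15)
            for x in grid:
                for y in grid:
                    for z in zs:
                        e, _ = pose_energy(np.array([x, y, z]), bound,
                                           [long_filament], R, motor_params)
                        if best is None or e < best[0]:
                            best = (e, np.array([x, y, z]))
            fine = best[1]
            for x in np.linspace(fine[0] - 15, fine[0] + 15, 9):
                for y in np.linspace(fine[1] - 15, fine[1] + 15, 9):
                    for z in np.linspace(fine[2] - 15, fine[2] + 15, 9):
                        e, _ = pose_energy(np.array([x, y, z]), bound,
                                           [long_filament], R, motor_params)
                        if e < best[0]:
                            best = (e, np.array([x, y, z]))
            assert pose.energy <= best[0] * 1.01 + 0.01

    def test_no_bound_motors_rejected(self, long_filament, motor_params):
        with pytest.raises(ValueError):
            equilibrate_pose(np.zeros(3), [], [long_filament], R, motor_params)

    def test_respects_excluded_volume(self, long_filament, motor_params):
        head = long_filament.axis_point(0.0)
        # start deliberately inside the filament
        c0 = head + np.array([0.0, 0.0, 100.0])
        pose = equilibrate_pose(c0, [(head, 0.0, long_filament)],
                                [long_filament], R, motor_params)
        rel = pose.center - long_filament.origin
        ax = rel @ long_filament.direction
        perp = np.linalg.norm(rel - ax * long_filament.direction)
        assert perp > R + long_filament.radius - 1.0  # penalty-softened contact
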