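"""Event-driven stochastic engine for ensemble cargo transport.

The simulation is a Gillespie loop over discrete motor events -- binding,
unbinding and long/short/backward steps -- whose propensities are evaluated
at the current quasi-statically relaxed cargo pose and frozen until the next
event.  After every event the cargo centre re-equilibrates (re-centring over
the bound motors), which is what lets an ensemble spiral around the actin
helix, hesitate at a structural barrier and resolve a tug-of-war at an
intersection.  Membrane-anchor diffusion (0.92 um^2/s) relaxes far faster
than the kinetics, so free anchors are treated as uniformly distributed on
the sphere and enter only through the ensemble attachment propensity.

Three geometries are supported: a single suspended filament (spiralling
runs), a 3D intersection of two nearly perpendicular filaments (directional
outcomes) and a harmonic laser trap on a single filament (stall forces).
Identical configuration + seed reproduces the event log bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .actin_geometry import (
    ActinFilament,
    BindingSite,
    IntersectionGeometry,
    InteractionParams,
    site_position,
)
from .motor_mechanics import (
    D_LONG,
    STEP_LONG_SUBUNITS,
    STEP_SHORT_SUBUNITS,
    Motor,
    MotorParams,
    attachment_propensity,
    detachment_rate,
    equilibrate_pose,
    linkage_tension,
    pose_energy,
    step_rates,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "OutcomeRecord",
    "make_intersection",
    "simulate",
    "run_intersection",
    "run_trap",
    "engaged_motor_census",
]

Outcome = Literal["straight", "turn_left", "turn_right", "terminate"]

# Axial half-width of the "at the intersection" zone used for the dwell
# clock: cargo radius + motor reach (a cargo closer than this can be in
# mechanical contact with the crossing).
_DWELL_HALFWIDTH = 225.0
# A run has committed to an exit once its centre is this far from the
# crossing along the exit filament (beyond any interaction range).
_EXIT_MARGIN = 500.0
_CONTACT_DRAG_FACTOR = 1.0


@dataclass
class SimConfig:
    """Configuration of one simulation run.

    ``geometry`` selects the scenario: ``"single_filament"``, ``"trap"`` or
    an :class:`IntersectionGeometry`.  ``membrane_D`` is carried for
    completeness (fast-diffusion limit; see docs/methods.md).
    """

    seed: int
    geometry: IntersectionGeometry | str = "single_filament"
    cargo_diameter: float = 350.0
    n_motors: int = 10
    membrane_D: float = 0.92          # um^2/s, anchor diffusion on the membrane
    trap_stiffness: float = 0.019     # pN/nm
    frame_interval: float = 0.1       # s, analysis parity with 100 ms video
    max_time: float = 12.0            # s
    intersection_dwell_limit: float = 10.0  # s
    filament_length: float = 6000.0   # nm, single-filament / trap track
    start_axial: float = 200.0        # nm, initial binding site position
    azimuth_diffusion: bool = False   # thermal azimuth mode at barriers
    init_azimuth: float | None = None  # deg; None -> uniform random
    motor: MotorParams = field(default_factory=MotorParams)

    def __post_init__(self) -> None:
        if self.n_motors < 0:
            raise ValueError("n_motors must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.cargo_diameter <= 0:
            raise ValueError("cargo_diameter must be positive")
        if self.trap_stiffness < 0:
            raise ValueError("trap_stiffness must be non-negative")

    @property
    def interaction_params(self) -> InteractionParams:
        return InteractionParams(cargo_diameter=self.cargo_diameter,
                                 motor_reach=self.motor.rest_length)


@dataclass
class Trajectory:
    """Sampled cargo trajectory plus the exact event log."""

    times: np.ndarray                  # (n,) s
    centers: np.ndarray                # (n, 3) nm
    engaged_per_filament: np.ndarray   # (n, n_filaments) int
    events: list[dict]
    filaments: list[ActinFilament]
    terminal: str = "time"             # time | all_detached | reached_end | outcome
    forces: np.ndarray | None = None   # (n,) pN, trap runs only
    attached_time_by_count: dict[int, list[float]] = field(default_factory=dict)


@dataclass
class OutcomeRecord:
    """Directional outcome of one intersection transit."""

    alpha: float           # measured approach angle, deg in [0, 360)
    d: float               # filament separation, nm
    outcome: Outcome
    dwell_at_intersection: float  # s spent within reach of the crossing
    reached: bool = True   # cargo came within reach of the crossing


def make_intersection(
    separation_d: float,
    intersecting_polarity: int = 1,
    approach_length: float = 2500.0,
) -> IntersectionGeometry:
    """Standard intersection scene: the original filament runs South->North
    (+y, plus end North) through the origin; the intersecting filament runs
    East-West at height ``separation_d`` above it, plus end East for
    polarity +1 (so turns onto it head East = turn right)."""
    original = ActinFilament(
        origin=[0.0, -approach_length, 0.0], direction=[0.0, 1.0, 0.0],
        length=approach_length + 2000.0, polarity=1)
    intersecting = ActinFilament(
        origin=[-2500.0, 0.0, separation_d], direction=[1.0, 0.0, 0.0],
        length=5000.0, polarity=intersecting_polarity)
    return IntersectionGeometry(original=original, intersecting=intersecting,
                                separation_d=separation_d)


class _Engine:
    """Internal mutable simulation state and the Gillespie loop."""

    def __init__(self, config: SimConfig, filaments: list[ActinFilament],
                 trap: bool = False):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.filaments = filaments
        self.trap = trap
        self.trap_center: np.ndarray | None = None
        self.geom = config.interaction_params
        self.R = config.cargo_diameter / 2.0
        self.motors = [Motor() for _ in range(config.n_motors)]
        self.occupied: list[set[int]] = [set() for _ in filaments]
        self.center = np.zeros(3)
        self.t = 0.0
        self.events: list[dict] = []
        self.frames_t: list[float] = []
        self.frames_c: list[np.ndarray] = []
        self.frames_n: list[list[int]] = []
        self.frames_f: list[float] = []
        self.count_time: dict[int, list[float]] = {}
        self._next_frame = 0.0

    # -- initialisation ----------------------------------------------------

    def bind_initial_motor(self, axial_nm: float, azimuth_deg: float) -> None:
        """Bind motor 0 near the given axial position at the lattice site
        whose azimuth best matches the requested cargo azimuth, and place
        the relaxed cargo on that side."""
        fil = self.filaments[0]
        i0 = int(round(axial_nm / fil.monomer_rise))
        window = np.arange(i0, i0 + STEP_LONG_SUBUNITS)
        azs = fil.site_azimuth(window)
        diff = np.abs((azs - azimuth_deg + 180.0) % 360.0 - 180.0)
        index = int(window[np.argmin(diff)])
        site = BindingSite(filament_id=0, monomer_index=index,
                           position=site_position(fil, index),
                           azimuth=float(fil.site_azimuth(index)))
        self.motors[0].head = site
        self.occupied[0].add(index)
        az = math.radians(azimuth_deg)
        e1, e2 = fil._frame
        radial = math.cos(az) * e1 + math.sin(az) * e2
        hang = self.R + fil.radius + 0.5 * self.cfg.motor.rest_length
        self.center = site.position - fil.radius * radial + hang * radial
        self.motors[0].bound_azimuth_ref = fil.azimuth_of(self.center)
        self.relax()

    # -- mechanics ---------------------------------------------------------

    def head_point(self, m: Motor) -> np.ndarray:
        """Mechanical attachment point of a bound head: the filament-axis
        point at the site's axial coordinate.  The 4 nm radial monomer
        offset is kept for lattice azimuth bookkeeping (handedness) but is
        negligible against the 225 nm tether and would otherwise inject a
        spurious sub-thermal azimuthal torque."""
        fil = self.filaments[m.head.filament_id]
        return fil.axis_point(m.head.monomer_index * fil.monomer_rise)

    def bound_list(self) -> list[tuple[np.ndarray, float, ActinFilament]]:
        return [(self.head_point(m), m.bound_azimuth_ref,
                 self.filaments[m.head.filament_id])
                for m in self.motors if m.bound]

    def relax(self) -> None:
        pose = equilibrate_pose(
            self.center, self.bound_list(), self.filaments, self.R,
            self.cfg.motor, trap_center=self.trap_center,
            trap_stiffness=self.cfg.trap_stiffness if self.trap else 0.0)
        self.center = pose.center

    def azimuth_diffuse(self, dt: float) -> None:
        """Thermal azimuthal diffusion of a cargo whose ensemble is bound
        to a single filament, advanced over the elapsed interval ``dt``.

        With bound heads on (essentially) the filament axis, rotating the
        cargo about that axis stretches no linkage: the azimuth is a soft
        mode restrained only by the sub-thermal torsion springs and by
        steric contacts, so a quasi-static minimizer over-pins it -- in
        particular against a steric barrier, where repositioning is what
        eventually lets the cargo find an unobstructed approach angle.
        The mode is advanced as overdamped rotational Brownian motion of
        the sphere about the filament (D_az = kBT / (6 pi eta R rho^2)
        ~ 0.03 rad^2/s, i.e. a few degrees per event interval), proposed
        as one Gaussian azimuth step and accepted by Metropolis on the
        relaxed energies, which preserves the Boltzmann distribution over
        the arc without letting the cargo teleport across it.
        """
        if (not self.cfg.azimuth_diffusion or self.trap or dt <= 0
                or len(self.filaments) < 2):
            return
        bound = [m for m in self.motors if m.bound]
        if not bound:
            return
        fids = {m.head.filament_id for m in bound}
        if len(fids) != 1:
            return  # motors on two filaments pin the azimuth
        fid_b = fids.pop()
        fil_b = self.filaments[fid_b]
        # Only worth advancing when another filament is in hard contact:
        # elsewhere the azimuthal mode has no measurable consequence (the
        # observed spirals are phase-coherent) and the draw would just
        # perturb the rng stream.
        margin = self.R + 25.0
        blocked = False
        for fid, fil in enumerate(self.filaments):
            if fid == fid_b:
                continue
            rel = self.center - fil.origin
            ax = float(rel @ fil.direction)
            perp = rel - ax * fil.direction
            if float(perp @ perp) < (margin + fil.radius) ** 2:
                blocked = True
                break
        if not blocked:
            return
        e1, e2 = fil_b._frame
        rel = self.center - fil_b.origin
        ax = float(rel @ fil_b.direction)
        pv = rel - ax * fil_b.direction
        rho = float(np.linalg.norm(pv))
        if rho < 1e-6:
            return
        mp = self.cfg.motor
        eta = 1e-9  # pN s / nm^2, water
        # Near-contact lubrication raises the drag on a sphere rotating
        # against a filament well above the free Stokes value.
        drag_factor = _CONTACT_DRAG_FACTOR
        d_az = mp.kBT / (6.0 * math.pi * eta * self.R * rho * rho
                         * drag_factor)
        sigma = math.sqrt(2.0 * d_az * dt)
        dtheta = float(self.rng.normal(0.0, sigma))
        theta = math.atan2(float(pv @ e2), float(pv @ e1)) + dtheta
        c0 = (fil_b.origin + ax * fil_b.direction
              + rho * (math.cos(theta) * e1 + math.sin(theta) * e2))
        blist = self.bound_list()
        e_now, _ = pose_energy(self.center, blist, self.filaments, self.R, mp)
        pose = equilibrate_pose(c0, blist, self.filaments, self.R, mp)
        dE = pose.energy - e_now
        if dE <= 0 or self.rng.random() < math.exp(-dE / mp.kBT):
            self.center = pose.center

    def motor_load(self, motor: Motor) -> tuple[float, float, float]:
        """(tension magnitude, resistive, assisting) components of the
        linkage force along the motor's stepping direction."""
        fil = self.filaments[motor.head.filament_id]
        fvec, mag = linkage_tension(self.center, self.head_point(motor), self.R,
                                    self.cfg.motor)
        step_dir = fil.polarity * fil.direction
        par = float(fvec @ step_dir)
        return mag, max(0.0, -par), max(0.0, par)

    # -- propensities ------------------------------------------------------

    def propensities(self):
        """Return (rates, actions) for every open reaction channel."""
        rates: list[float] = []
        actions: list[tuple] = []
        mp = self.cfg.motor
        for mi, m in enumerate(self.motors):
            if not m.bound:
                continue
            fil = self.filaments[m.head.filament_id]
            tension, resist, assist = self.motor_load(m)
            rates.append(detachment_rate(tension, mp, assisting=assist > resist))
            actions.append(("unbind", mi))
            k_long, k_short, k_back = step_rates(resist, mp)
            for kind, rate, subunits in (
                ("step_long", k_long, STEP_LONG_SUBUNITS),
                ("step_short", k_short, STEP_SHORT_SUBUNITS),
                ("step_back", k_back, -STEP_LONG_SUBUNITS),
            ):
                target = m.head.monomer_index + fil.polarity * subunits
                s = target * fil.monomer_rise
                # Steps only require a free target monomer: established
                # motors tread through each other's lever sweep, whereas a
                # newly arriving motor needs the wider clear corridor
                # enforced in accessible_sites.
                if 0 <= s <= fil.length and target not in self.occupied[m.head.filament_id]:
                    rates.append(rate)
                    actions.append((kind, mi, target))
        n_free = sum(1 for m in self.motors if not m.bound)
        if n_free > 0:
            anchors = self.bound_anchor_points()
            for fid, fil in enumerate(self.filaments):
                rate, idx, w = attachment_propensity(
                    self.center, fil, self.occupied[fid], n_free,
                    self.cfg.n_motors, self.geom, mp, anchors)
                if rate > 0:
                    rates.append(rate)
                    actions.append(("bind", fid, idx, w))
        return np.array(rates), actions

    def bound_anchor_points(self) -> np.ndarray:
        """World positions of bound-motor anchors: the sphere point nearest
        each bound head (fluid-membrane limit)."""
        pts = []
        for m in self.motors:
            if m.bound:
                v = self.head_point(m) - self.center
                n = np.linalg.norm(v)
                if n > 1e-9:
                    pts.append(self.center + self.R * v / n)
        return np.array(pts).reshape(-1, 3)

    # -- event application -------------------------------------------------

    def apply(self, action: tuple) -> None:
        kind = action[0]
        if kind == "unbind":
            mi = action[1]
            m = self.motors[mi]
            self.occupied[m.head.filament_id].discard(m.head.monomer_index)
            self.events.append({"t": self.t, "kind": "unbind", "motor": mi,
                                "filament": m.head.filament_id,
                                "site": m.head.monomer_index})
            m.head = None
            if self.n_bound() == 0 and not self.trap:
                return  # pose undefined; the loop terminates this run
        elif kind == "bind":
            fid, idx, w = action[1], action[2], action[3]
            site_idx = int(self.rng.choice(idx, p=w))
            mi = next(i for i, m in enumerate(self.motors) if not m.bound)
            fil = self.filaments[fid]
            self.motors[mi].head = BindingSite(
                filament_id=fid, monomer_index=site_idx,
                position=site_position(fil, site_idx),
                azimuth=float(fil.site_azimuth(site_idx)))
            self.motors[mi].bound_azimuth_ref = fil.azimuth_of(self.center)
            self.occupied[fid].add(site_idx)
            self.events.append({"t": self.t, "kind": "bind", "motor": mi,
                                "filament": fid, "site": site_idx})
        else:  # a step
            mi, target = action[1], action[2]
            m = self.motors[mi]
            fid = m.head.filament_id
            fil = self.filaments[fid]
            d_index = target - m.head.monomer_index
            self.occupied[fid].discard(m.head.monomer_index)
            self.occupied[fid].add(target)
            m.head = BindingSite(filament_id=fid, monomer_index=target,
                                 position=site_position(fil, target),
                                 azimuth=float(fil.site_azimuth(target)))
            # The new lead head re-anchors the torsion reference at the new
            # lattice azimuth: the short-step twist is what spirals the cargo.
            m.bound_azimuth_ref = (
                m.bound_azimuth_ref + d_index * fil.monomer_twist) % 360.0
            self.events.append({"t": self.t, "kind": kind, "motor": mi,
                                "filament": fid, "site": target})
        self.relax()

    # -- sampling ----------------------------------------------------------

    def emit_frames_until(self, t_stop: float) -> None:
        """Emit 100 ms frames carrying the piecewise-constant pose."""
        while self._next_frame <= t_stop + 1e-12:
            self.frames_t.append(self._next_frame)
            self.frames_c.append(self.center.copy())
            self.frames_n.append([sum(1 for m in self.motors
                                      if m.bound and m.head.filament_id == fid)
                                  for fid in range(len(self.filaments))])
            if self.trap and self.trap_center is not None:
                disp = float((self.center - self.trap_center)
                             @ self.filaments[0].direction)
                self.frames_f.append(self.cfg.trap_stiffness * abs(disp))
            self._next_frame += self.cfg.frame_interval

    def account_counts(self, dt: float) -> None:
        for fid in range(len(self.filaments)):
            n = sum(1 for m in self.motors
                    if m.bound and m.head.filament_id == fid)
            per = self.count_time.setdefault(fid, [])  # type: ignore[arg-type]
            while len(per) <= n:
                per.append(0.0)
            per[n] += dt

    def n_bound(self) -> int:
        return sum(1 for m in self.motors if m.bound)

    def build_trajectory(self, terminal: str) -> Trajectory:
        return Trajectory(
            times=np.array(self.frames_t),
            centers=np.array(self.frames_c).reshape(-1, 3),
            engaged_per_filament=np.array(self.frames_n, dtype=int).reshape(
                -1, len(self.filaments)),
            events=self.events,
            filaments=self.filaments,
            terminal=terminal,
            forces=np.array(self.frames_f) if self.trap else None,
            attached_time_by_count=self.count_time,
        )


def _run_loop(eng: _Engine, stop) -> str:
    """Advance the Gillespie loop until ``stop(eng)`` returns a terminal
    label, time runs out, or (outside a trap) the last motor detaches."""
    cfg = eng.cfg
    if cfg.n_motors == 0 or (eng.n_bound() == 0 and not eng.trap):
        eng.emit_frames_until(0.0)
        return "all_detached"
    while eng.t < cfg.max_time:
        rates, actions = eng.propensities()
        total = float(rates.sum())
        if total <= 0:
            eng.emit_frames_until(cfg.max_time)
            eng.account_counts(cfg.max_time - eng.t)
            eng.t = cfg.max_time
            return "stalled"
        dt = float(eng.rng.exponential(1.0 / total))
        t_next = eng.t + dt
        eng.emit_frames_until(min(t_next, cfg.max_time) - 1e-12)
        eng.account_counts(min(t_next, cfg.max_time) - eng.t)
        if t_next >= cfg.max_time:
            eng.t = cfg.max_time
            return "time"
        eng.t = t_next
        eng.azimuth_diffuse(dt)
        choice = int(eng.rng.choice(len(rates), p=rates / total))
        eng.apply(actions[choice])
        label = stop(eng)
        if label:
            eng.emit_frames_until(eng.t)
            return label
        if eng.n_bound() == 0 and not eng.trap:
            eng.events.append({"t": eng.t, "kind": "end", "motor": -1,
                               "filament": -1, "site": -1})
            eng.emit_frames_until(eng.t)
            return "all_detached"
    return "time"


# --- public entry points ---------------------------------------------------

def simulate(config: SimConfig) -> Trajectory:
    """Run a single-filament transport simulation.

    The cargo starts with one motor bound at ``start_axial`` and travels
    toward the plus end (North, +y) until it reaches the filament end, all
    motors detach, or ``max_time`` elapses.
    """
    if config.geometry != "single_filament":
        raise ValueError("simulate() requires geometry='single_filament'")
    fil = ActinFilament(origin=[0.0, 0.0, 0.0], direction=[0.0, 1.0, 0.0],
                        length=config.filament_length, polarity=1)
    eng = _Engine(config, [fil])
    if config.n_motors == 0:
        eng.emit_frames_until(0.0)
        return eng.build_trajectory("all_detached")
    az = (config.init_azimuth if config.init_azimuth is not None
          else float(eng.rng.uniform(0.0, 360.0)))
    eng.bind_initial_motor(config.start_axial, az)
    end_s = config.filament_length - 3 * D_LONG

    def stop(e: _Engine):
        if e.filaments[0].axial_coord(e.center) >= end_s:
            return "reached_end"
        return None

    terminal = _run_loop(eng, stop)
    return eng.build_trajectory(terminal)


def _measured_alpha(traj: Trajectory, inter: IntersectionGeometry) -> float:
    """Approach angle from the 10 frames before the crossing (simulation-
    side twin of the analysis procedure), circular-mean, degrees [0,360)."""
    fil = inter.original
    y = np.array([fil.axial_coord(c) for c in traj.centers])
    y_cross = fil.axial_coord(inter.crossing_point)
    ahead = np.nonzero(y >= y_cross)[0]
    stop = int(ahead[0]) if ahead.size else len(y)
    sel = slice(max(stop - 10, 0), stop)
    pts = traj.centers[sel]
    if len(pts) == 0:
        pts = traj.centers[-1:]
    # Azimuth about the original filament with 0 deg on the intersecting
    # filament's side (+z here) and 90 deg East (+x).
    sign = 1.0 if inter.intersecting.origin[2] >= 0 else -1.0
    ang = np.arctan2(pts[:, 0], sign * pts[:, 2])
    alpha = math.degrees(math.atan2(float(np.mean(np.sin(ang))),
                                    float(np.mean(np.cos(ang)))))
    return alpha % 360.0


def run_intersection(config: SimConfig) -> tuple[Trajectory, OutcomeRecord]:
    """Simulate one transit of a 3D intersection and classify its outcome.

    The cargo starts bound to the original filament 2.5 um South of the
    crossing (ensemble size reaches steady state well before arrival) with
    a uniformly random initial azimuth; the realized approach angle is
    *measured* from the final 10 pre-crossing frames, exactly as the
    trajectory analysis does.
    """
    inter = config.geometry
    if not isinstance(inter, IntersectionGeometry):
        raise ValueError("run_intersection() requires an IntersectionGeometry")
    filaments = [inter.original, inter.intersecting]
    eng = _Engine(config, filaments)
    az = (config.init_azimuth if config.init_azimuth is not None
          else float(eng.rng.uniform(0.0, 360.0)))
    start_axial = inter.original.axial_coord(inter.crossing_point) - 1500.0
    eng.bind_initial_motor(start_axial, az)

    y_cross = inter.original.axial_coord(inter.crossing_point)
    x_cross = inter.intersecting.axial_coord(inter.crossing_point)
    dwell = {"time": 0.0, "prev_t": 0.0}

    def stop(e: _Engine):
        y = inter.original.axial_coord(e.center) - y_cross
        x = inter.intersecting.axial_coord(e.center) - x_cross
        if abs(y) <= _DWELL_HALFWIDTH:
            dwell["time"] += e.t - dwell["prev_t"]
        dwell["prev_t"] = e.t
        if y >= _EXIT_MARGIN:
            return "straight"
        if abs(x) >= _EXIT_MARGIN:
            east = (np.array([1.0, 0.0, 0.0])
                    @ inter.intersecting.direction) * np.sign(x)
            return "turn_right" if east > 0 else "turn_left"
        if dwell["time"] > e.cfg.intersection_dwell_limit:
            return "terminate_dwell"
        return None

    terminal = _run_loop(eng, stop)
    traj = eng.build_trajectory(terminal)
    alpha = _measured_alpha(traj, inter)

    if terminal == "straight":
        outcome: Outcome = "straight"
    elif terminal in ("turn_left", "turn_right"):
        outcome = terminal  # type: ignore[assignment]
    elif terminal == "terminate_dwell":
        outcome = "terminate"
    else:
        # Run ended without committing to an exit (all motors released or
        # time ran out).  It counts as a termination *at the intersection*
        # only if the cargo died within interaction range of the crossing;
        # a release far upstream never reached the intersection and is
        # distinguishable through ``trajectory.terminal``.
        outcome = "terminate"
    y_max = max(inter.original.axial_coord(c) for c in traj.centers)
    reached = y_max >= y_cross - _DWELL_HALFWIDTH
    record = OutcomeRecord(alpha=alpha, d=inter.separation_d, outcome=outcome,
                           dwell_at_intersection=dwell["time"],
                           reached=bool(reached))
    return traj, record


def run_trap(config: SimConfig) -> Trajectory:
    """Simulate a motor-cargo complex working against a harmonic trap on a
    single filament; returns a trajectory whose ``forces`` carry the trap
    force magnitude (pN) per frame.

    The trap centre is the relaxed cargo position at first binding.  On
    full detachment the cargo snaps back to the trap centre (quasi-static,
    no thermal noise) and motors may re-engage -- the saw-tooth pattern.
    """
    if config.geometry != "trap":
        raise ValueError("run_trap() requires geometry='trap'")
    if config.trap_stiffness <= 0:
        raise ValueError("trap_stiffness must be positive")
    fil = ActinFilament(origin=[0.0, 0.0, 0.0], direction=[0.0, 1.0, 0.0],
                        length=config.filament_length, polarity=1)
    eng = _Engine(config, [fil], trap=True)
    if config.n_motors == 0:
        eng.trap_center = np.array([0.0, config.start_axial,
                                    config.cargo_diameter / 2 + fil.radius])
        eng.center = eng.trap_center.copy()
        eng.emit_frames_until(config.max_time)
        return eng.build_trajectory("time")
    az = (config.init_azimuth if config.init_azimuth is not None
          else float(eng.rng.uniform(0.0, 360.0)))
    eng.bind_initial_motor(config.start_axial, az)
    eng.trap_center = eng.center.copy()
    eng.relax()
    terminal = _run_loop(eng, lambda e: None)
    return eng.build_trajectory(terminal)


def engaged_motor_census(trajectory: Trajectory,
                         filament_id: int = 0) -> dict[int, float]:
    """Time-weighted histogram {engaged count: seconds} for one filament,
    over frames with at least one motor engaged (so the weights sum to the
    attached time on that filament)."""
    if trajectory.attached_time_by_count.get(filament_id):
        per = trajectory.attached_time_by_count[filament_id]
        return {n: w for n, w in enumerate(per) if n >= 1 and w > 0}
    dt = float(np.diff(trajectory.times).mean()) if len(trajectory.times) > 1 else 0.0
    counts = trajectory.engaged_per_filament[:, filament_id]
    out: dict[int, float] = {}
    for n in np.unique(counts):
        if n >= 1:
            out[int(n)] = float((counts == n).sum() * dt)
    return out
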