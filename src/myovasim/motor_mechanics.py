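"""Single-motor elastics and load-dependent kinetics, plus quasi-static
relaxation of the cargo pose.

A myosin Va HMM is modelled as a compliant tether between a membrane anchor
on the cargo sphere and a bound head on an actin binding site: stiff in
extension (1 pN/nm beyond the 50 nm rest length, slack in compression --
a flexible 50 nm molecule cannot push) and weakly torsional about the
filament axis (0.25 pN nm/rad), which resists rolling of the cargo around
the track.  Attachment, detachment and stepping are stochastic rates;
detachment and stepping carry Bell-form load dependence anchored to the
published unloaded velocity (~420 nm/s) and single-motor stall (~1.9 pN).

Because the membrane is fluid, bound anchors slide instantaneously to the
sphere point nearest their head, and the cargo pose reduces to its centre
position: rotation of the lipid sphere moves no anchors and stores no
energy.  :func:`equilibrate_pose` therefore minimizes the total elastic
energy over the 3-dof centre subject to cargo-filament excluded volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .actin_geometry import ActinFilament, BindingSite, InteractionParams, site_positions

__all__ = [
    "MotorParams",
    "Motor",
    "CargoPose",
    "linkage_force",
    "linkage_tension",
    "torsion_energy",
    "detachment_rate",
    "step_rates",
    "net_step_velocity",
    "p_short",
    "accessible_sites",
    "attachment_propensity",
    "pose_energy",
    "equilibrate_pose",
]

# Axial advance per step type on the lattice (13-, 11- and -13-subunit
# steps at 2.75 nm rise): ~36 nm long forward, ~31 nm short, 36 nm back.
STEP_LONG_SUBUNITS = 13
STEP_SHORT_SUBUNITS = 11
D_LONG = STEP_LONG_SUBUNITS * 2.75   # 35.75 nm
D_SHORT = STEP_SHORT_SUBUNITS * 2.75  # 30.25 nm

_PENALTY_K = 100.0  # pN/nm, cargo-filament excluded-volume penalty


def _stall_consistent_back_distance(
    k_step0: float, step_distance_param: float, kBT: float, stall_force: float,
    p_short_stall: float, k_back0: float,
) -> float:
    """Back-step Bell distance that places the zero of the net stepping
    velocity exactly at the stall force, given the unloaded back rate.

    Back-stepping is strongly load-promoted: rare unloaded, matching the
    forward flux at stall.
    """
    mean_fwd = (1.0 - p_short_stall) * D_LONG + p_short_stall * D_SHORT
    k_fwd_stall = k_step0 * math.exp(-stall_force * step_distance_param / kBT)
    k_back_stall = k_fwd_stall * mean_fwd / D_LONG
    if k_back_stall <= k_back0:
        raise ValueError("k_back0 too large for the requested stall force")
    return kBT / stall_force * math.log(k_back_stall / k_back0)


@dataclass
class MotorParams:
    """Mechanical and kinetic parameters of one myosin Va motor.

    Units: nm, s, pN, pN nm.  ``back_distance`` defaults to the value that
    makes the net stepping velocity vanish exactly at ``stall_force``
    given the unloaded back rate (~6.4 nm with the other defaults); pass a
    number to override.
    """

    k_ext: float = 1.0            # extensional stiffness, pN/nm
    k_tor: float = 0.25           # torsional stiffness, pN nm/rad
    rest_length: float = 50.0     # HMM contour length, nm
    k_detach0: float = 0.35       # unloaded detachment rate, 1/s
    detach_distance: float = 1.0  # Bell distance, resistive load, nm
    detach_distance_assist: float = 1.8  # Bell distance, assisting load, nm
    k_step0: float = 15.0         # unloaded forward stepping rate, 1/s
    p_short0: float = 0.17        # unloaded short-step probability
    p_short_stall: float = 0.50   # short-step probability at stall
    k_back0: float | None = None  # unloaded back-step rate, 1/s
    step_distance_param: float = 3.4  # Bell distance for forward steps, nm
    back_distance: float | None = None  # Bell distance for back steps, nm
    # Zero of the net stepping velocity.  Measured stall peaks overshoot
    # this root by about half a step's worth of trap force (a 36 nm step
    # in a 0.019 pN/nm trap is 0.68 pN), so this root yields measured
    # single-motor stall peaks near the canonical ~1.9 pN.
    stall_force: float = 1.55     # pN
    k_attach_max: float = 2.4     # ensemble attachment rate ceiling, 1/s
    kBT: float = 4.1              # thermal energy, pN nm
    footprint_radius: float = 40.0  # membrane area swept by a bound HMM, nm
    site_exclusion: int = 26        # lattice subunits a new motor must clear

    def __post_init__(self) -> None:
        # The stall force anchors the back-stepping channel: given one of
        # (unloaded back rate, back Bell distance), the other is derived so
        # the net stepping velocity vanishes exactly at stall_force.
        if self.k_back0 is None:
            if self.back_distance is None:
                self.back_distance = self.step_distance_param
            mean_fwd = ((1.0 - self.p_short_stall) * D_LONG
                        + self.p_short_stall * D_SHORT)
            k_fwd_stall = self.k_step0 * math.exp(
                -self.stall_force * self.step_distance_param / self.kBT)
            self.k_back0 = (k_fwd_stall * mean_fwd / D_LONG
                            * math.exp(-self.stall_force * self.back_distance
                                       / self.kBT))
        elif self.back_distance is None:
            self.back_distance = _stall_consistent_back_distance(
                self.k_step0, self.step_distance_param, self.kBT,
                self.stall_force, self.p_short_stall, self.k_back0,
            )
        for name in ("k_ext", "k_tor", "rest_length", "k_detach0", "k_step0",
                     "k_back0", "step_distance_param", "back_distance",
                     "k_attach_max", "kBT"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_short0 <= 1.0:
            raise ValueError("p_short0 must be a probability")
        if self.stall_force <= 0:
            raise ValueError("stall_force must be positive")


@dataclass
class Motor:
    """One motor: a membrane anchor (implicit, fluid) and a head that is
    either free or bound to a lattice site.  ``bound_azimuth_ref`` is the
    torsion reference azimuth (degrees) about the bound filament; it is set
    when the motor binds and advanced by each step's lattice twist."""

    head: BindingSite | None = None
    bound_azimuth_ref: float = 0.0

    @property
    def bound(self) -> bool:
        return self.head is not None


@dataclass
class CargoPose:
    """Rigid-sphere cargo pose.  With a fluid membrane only the centre is
    dynamically meaningful; ``energy`` is the relaxed elastic energy."""

    center: np.ndarray
    energy: float = 0.0


def linkage_force(
    anchor_world: np.ndarray, head_pos: np.ndarray, params: MotorParams
) -> np.ndarray:
    """Force (pN, vector) the linkage exerts on the head: tension toward the
    anchor when stretched beyond rest length, zero when slack."""
    anchor_world = np.asarray(anchor_world, dtype=float)
    head_pos = np.asarray(head_pos, dtype=float)
    r = anchor_world - head_pos
    dist = float(np.linalg.norm(r))
    ext = dist - params.rest_length
    if ext <= 0 or dist == 0:
        return np.zeros(3)
    return params.k_ext * ext * (r / dist)


def linkage_tension(
    center: np.ndarray, head_pos: np.ndarray, cargo_radius: float, params: MotorParams
) -> tuple[np.ndarray, float]:
    """Tension on a bound head given the cargo centre, with the anchor at
    the sphere point nearest the head (fluid-membrane limit).

    Returns ``(force_vector_on_head, magnitude)``; the vector points from
    the head toward the anchor when the linkage is taut.
    """
    center = np.asarray(center, dtype=float)
    head_pos = np.asarray(head_pos, dtype=float)
    r = center - head_pos
    dist = float(np.linalg.norm(r))
    ext = dist - cargo_radius - params.rest_length
    if ext <= 0 or dist == 0:
        return np.zeros(3), 0.0
    mag = params.k_ext * ext
    return mag * (r / dist), mag


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def torsion_energy(
    motor: Motor, pose: CargoPose, filament: ActinFilament, params: MotorParams
) -> float:
    """Torsional energy (pN nm) of a bound motor: 1/2 k_tor theta^2 with
    theta the angular deviation (rad) of the current linkage azimuth about
    the filament axis from the reference set at binding."""
    if not motor.bound:
        raise ValueError("torsion_energy requires a bound motor")
    theta = math.radians(
        _wrap_deg(filament.azimuth_of(pose.center) - motor.bound_azimuth_ref)
    )
    return 0.5 * params.k_tor * theta * theta


def detachment_rate(F: float, params: MotorParams, assisting: bool = False) -> float:
    """Bell-form detachment rate (1/s) under load magnitude ``F`` (pN).

    Detachment is direction-sensitive: resistive (backward) load uses a
    short Bell distance (myosin V holds on while working against load),
    while assisting (forward) load -- a motor being dragged by its cargo --
    detaches much faster.
    """
    if F < 0:
        raise ValueError("load magnitude must be non-negative")
    delta = params.detach_distance_assist if assisting else params.detach_distance
    return params.k_detach0 * math.exp(F * delta / params.kBT)


def p_short(F: float, params: MotorParams) -> float:
    """Short-step probability: rises linearly from its unloaded value to
    ``p_short_stall`` at the stall force, clamped beyond."""
    frac = min(max(F, 0.0) / params.stall_force, 1.0)
    return params.p_short0 + (params.p_short_stall - params.p_short0) * frac


def step_rates(F_parallel: float, params: MotorParams) -> tuple[float, float, float]:
    """(k_fwd_long, k_fwd_short, k_back) in 1/s under resistive load
    ``F_parallel`` (pN; assisting load is treated as zero)."""
    F = max(F_parallel, 0.0)
    k_fwd = params.k_step0 * math.exp(-F * params.step_distance_param / params.kBT)
    ps = p_short(F, params)
    k_back = params.k_back0 * math.exp(F * params.back_distance / params.kBT)
    return k_fwd * (1.0 - ps), k_fwd * ps, k_back


def net_step_velocity(F_parallel: float, params: MotorParams) -> float:
    """Mean axial displacement rate (nm/s) of a bound head under load;
    strictly decreasing in load and zero at the stall force."""
    kl, ks, kb = step_rates(F_parallel, params)
    return kl * D_LONG + ks * D_SHORT - kb * D_LONG


# --- attachment geometry ---------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors for solid-angle quadrature."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


_SPHERE_DIRS = _fibonacci_sphere(512)


def accessible_sites(
    center: np.ndarray,
    filament: ActinFilament,
    occupied: set[int] | frozenset[int],
    geom: InteractionParams,
    params: MotorParams,
    bound_anchors: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Solid-angle accessibility of a filament's free sites from the cargo.

    A membrane direction ``u`` (anchor at ``center + R u``) is *covered* if
    some unoccupied site lies within the motor's rest length of that anchor
    and the anchor is not inside the membrane footprint (radius
    ``params.footprint_radius``) of an already-bound motor.  The footprint
    is what makes an additional motor progressively less likely to join an
    ensemble: the strip of membrane within reach of the filament is only
    ~100 nm wide, and each engaged 50-nm two-headed HMM sweeps a comparable
    patch of it.

    Returns ``(fraction_covered, site_indices, site_weights)`` where the
    weights apportion covered directions to their nearest reachable site
    (used to choose a binding target).
    """
    center = np.asarray(center, dtype=float)
    R = geom.cargo_diameter / 2.0
    reach = R + params.rest_length
    # Candidate axial window on the lattice.
    s_c = filament.axial_coord(center)
    perp = math.sqrt(max((center - filament.origin) @ (center - filament.origin)
                         - s_c * s_c, 0.0))
    if perp - filament.radius > reach:
        return 0.0, np.empty(0, dtype=int), np.empty(0)
    half = math.sqrt(max(reach * reach - max(perp - filament.radius, 0.0) ** 2, 0.0))
    lo = max(int(math.ceil((s_c - half) / filament.monomer_rise)), 0)
    hi = min(int(math.floor((s_c + half) / filament.monomer_rise)), filament.n_sites - 1)
    if hi < lo:
        return 0.0, np.empty(0, dtype=int), np.empty(0)
    idx = np.arange(lo, hi + 1)
    if occupied:
        # A bound two-headed HMM spans ~13 subunits and sterically blocks
        # the lattice around its lead head, not just the one monomer.
        occ = np.fromiter(occupied, dtype=int)
        blocked = (np.abs(idx[:, None] - occ[None, :])
                   <= params.site_exclusion).any(axis=1)
        idx = idx[~blocked]
    if idx.size == 0:
        return 0.0, np.empty(0, dtype=int), np.empty(0)
    pos = site_positions(filament, idx)
    within = np.linalg.norm(pos - center, axis=1) <= reach
    idx, pos = idx[within], pos[within]
    if idx.size == 0:
        return 0.0, np.empty(0, dtype=int), np.empty(0)
    anchors = center + R * _SPHERE_DIRS
    # Prefilter: an anchor farther than rest_length + filament radius from
    # the axis cannot reach any site; cheap perpendicular-distance cull.
    rel = anchors - filament.origin
    ax = rel @ filament.direction
    perp2 = (rel * rel).sum(axis=1) - ax * ax
    cand = perp2 <= (params.rest_length + filament.radius) ** 2
    if bound_anchors is not None and len(bound_anchors):
        ba = np.asarray(bound_anchors, dtype=float).reshape(-1, 3)
        d2a = ((anchors[:, None, :] - ba[None, :, :]) ** 2).sum(axis=2)
        cand &= (d2a > params.footprint_radius ** 2).all(axis=1)
    covered = np.zeros(len(anchors), dtype=bool)
    nearest_full = np.zeros(len(anchors), dtype=int)
    if cand.any():
        d2 = ((anchors[cand, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        covered[cand] = d2[np.arange(len(nearest)), nearest] <= params.rest_length ** 2
        nearest_full[cand] = nearest
    nearest = nearest_full
    frac = float(covered.mean())
    if frac == 0.0:
        return 0.0, np.empty(0, dtype=int), np.empty(0)
    counts = np.bincount(nearest[covered], minlength=idx.size).astype(float)
    keep = counts > 0
    return frac, idx[keep], counts[keep] / counts.sum()


def _reference_fraction(geom: InteractionParams, params: MotorParams) -> float:
    """Accessible fraction for the calibration geometry: an unconstrained
    cargo tethered to a long bare filament by a single motor, hanging at
    mid-tether (the state from which the ~2.4 1/s ensemble recruitment
    rate is anchored)."""
    fil = ActinFilament(origin=[0.0, -5000.0, 0.0], direction=[0.0, 1.0, 0.0],
                        length=10000.0)
    hang = geom.cargo_diameter / 2.0 + fil.radius + 0.75 * params.rest_length
    center = np.array([0.0, 0.0, hang])
    frac, _, _ = accessible_sites(center, fil, frozenset(), geom, params)
    return frac


_REF_CACHE: dict[tuple[float, float], float] = {}


def attachment_propensity(
    center: np.ndarray,
    filament: ActinFilament,
    occupied: set[int] | frozenset[int],
    n_free: int,
    n_motors: int,
    geom: InteractionParams,
    params: MotorParams,
    bound_anchors: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Ensemble attachment propensity (1/s) of the free-motor pool to one
    filament, with the per-site target weights.

    The rate is ``k_attach_max * (n_free / n_motors) * min(f / f_ref, 1)``
    where ``f`` is the accessible solid-angle fraction (excluding membrane
    already swept by bound motors) and ``f_ref`` its value for a full free
    pool on a cargo tethered to a bare filament -- the calibration contract
    that an unconstrained cargo binds at ~``k_attach_max`` overall.  Free
    anchors are taken uniform on the sphere (membrane diffusion relaxes
    far faster than binding).
    """
    if n_free <= 0:
        return 0.0, np.empty(0, dtype=int), np.empty(0)
    key = (geom.cargo_diameter, params.rest_length)
    f_ref = _REF_CACHE.get(key)
    if f_ref is None:
        f_ref = _reference_fraction(geom, params)
        _REF_CACHE[key] = f_ref
    frac, idx, w = accessible_sites(center, filament, occupied, geom, params,
                                    bound_anchors)
    if frac == 0.0:
        return 0.0, idx, w
    rate = params.k_attach_max * (n_free / n_motors) * min(frac / f_ref, 1.0)
    return rate, idx, w


# --- pose relaxation -------------------------------------------------------

def pose_energy(
    center: np.ndarray,
    bound: Sequence[tuple[np.ndarray, float, ActinFilament]],
    filaments: Sequence[ActinFilament],
    cargo_radius: float,
    params: MotorParams,
    trap_center: np.ndarray | None = None,
    trap_stiffness: float = 0.0,
    penalty: float = _PENALTY_K,
) -> tuple[float, np.ndarray]:
    """Total elastic energy (pN nm) and its gradient at a trial centre.

    ``bound`` lists (head_position, azimuth_ref_deg, filament) per bound
    motor.  Cargo-filament overlap is charged a stiff quadratic penalty so
    the relaxed pose respects excluded volume to within ~F/penalty nm.
    """
    c = np.asarray(center, dtype=float)
    E = 0.0
    g = np.zeros(3)
    slack = cargo_radius + params.rest_length
    for head, ref, fil in bound:
        r = c - head
        dist = float(np.linalg.norm(r))
        ext = dist - slack
        if ext > 0 and dist > 0:
            E += 0.5 * params.k_ext * ext * ext
            g += params.k_ext * ext * (r / dist)
        if params.k_tor > 0:
            e1, e2 = fil._frame
            rel = c - fil.origin
            a, b = float(rel @ e1), float(rel @ e2)
            rho2 = a * a + b * b
            if rho2 > 1e-12:
                theta = math.radians(
                    _wrap_deg(math.degrees(math.atan2(b, a)) - ref)
                )
                E += 0.5 * params.k_tor * theta * theta
                # d(theta)/dc = (-b e1 + a e2) / rho^2
                g += params.k_tor * theta * (-b * e1 + a * e2) / rho2
    for fil in filaments:
        rel = c - fil.origin
        ax = float(rel @ fil.direction)
        perp = rel - ax * fil.direction
        dist = float(np.linalg.norm(perp))
        overlap = cargo_radius + fil.radius - dist
        if overlap > 0 and dist > 1e-9:
            E += 0.5 * penalty * overlap * overlap
            g += -penalty * overlap * (perp / dist)
    if trap_center is not None and trap_stiffness > 0:
        r = c - np.asarray(trap_center, dtype=float)
        E += 0.5 * trap_stiffness * float(r @ r)
        g += trap_stiffness * r
    return E, g


def _energy_grad_hess(
    c: np.ndarray,
    bound: Sequence[tuple[np.ndarray, float, ActinFilament]],
    filaments: Sequence[ActinFilament],
    cargo_radius: float,
    params: MotorParams,
    trap_center: np.ndarray | None,
    trap_stiffness: float,
    penalty: float = _PENALTY_K,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Energy, gradient and 3x3 Hessian for Newton relaxation.

    The Hessian is exact on each smooth piece; the torsional mode is ~1e7
    times softer than the excluded-volume penalty, which is why a
    curvature-aware step is needed at all.
    """
    E = 0.0
    g = np.zeros(3)
    H = np.zeros((3, 3))
    I3 = np.eye(3)
    slack = cargo_radius + params.rest_length
    for head, ref, fil in bound:
        r = c - head
        dist = math.sqrt(float(r @ r))
        if dist > 1e-9:
            ext = dist - slack
            if ext > 0:
                u = r / dist
                uu = np.multiply.outer(u, u)
                E += 0.5 * params.k_ext * ext * ext
                g += params.k_ext * ext * u
                H += params.k_ext * (uu + (ext / dist) * (I3 - uu))
        if params.k_tor > 0:
            e1, e2 = fil._frame
            rel = c - fil.origin
            a, b = float(rel @ e1), float(rel @ e2)
            rho2 = a * a + b * b
            if rho2 > 1e-12:
                theta = math.radians(_wrap_deg(math.degrees(math.atan2(b, a)) - ref))
                tvec = (-b * e1 + a * e2) / rho2
                d2th = (2 * a * b * (np.multiply.outer(e1, e1)
                                     - np.multiply.outer(e2, e2))
                        + (b * b - a * a) * (np.multiply.outer(e1, e2)
                                             + np.multiply.outer(e2, e1))
                        ) / (rho2 * rho2)
                E += 0.5 * params.k_tor * theta * theta
                g += params.k_tor * theta * tvec
                H += params.k_tor * (np.multiply.outer(tvec, tvec) + theta * d2th)
    for fil in filaments:
        rel = c - fil.origin
        ax = float(rel @ fil.direction)
        perp = rel - ax * fil.direction
        rho = math.sqrt(float(perp @ perp))
        margin = cargo_radius + fil.radius
        if 1e-9 < rho < margin:
            p = perp / rho
            over = margin - rho
            pp = np.multiply.outer(p, p)
            P = I3 - np.multiply.outer(fil.direction, fil.direction)
            E += 0.5 * penalty * over * over
            g += -penalty * over * p
            H += penalty * pp - penalty * over * (P - pp) / rho
    if trap_center is not None and trap_stiffness > 0:
        r = c - np.asarray(trap_center, dtype=float)
        E += 0.5 * trap_stiffness * float(r @ r)
        g += trap_stiffness * r
        H += trap_stiffness * I3
    return E, g, H


def equilibrate_pose(
    center0: np.ndarray,
    bound: Sequence[tuple[np.ndarray, float, ActinFilament]],
    filaments: Sequence[ActinFilament],
    cargo_radius: float,
    params: MotorParams,
    trap_center: np.ndarray | None = None,
    trap_stiffness: float = 0.0,
    gtol: float = 1e-5,
    max_iter: int = 60,
) -> CargoPose:
    """Quasi-static cargo re-centring: minimize the total elastic energy
    over the centre by damped Newton iteration, warm-started from the
    current pose (so an already-minimal, fully slack pose does not move).
    The relaxed energy never exceeds the starting energy.

    Raises ``ValueError`` with no bound motors and no trap (the pose is
    then undefined; callers treat that as run termination).
    """
    if not bound and trap_center is None:
        raise ValueError("pose undefined: no bound motors and no trap")
    c = np.asarray(center0, dtype=float).copy()
    E, g, H = _energy_grad_hess(c, bound, filaments, cargo_radius, params,
                                trap_center, trap_stiffness)
    E0 = E
    for _ in range(max_iter):
        if float(np.linalg.norm(g)) < gtol:
            break
        shift = 1e-12
        while True:
            try:
                step = np.linalg.solve(H + shift * np.eye(3), -g)
                if step @ g < 0:  # descent direction
                    break
            except np.linalg.LinAlgError:
                pass
            shift = max(shift * 10.0, 1e-9)
            if shift > 1e6:
                step = -g
                break
        # Trust region: a (near-)singular Hessian in a slack pose would
        # otherwise propose astronomically long steps along null modes.
        slen = float(np.linalg.norm(step))
        if slen > 150.0:
            step *= 150.0 / slen
        # Armijo backtracking on the energy.
        t_ls = 1.0
        for _ in range(40):
            E_new, g_new, H_new = _energy_grad_hess(
                c + t_ls * step, bound, filaments, cargo_radius, params,
                trap_center, trap_stiffness)
            if E_new <= E + 1e-4 * t_ls * float(g @ step) + 1e-12:
                c = c + t_ls * step
                E, g, H = E_new, g_new, H_new
                break
            t_ls *= 0.5
        else:
            break
    if E > E0 + 1e-9:  # pathological line-search failure: keep the old pose
        return CargoPose(center=np.asarray(center0, dtype=float), energy=E0)
    return CargoPose(center=c, energy=float(E))
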