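"""Measurement procedures for 3D cargo trajectories.

These mirror what is done to experimental 3D single-particle tracking data:
sinusoidal helix fitting of the transverse coordinates (with the constraint
windows used for real video data), transport velocity by linear fit,
approach-angle estimation from the ten frames before an intersection,
filament Z-separation from localization clouds, directional-outcome
classification with the compass convention, Kaplan-Meier run-length
estimation for end-censored runs, and the straight-to-turn regime heatmap.

The same functions run on simulated and on synthetic noisy trajectories,
so simulator output and experiment-like data are measured identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.optimize import least_squares

from .actin_geometry import (
    IntersectionGeometry,
    InteractionParams,
    REGIME_LABELS,
    interacts,
    max_interaction_separation,
    mirror_angle,
    regime_bin,
)
from .transport_simulator import OutcomeRecord, Trajectory

__all__ = [
    "HelixFit",
    "RunRecord",
    "fit_helix",
    "approach_angle",
    "filament_separation",
    "classify_outcome",
    "km_run_length",
    "straight_turn_heatmap",
]

# Constraint windows for the sinusoid fit, as used on the experimental data:
# amplitudes within [50, 500] nm and frequency within [0.001, 10] 1/s.
AMP_MIN, AMP_MAX = 50.0, 500.0
FREQ_MIN, FREQ_MAX = 1e-3, 10.0


@dataclass
class HelixFit:
    """Joint sinusoid fit of the transverse (X, Z) coordinates.

    ``handedness`` follows the right-handed axes (x East, y = travel,
    z up): a positive rotation about +y carries +z into +x, so
    ``phase_z - phase_x = +pi/2`` is a right-handed spiral and ``-pi/2``
    a left-handed one.  ``pitch = velocity / frequency``.
    """

    amplitude_x: float
    amplitude_z: float
    frequency: float          # 1/s
    phase_x: float            # rad
    phase_z: float            # rad
    handedness: Literal["left", "right", "non_helical"]
    pitch: float              # nm
    velocity: float           # nm/s, from the linear fit of Y(t)
    rmsd: float               # nm


@dataclass(frozen=True)
class RunRecord:
    """One run length; ``censored`` marks runs ending at a filament end or
    support bead rather than by detachment."""

    run_length: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.run_length < 0:
            raise ValueError("run length must be non-negative")


def _sinusoid_residuals(p, t, x, z):
    ax, az_, f, phx, phz, cx, cz = p
    w = 2.0 * math.pi * f
    return np.concatenate([
        ax * np.sin(w * t + phx) + cx - x,
        az_ * np.sin(w * t + phz) + cz - z,
    ])


def fit_helix(trajectory: Trajectory | np.ndarray,
              times: np.ndarray | None = None) -> HelixFit:
    """Fit X(t) and Z(t) to ``A sin(2 pi f t + phi)`` with a shared
    frequency and classify the spiral handedness.

    Accepts a :class:`Trajectory` (already aligned with motion along +y) or
    an ``(n, 3)`` position array plus ``times``.  Fits that do not converge
    inside the amplitude/frequency constraint windows are classified
    ``non_helical`` (straight trajectories fail the amplitude window).
    Velocity comes from a linear fit of Y(t) and pitch = velocity/frequency.

    Raises ``ValueError`` for fewer than 10 frames.
    """
    if isinstance(trajectory, Trajectory):
        centers = trajectory.centers
        t = trajectory.times
    else:
        centers = np.asarray(trajectory, dtype=float)
        if times is None:
            raise ValueError("times required with a bare position array")
        t = np.asarray(times, dtype=float)
    if len(t) < 10:
        raise ValueError("helix fit needs at least 10 frames")
    x = centers[:, 0] - centers[:, 0].mean()
    z = centers[:, 2] - centers[:, 2].mean()
    y = centers[:, 1]
    t = t - t[0]
    velocity = float(np.polyfit(t, y, 1)[0])

    # Initial frequency from the transverse spectrum; fall back on a grid.
    dt = float(np.median(np.diff(t)))
    freqs = np.fft.rfftfreq(len(t), dt)[1:]
    spec = (np.abs(np.fft.rfft(x)) + np.abs(np.fft.rfft(z)))[1:]
    f0_candidates = [float(freqs[np.argmax(spec)])] if len(freqs) else []
    f0_candidates += [0.05, 0.1, 0.2, 0.5]

    best = None
    for f0 in f0_candidates:
        f0 = min(max(f0, FREQ_MIN * 1.1), FREQ_MAX * 0.9)
        a0x = max(math.sqrt(2.0) * float(np.std(x)), AMP_MIN * 1.05)
        a0z = max(math.sqrt(2.0) * float(np.std(z)), AMP_MIN * 1.05)
        p0 = [min(a0x, AMP_MAX * 0.95), min(a0z, AMP_MAX * 0.95),
              f0, 0.0, 0.0, 0.0, 0.0]
        try:
            res = least_squares(
                _sinusoid_residuals, p0, args=(t, x, z),
                bounds=([AMP_MIN, AMP_MIN, FREQ_MIN, -2 * math.pi, -2 * math.pi,
                         -200.0, -200.0],
                        [AMP_MAX, AMP_MAX, FREQ_MAX, 2 * math.pi, 2 * math.pi,
                         200.0, 200.0]),
                max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    rmsd = float(np.sqrt(np.mean(_sinusoid_residuals(best.x, t, x, z) ** 2))) \
        if best is not None else float("nan")

    def _non_helical() -> HelixFit:
        return HelixFit(float("nan"), float("nan"), float("nan"),
                        float("nan"), float("nan"), "non_helical",
                        float("nan"), velocity, rmsd)

    if best is None or not best.success:
        return _non_helical()
    ax, az_, f, phx, phz, _, _ = best.x
    # Convergence *inside* the window; a fit pinned at a bound means the
    # data do not support a helix within the physical ranges.
    eps_a, eps_f = 1e-3, 1e-6
    if not (AMP_MIN + eps_a < ax < AMP_MAX - eps_a
            and AMP_MIN + eps_a < az_ < AMP_MAX - eps_a
            and FREQ_MIN + eps_f < f < FREQ_MAX - eps_f):
        return _non_helical()
    dphi = math.atan2(math.sin(phz - phx), math.cos(phz - phx))
    if abs(math.sin(dphi)) < 0.2:  # phases aligned: planar wobble, not a spiral
        return _non_helical()
    handedness = "right" if dphi > 0 else "left"
    pitch = abs(velocity) / f
    return HelixFit(float(ax), float(az_), float(f), float(phx), float(phz),
                    handedness, float(pitch), velocity, rmsd)


def approach_angle(trajectory: Trajectory | np.ndarray,
                   intersection: IntersectionGeometry,
                   times: np.ndarray | None = None,
                   n_frames: int = 10) -> float:
    """Approach angle alpha (degrees, [0, 360)) from the ``n_frames``
    frames immediately before the cargo reaches the crossing centre.

    0 deg = cargo centre on the intersecting filament's side of the
    original filament, 180 deg = opposite side, 90 deg = East.  The
    per-frame azimuths are combined with a circular mean.

    Raises ``ValueError`` with fewer than ``n_frames`` pre-crossing frames.
    """
    centers = trajectory.centers if isinstance(trajectory, Trajectory) \
        else np.asarray(trajectory, dtype=float)
    fil = intersection.original
    y = np.array([fil.axial_coord(c) for c in centers])
    y_cross = fil.axial_coord(intersection.crossing_point)
    ahead = np.nonzero(y >= y_cross)[0]
    stop = int(ahead[0]) if ahead.size else len(y)
    if stop < n_frames:
        raise ValueError(
            f"approach_angle needs {n_frames} pre-crossing frames, got {stop}")
    pts = centers[stop - n_frames:stop]
    rel = pts - fil.origin
    ax = rel @ fil.direction
    perp = rel - np.outer(ax, fil.direction)
    # Reference direction: from the crossing point (on the original axis)
    # toward the intersecting filament's axis (the published 0-degree convention),
    # East = +90.
    cross = intersection.crossing_point
    other = intersection.intersecting
    q = other.origin + ((cross - other.origin) @ other.direction) * other.direction
    to_int = q - cross
    to_int = to_int - (to_int @ fil.direction) * fil.direction
    if np.linalg.norm(to_int) < 1e-9:
        to_int = np.array([0.0, 0.0, 1.0])
    ref0 = to_int / np.linalg.norm(to_int)
    east = np.cross(ref0, -fil.direction)
    ang = np.arctan2(perp @ east, perp @ ref0)
    alpha = math.degrees(math.atan2(float(np.mean(np.sin(ang))),
                                    float(np.mean(np.cos(ang)))))
    return alpha % 360.0


def filament_separation(localizations_a: np.ndarray,
                        localizations_b: np.ndarray,
                        cutoff: float = 250.0) -> tuple[float, bool]:
    """Filament separation d = |mean Z(A) - mean Z(B)| from two 3D
    localization clouds, with a flag marking separations beyond the
    analysis cutoff (excluded from outcome statistics).

    Raises ``ValueError`` if either cloud has fewer than 10 points.
    """
    a = np.asarray(localizations_a, dtype=float)
    b = np.asarray(localizations_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or len(a) < 10 or len(b) < 10:
        raise ValueError("each localization cloud needs >= 10 points (n x 3)")
    d = float(abs(a[:, 2].mean() - b[:, 2].mean()))
    return d, d > cutoff


def classify_outcome(trajectory: Trajectory | np.ndarray,
                     intersection: IntersectionGeometry,
                     params: InteractionParams | None = None) -> str:
    """Directional outcome from a trajectory overlapping an intersection.

    straight: exits on the original filament past the crossing;
    turn_left / turn_right: exits along the intersecting filament (compass
    rule: travelling South to North, East is a right turn); terminate: the
    track ends while the cargo is within interaction range of the crossing.
    Returns ``"not_applicable"`` if the trajectory never comes near the
    crossing.
    """
    centers = trajectory.centers if isinstance(trajectory, Trajectory) \
        else np.asarray(trajectory, dtype=float)
    params = params or InteractionParams()
    orig, inter = intersection.original, intersection.intersecting
    cross = intersection.crossing_point
    y = np.array([orig.axial_coord(c) for c in centers]) - orig.axial_coord(cross)
    x = np.array([inter.axial_coord(c) for c in centers]) - inter.axial_coord(cross)
    exit_margin = 400.0
    near = params.cargo_diameter / 2.0 + params.motor_reach
    if y.max() < -near:
        return "not_applicable"
    straight_at = np.nonzero(y >= exit_margin)[0]
    turn_at = np.nonzero(np.abs(x) >= exit_margin)[0]
    first_s = straight_at[0] if straight_at.size else np.inf
    first_t = turn_at[0] if turn_at.size else np.inf
    if first_t < first_s:
        i = int(first_t)
        east = float(np.sign(x[i]) * (np.array([1.0, 0.0, 0.0]) @ inter.direction))
        return "turn_right" if east > 0 else "turn_left"
    if first_s < np.inf:
        return "straight"
    # Track ended with no exit: terminate if it died within interaction
    # range of the crossing (the 2D "spatial centre" criterion generalized
    # to 3D via d_int at the final approach angle).
    try:
        alpha = approach_angle(centers, intersection)
    except ValueError:
        alpha = 0.0
    reach = max(max_interaction_separation(alpha, params), near)
    if float(np.linalg.norm(centers[-1] - cross)) <= reach:
        return "terminate"
    return "not_applicable"


def km_run_length(runs: Iterable[RunRecord]):
    """Kaplan-Meier survival estimate of run length with right-censoring
    (runs that reached a filament end are censored, not terminated).

    Returns ``(kmf, summary)`` where ``kmf`` is the fitted lifelines
    ``KaplanMeierFitter`` and ``summary`` a dict with the restricted mean,
    the median, counts, and a ``lower_bound_only`` flag (true when every
    record is censored, in which case a warning is issued and the mean is
    only a lower bound).
    """
    records = list(runs)
    if not records:
        raise ValueError("km_run_length needs at least one record")
    lengths = np.array([r.run_length for r in records], dtype=float)
    observed = np.array([not r.censored for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(lengths, event_observed=observed)
    lower_only = not observed.any()
    if lower_only:
        warnings.warn("all runs censored: mean run length is a lower bound",
                      UserWarning, stacklevel=2)
    horizon = float(lengths.max())
    from lifelines.utils import restricted_mean_survival_time
    mean = float(restricted_mean_survival_time(kmf, t=horizon))
    median = float(kmf.median_survival_time_)
    summary = {
        "mean": mean,
        "median": median,
        "n": len(records),
        "n_censored": int((~observed).sum()),
        "restricted": bool((~observed).any() and lengths[~observed].max()
                           >= lengths[observed].max() if observed.any() else True),
        "lower_bound_only": lower_only,
    }
    return kmf, summary


def straight_turn_heatmap(outcomes: Sequence[OutcomeRecord],
                          params: InteractionParams | None = None) -> dict:
    """Straight-to-turn ratio per (alpha, d) regime.

    Approach angles are mirrored onto [0, 180]; each record lands in one
    of the four interaction regimes (boundaries at 60 degrees and 125 nm)
    or the non-interaction regime.  Zero-turn regimes report ``inf`` and
    empty regimes ``None``; counts are always included alongside.
    """
    params = params or InteractionParams()
    per: dict[str, dict] = {lab: {"straight": 0, "turn": 0, "terminate": 0}
                            for lab in REGIME_LABELS}
    for rec in outcomes:
        lab = regime_bin(mirror_angle(rec.alpha), rec.d, params)
        if rec.outcome == "straight":
            per[lab]["straight"] += 1
        elif rec.outcome in ("turn_left", "turn_right"):
            per[lab]["turn"] += 1
        else:
            per[lab]["terminate"] += 1
    out = {}
    for lab, c in per.items():
        n = c["straight"] + c["turn"] + c["terminate"]
        if n == 0:
            ratio = None
        elif c["turn"] == 0:
            ratio = float("inf")
        else:
            ratio = c["straight"] / c["turn"]
        out[lab] = {"ratio": ratio, **c, "n": n}
    return out
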