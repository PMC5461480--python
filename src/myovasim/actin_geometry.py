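"""Suspended actin filaments, their helical binding-site lattice, and
intersection interaction geometry.

Coordinate convention (used throughout the package): units are nm, the
*original* filament runs along +y ("South" to "North"), +z is up and +x is
"East".  An intersecting filament crosses nearly perpendicular in the XY
projection, vertically offset by the centre-to-centre separation ``d``.

The central geometric result is the interaction boundary
``d_int(alpha) = (R + L) * (1 + cos(alpha))`` -- the maximum filament
separation at which a spherical cargo of radius ``R`` approaching the
crossing at azimuthal angle ``alpha`` (0 deg = same side as the intersecting
filament) can still present a motor of reach ``L`` to the intersecting
filament.  With the defaults (350 nm cargo, 50 nm motors) this gives 450 nm
head-on and 225 nm at 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "F_ACTIN_RISE_NM",
    "F_ACTIN_TWIST_DEG",
    "F_ACTIN_RADIUS_NM",
    "ActinFilament",
    "BindingSite",
    "IntersectionGeometry",
    "InteractionParams",
    "site_position",
    "site_positions",
    "max_interaction_separation",
    "interacts",
    "mirror_angle",
    "regime_bin",
    "REGIME_LABELS",
]

# Standard F-actin lattice constants.  The axial rise per monomer and the
# left-handed genetic-helix twist make a 13-subunit step (the myosin Va
# working stroke, ~36 nm) azimuthally near-neutral (-2159.95 deg = +0.05 deg
# mod 360), while an 11-subunit short step (~31 nm) rotates the bound head
# by -27.65 deg around the filament axis.
F_ACTIN_RISE_NM = 2.75
F_ACTIN_TWIST_DEG = -166.15
F_ACTIN_RADIUS_NM = 4.0


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


@dataclass
class ActinFilament:
    """A rigid suspended filament carrying a discrete helical site lattice.

    ``direction`` points toward the plus end when ``polarity`` is +1 and
    away from it when ``polarity`` is -1; motors always walk toward the
    plus end.  ``azimuth0`` orients the helical lattice: the monomer at
    index 0 sits at that azimuth (degrees, right-handed about
    ``direction``, measured from +z, toward +x for a +y filament).
    """

    origin: np.ndarray
    direction: np.ndarray
    length: float
    polarity: int = 1
    monomer_rise: float = F_ACTIN_RISE_NM
    monomer_twist: float = F_ACTIN_TWIST_DEG
    azimuth0: float = 0.0
    radius: float = F_ACTIN_RADIUS_NM

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = _unit(self.direction)
        if self.length <= 0:
            raise ValueError("filament length must be positive")
        if self.monomer_rise <= 0:
            raise ValueError("monomer rise must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        # Orthonormal frame (e1, e2, direction); e1 is the azimuth origin.
        d = self.direction
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = _unit(ref - (ref @ d) * d)
        e2 = np.cross(d, e1)
        self._frame = (e1, e2)

    @property
    def n_sites(self) -> int:
        return int(np.floor(self.length / self.monomer_rise)) + 1

    def site_azimuth(self, index: int | np.ndarray) -> np.ndarray:
        """Lattice azimuth (degrees, mod 360) of monomer ``index``."""
        return np.mod(self.azimuth0 + np.asarray(index) * self.monomer_twist, 360.0)

    def axis_point(self, s: float | np.ndarray) -> np.ndarray:
        return self.origin + np.multiply.outer(np.asarray(s, dtype=float), self.direction)

    def axial_coord(self, point: np.ndarray) -> float:
        """Arc-length coordinate of ``point`` projected onto the axis."""
        return float((np.asarray(point, dtype=float) - self.origin) @ self.direction)

    def azimuth_of(self, point: np.ndarray) -> float:
        """Azimuth (degrees) of a world point about the filament axis."""
        e1, e2 = self._frame
        r = np.asarray(point, dtype=float) - self.origin
        return float(np.degrees(np.arctan2(r @ e2, r @ e1)))


@dataclass(frozen=True)
class BindingSite:
    """One actin monomer on a filament lattice, as a motor binding target."""

    filament_id: int
    monomer_index: int
    position: np.ndarray
    azimuth: float


def site_position(filament: ActinFilament, index: int) -> np.ndarray:
    """World position of binding site ``index``: on the axis at
    ``index * rise``, displaced radially by the filament radius at the
    lattice azimuth.

    Raises ``IndexError`` if the site falls outside the filament.
    """
    s = index * filament.monomer_rise
    if s < 0 or s > filament.length:
        raise IndexError(f"site index {index} outside filament (0..{filament.length} nm)")
    e1, e2 = filament._frame
    az = np.radians(filament.azimuth0 + index * filament.monomer_twist)
    radial = np.cos(az) * e1 + np.sin(az) * e2
    return filament.origin + s * filament.direction + filament.radius * radial


def site_positions(filament: ActinFilament, indices: np.ndarray) -> np.ndarray:
    """Vectorized :func:`site_position` (no bounds check) -> (n, 3) array."""
    idx = np.asarray(indices)
    e1, e2 = filament._frame
    az = np.radians(filament.azimuth0 + idx * filament.monomer_twist)
    return (
        filament.origin
        + np.multiply.outer(idx * filament.monomer_rise, filament.direction)
        + filament.radius * (np.multiply.outer(np.cos(az), e1) + np.multiply.outer(np.sin(az), e2))
    )


@dataclass
class InteractionParams:
    """Geometric scale of the motor-cargo complex."""

    cargo_diameter: float = 350.0
    motor_reach: float = 50.0

    def __post_init__(self) -> None:
        if self.cargo_diameter <= 0 or self.motor_reach <= 0:
            raise ValueError("cargo diameter and motor reach must be positive")


@dataclass
class IntersectionGeometry:
    """Two nearly perpendicular suspended filaments, vertically separated by
    ``separation_d`` (centre-to-centre) at the crossing."""

    original: ActinFilament
    intersecting: ActinFilament
    separation_d: float
    crossing_point: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 <= self.separation_d <= 250:
            raise ValueError("separation_d must lie in [0, 250] nm (analysis cutoff)")
        if self.crossing_point is None:
            # Closest point of the original axis to the intersecting axis.
            p, d1 = self.original.origin, self.original.direction
            q, d2 = self.intersecting.origin, self.intersecting.direction
            n = np.cross(d1, d2)
            if np.linalg.norm(n) < 1e-9:
                raise ValueError("filaments are parallel; no crossing")
            r = q - p
            s = float(np.cross(r, d2) @ n / (n @ n))
            self.crossing_point = p + s * d1
        self.crossing_point = np.asarray(self.crossing_point, dtype=float)


def mirror_angle(alpha: float) -> float:
    """Fold an approach angle from [0, 360) onto [0, 180] by mirror symmetry
    about the original filament's vertical plane."""
    a = float(np.mod(alpha, 360.0))
    return a if a <= 180.0 else 360.0 - a


def max_interaction_separation(
    alpha: float, params: InteractionParams | None = None
) -> float:
    """Maximum filament separation d_int(alpha) [nm] still permitting the
    cargo to reach the intersecting filament.

    Geometric construction: the cargo centre rides at radius R + L about the
    original filament at azimuth alpha; the highest point a motor can reach
    is centre-height + (R + L), so
    ``d_int = (R + L) * (1 + cos alpha)`` with R the cargo radius and L the
    motor reach.  Head-on (alpha = 0): cargo diameter + 2 reaches = 450 nm
    at defaults; alpha = 90 deg: R + L = 225 nm; alpha = 180 deg: 0.
    """
    params = params or InteractionParams()
    a = np.radians(mirror_angle(alpha))
    rl = params.cargo_diameter / 2.0 + params.motor_reach
    return float(rl * (1.0 + np.cos(a)))


def interacts(alpha: float, d: float, params: InteractionParams | None = None) -> bool:
    """Whether a cargo approaching at ``alpha`` can physically interact with
    an intersecting filament at separation ``d`` (boundary inclusive)."""
    if d < 0:
        raise ValueError("separation d must be non-negative")
    return d <= max_interaction_separation(alpha, params)


# Heat-map regimes: four interaction quadrants split at alpha = 60 deg and
# d = 125 nm (after mirroring), plus one non-interaction regime.
REGIME_LABELS = (
    "low_alpha_low_d",
    "low_alpha_high_d",
    "high_alpha_low_d",
    "high_alpha_high_d",
    "non_interaction",
)

_ALPHA_BOUNDARY_DEG = 60.0
_D_BOUNDARY_NM = 125.0


def regime_bin(alpha: float, d: float, params: InteractionParams | None = None) -> str:
    """Assign an (alpha, d) pair to one of the five heat-map regimes."""
    a = mirror_angle(alpha)
    if not interacts(a, d, params):
        return "non_interaction"
    low_a = a < _ALPHA_BOUNDARY_DEG
    low_d = d < _D_BOUNDARY_NM
    if low_a:
        return "low_alpha_low_d" if low_d else "low_alpha_high_d"
    return "high_alpha_low_d" if low_d else "high_alpha_high_d"
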