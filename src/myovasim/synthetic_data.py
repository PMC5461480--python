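"""Seeded generators of experiment-like inputs with known ground truth.

Every analysis operation in the package has a generator here producing its
input: noisy helical trajectories (localization noise 17/18/30 nm in
X/Y/Z at 100 ms frames, as for the real 3D tracking), binomial
photobleaching intensity traces, saw-tooth optical-trap force traces, and
STORM-like filament localization clouds (5 nm Z precision).  All
generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseModel",
    "gen_helical_trajectory",
    "gen_bleach_traces",
    "gen_trap_trace",
    "gen_filament_cloud",
]


@dataclass
class NoiseModel:
    """Per-axis Gaussian localization noise (nm) and the frame interval."""

    sigma_x: float = 17.0
    sigma_y: float = 18.0
    sigma_z: float = 30.0
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_y, self.sigma_z) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


def gen_helical_trajectory(
    pitch: float = 2160.0,
    radius: float = 225.0,
    velocity: float = 423.0,
    handedness: str = "left",
    duration: float = 30.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    phase0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy helical trajectory travelling along +y.

    Defaults echo the measured transport values (pitch 2,160 nm, velocity
    423 nm/s, orbit radius = cargo radius + motor reach).  Returns
    ``(times, centers)`` with centers in nm.  Handedness follows the
    package convention: left-handed = azimuth decreasing about +y.
    """
    if pitch <= 0 or velocity <= 0:
        raise ValueError("pitch and velocity must be positive")
    if handedness not in ("left", "right"):
        raise ValueError("handedness must be 'left' or 'right'")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, noise.frame_interval)
    turns_per_s = velocity / pitch
    sign = -1.0 if handedness == "left" else 1.0
    theta = phase0 + sign * 2.0 * math.pi * turns_per_s * t
    x = radius * np.sin(theta) + rng.normal(0.0, noise.sigma_x, len(t))
    y = velocity * t + rng.normal(0.0, noise.sigma_y, len(t))
    z = radius * np.cos(theta) + rng.normal(0.0, noise.sigma_z, len(t))
    return t, np.column_stack([x, y, z])


def gen_bleach_traces(
    n_fluorophores: int = 20,
    v: float = 100.0,
    tau: float = 10.0,
    n_traces: int = 200,
    duration: float = 40.0,
    frame_interval: float = 0.1,
    shot_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial photobleaching ensemble: each of ``n_fluorophores``
    fluorophores (intensity ``v`` each) survives to time t independently
    with probability exp(-t/tau).

    Returns ``(times, intensities)`` with intensities of shape
    ``(n_traces, n_frames)``.  ``tau = inf`` gives constant traces.
    """
    if n_fluorophores < 1:
        raise ValueError("need at least one fluorophore")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, frame_interval)
    # Per-fluorophore exponential bleach times; survivors at each frame.
    if math.isinf(tau):
        survivors = np.full((n_traces, len(t)), n_fluorophores, dtype=float)
    else:
        bleach_t = rng.exponential(tau, size=(n_traces, n_fluorophores))
        survivors = (bleach_t[:, :, None] > t[None, None, :]).sum(axis=1)
    intensity = v * survivors.astype(float)
    if shot_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, shot_noise_sd, intensity.shape)
    return t, intensity


def gen_trap_trace(
    stall_mean: float = 1.9,
    stall_sd: float = 0.0,
    k_trap: float = 0.019,
    n_events: int = 10,
    ramp_v: float = 100.0,
    rest_time: float = 1.0,
    plateau_time: float = 0.1,
    noise_sd: float = 0.0,
    frame_interval: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Saw-tooth trap force trace: repeated ramp-plateau-drop cycles.

    Each event ramps at ``ramp_v`` (nm/s, converted to force through
    ``k_trap``) to a peak drawn from N(stall_mean, stall_sd), holds a
    short plateau (shorter than the 250 ms detection window, so the
    rise-then-drop signature is visible to the stall detector), then
    drops to baseline -- the signature of motors pulling to stall and
    releasing.  Returns ``(times, force_pN)``.
    """
    if k_trap <= 0:
        raise ValueError("k_trap must be positive")
    rng = np.random.default_rng(seed)
    segs_t: list[np.ndarray] = []
    segs_f: list[np.ndarray] = []
    t0 = 0.0

    def _append(duration: float, f_fun) -> None:
        nonlocal t0
        n = max(int(round(duration / frame_interval)), 1)
        tt = t0 + frame_interval * np.arange(n)
        segs_t.append(tt)
        segs_f.append(f_fun(tt - t0))
        t0 = tt[-1] + frame_interval

    _append(rest_time, lambda td: np.zeros_like(td))
    ramp_rate = k_trap * ramp_v  # pN/s
    for _ in range(n_events):
        peak = max(float(rng.normal(stall_mean, stall_sd)), 0.1) \
            if stall_sd > 0 else stall_mean
        _append(peak / ramp_rate, lambda td, p=peak: ramp_rate * td)
        _append(plateau_time, lambda td, p=peak: np.full_like(td, p))
        _append(rest_time, lambda td: np.zeros_like(td))
    t = np.concatenate(segs_t)
    f = np.concatenate(segs_f)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, len(f))
    return t, f


def gen_filament_cloud(
    z_true: float,
    sigma_z: float = 5.0,
    n_points: int = 200,
    length: float = 2000.0,
    sigma_xy: float = 10.0,
    axis: str = "y",
    seed: int = 0,
) -> np.ndarray:
    """STORM-like localization cloud of a straight filament at height
    ``z_true`` (5 nm Z precision by default).  Returns (n, 3) positions."""
    if n_points < 1:
        raise ValueError("need at least one point")
    rng = np.random.default_rng(seed)
    along = rng.uniform(-length / 2.0, length / 2.0, n_points)
    off = rng.normal(0.0, sigma_xy, n_points)
    z = z_true + rng.normal(0.0, sigma_z, n_points)
    if axis == "y":
        return np.column_stack([off, along, z])
    return np.column_stack([along, off, z])
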