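"""Motor counting from photobleaching statistics and stall-force analysis
of optical-trap traces.

Photobleaching: with N independent fluorophores of unit intensity v, each
surviving to time t with probability p = exp(-t/tau), the across-trace
intensity variance is binomial, sigma_I^2(t) = v * I0 * p(1-p) with
I0 = N v the landing intensity.  Fitting that relation yields v without
resolving single steps, and the motor count follows as n = 2 I0 / v (two
fluorophore-tagged heads per motor).

Trap traces: stall events are the force maxima of saw-teeth, detected with
a 250 ms sliding window that must rise faster than +50 nm/s in its first
half and fall faster than -50 nm/s in its second half; the peak-force
sample is then decomposed into 1-4 Gaussian components selected by BIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

__all__ = [
    "BleachTrace",
    "StallEvent",
    "intensity_per_fluorophore",
    "motor_count",
    "detect_peak_forces",
    "stall_mixture",
]


@dataclass
class BleachTrace:
    """Ensemble of photobleaching intensity traces on a common time base."""

    times: np.ndarray          # (n_frames,) s
    intensity: np.ndarray      # (n_traces, n_frames) a.u.
    decay_rate: float | None = None  # fitted 1/tau, 1/s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if self.intensity.shape[1] != len(self.times):
            raise ValueError("intensity and times shapes disagree")


@dataclass(frozen=True)
class StallEvent:
    """One detected stall: time of the force peak and its magnitude."""

    time: float
    peak_force: float


def _fit_decay_time(t: np.ndarray, mean_i: np.ndarray) -> float:
    """Bleach time constant tau from the mean-intensity decay."""
    i0 = mean_i[0]
    if i0 <= 0:
        raise ValueError("degenerate trace: non-positive initial intensity")

    def model(tt, tau):
        return i0 * np.exp(-tt / tau)

    tau0 = max(float(t[-1]) / 3.0, 1e-3)
    popt, _ = curve_fit(model, t, mean_i, p0=[tau0], maxfev=5000)
    return float(abs(popt[0]))


def intensity_per_fluorophore(trace: BleachTrace) -> float:
    """Single-fluorophore intensity v from the binomial bleaching variance.

    tau is fitted from the mean-intensity decay first; v then comes from a
    weighted least-squares fit of sigma_I^2(t) = v * I0 * p(1-p) over the
    trace ensemble, using frames where p spans roughly [0.1, 1).

    Raises ``ValueError`` for traces that do not decay or carry no
    variance.
    """
    t = trace.times
    I = trace.intensity
    mean_i = I.mean(axis=0)
    scale = max(float(mean_i[0]) ** 2, 1e-300)
    if I.shape[0] < 2 or float(I.var(axis=0).max()) <= 1e-12 * scale:
        raise ValueError("degenerate input: zero across-trace variance")
    if mean_i[-1] > 0.9 * mean_i[0]:
        raise ValueError("trace does not decay enough to estimate v "
                         "(needs p to span ~[0.1, 1])")
    tau = _fit_decay_time(t, mean_i)
    trace.decay_rate = 1.0 / tau
    p = np.exp(-t / tau)
    var_i = I.var(axis=0, ddof=1)
    I0 = float(mean_i[0])
    keep = (p > 0.05) & (p < 0.999)
    if keep.sum() < 3:
        raise ValueError("too few frames in the informative bleaching range")
    x = (I0 * p * (1.0 - p))[keep]
    w = var_i[keep]
    # sigma^2 = v * x through the origin, weighted by x (frames with more
    # binomial signal dominate).
    v = float((x * w).sum() / (x * x).sum())
    if v <= 0:
        raise ValueError("non-positive fluorophore intensity estimate")
    return v


def motor_count(trace: BleachTrace, v: float | None = None) -> float:
    """Number of motors n = 2 I0 / v (one fluorophore per motor head, two
    heads per motor).  ``v`` defaults to :func:`intensity_per_fluorophore`
    on the same ensemble; I0 is the mean landing intensity.

    Scale-invariant: multiplying the trace by c scales I0 and v alike.
    """
    if v is None:
        v = intensity_per_fluorophore(trace)
    if v <= 0:
        raise ValueError("v must be positive")
    I0 = float(trace.intensity.mean(axis=0)[0])
    return 2.0 * I0 / v


def detect_peak_forces(
    times: np.ndarray,
    force: np.ndarray,
    trap_stiffness: float,
    window: float = 0.25,
    v_threshold: float = 50.0,
    release_fraction: float = 0.5,
) -> list[StallEvent]:
    """Stall-peak detection on a uniformly sampled force trace.

    A position of the 250 ms window qualifies when the displacement
    velocity (force / trap stiffness per unit time) over its first half
    exceeds ``+v_threshold`` and over its second half falls below
    ``-v_threshold``.  Qualifying windows are merged into one event per
    saw-tooth: successive windows belong to the same tooth as long as the
    force between them never falls below ``release_fraction`` of the
    running peak (a real release ends the tooth); the event's peak is the
    maximum force over the merged span.

    Raises ``ValueError`` if the trace is shorter than one window.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(force, dtype=float)
    if trap_stiffness <= 0:
        raise ValueError("trap_stiffness must be positive")
    if len(t) < 3:
        raise ValueError("force trace too short")
    dt = float(np.median(np.diff(t)))
    half = max(int(round(window / 2.0 / dt)), 1)
    if 2 * half + 1 > len(t):
        raise ValueError("force trace shorter than the detection window")
    x = f / trap_stiffness  # displacement, nm
    n = len(t)
    # Half-window velocities by least-squares slope (noise-robust, as for
    # low-pass-filtered detector data), vectorized as a correlation with
    # the slope kernel.
    tau = np.arange(half + 1) * dt
    kern = (tau - tau.mean())
    kern = kern / float((kern * kern).sum())
    slopes = np.correlate(x, kern, mode="valid")  # slope at each start
    starts = np.arange(0, n - 2 * half)
    v1 = slopes[starts]
    v2 = slopes[starts + half]
    idx = np.nonzero((v1 > v_threshold) & (v2 < -v_threshold))[0]
    # Peaks are read from a lightly smoothed trace (~25 ms boxcar) so the
    # reported force is the mechanical peak, not the localization-noise
    # maximum; qualification already uses noise-robust slopes.
    w = max(int(round(0.025 / dt)), 1)
    fs = np.convolve(f, np.ones(w) / w, mode="same") if w > 1 else f
    events: list[StallEvent] = []
    base = float(np.quantile(fs, 0.05))  # trace baseline; offset-free rule
    i = 0
    while i < len(idx):
        j = i
        lo = idx[i]
        hi = idx[i] + 2 * half + 1
        peak = float(fs[lo:hi].max())
        while j + 1 < len(idx):
            between = fs[idx[j] + half: idx[j + 1] + half + 1]
            if between.size and (float(between.min()) - base
                                 >= release_fraction * (peak - base)):
                j += 1
                hi = idx[j] + 2 * half + 1
                peak = max(peak, float(fs[idx[j]:hi].max()))
            else:
                break
        k = lo + int(np.argmax(fs[lo:hi]))
        events.append(StallEvent(time=float(t[k]), peak_force=peak))
        i = j + 1
    return events


def stall_mixture(
    forces: np.ndarray,
    k_range: range | tuple = (1, 2, 3, 4),
    min_events: int = 50,
    seed: int = 0,
):
    """Gaussian-mixture decomposition of a stall-force sample.

    Fits k-component mixtures for each k in ``k_range``, selects k by BIC,
    and returns ``(selected_k, components, bics)`` with components sorted
    by ascending mean, each ``(mean, sd, weight)``.

    Raises ``ValueError`` below ``min_events`` samples.
    """
    x = np.asarray(forces, dtype=float).reshape(-1, 1)
    if len(x) < min_events:
        raise ValueError(f"need >= {min_events} stall events, got {len(x)}")
    bics = {}
    fits = {}
    for k in k_range:
        gm = GaussianMixture(n_components=int(k), n_init=5, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(x)
        bics[int(k)] = float(gm.bic(x))
        fits[int(k)] = gm
    k_best = min(bics, key=bics.get)
    gm = fits[k_best]
    order = np.argsort(gm.means_.ravel())
    components = [
        (float(gm.means_.ravel()[i]),
         float(math.sqrt(gm.covariances_.ravel()[i])),
         float(gm.weights_.ravel()[i]))
        for i in order
    ]
    return k_best, components, bics
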