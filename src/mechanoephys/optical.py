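"""Calcium-trace analysis and soma morphometry.

The fluorescence stream is a ΔI/I time series sampled at the camera frame
rate (≤ 45 fps for the long-working-distance set-up).  The operations cover
ΔI/I computation, transient (peak) detection with a 3 s local-maximum
window, 10 %-of-peak response onset, the −2.5 s/+10 s alignment window,
single-exponential decay-constant fitting, responder classification against
a mechanical stimulus, and the polygon-based soma diameter-change measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from shapely.geometry import Polygon

__all__ = [
    "CalciumTrace",
    "CalciumResponse",
    "SomaOutline",
    "compute_dff",
    "detect_ca_peaks",
    "response_onset",
    "align_response_window",
    "fit_decay_tau",
    "classify_responder",
    "soma_diameter_change",
]

MAX_FRAME_RATE = 45.0


@dataclass
class CalciumTrace:
    """ΔI/I fluorescence time series on the camera clock."""

    frame_times: np.ndarray
    dff: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.frame_times.size != self.dff.size:
            raise ValueError("frame_times and dff must have equal length")
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frame_rate > MAX_FRAME_RATE:
            warnings.warn(f"frame_rate {self.frame_rate} exceeds the camera bound "
                          f"of {MAX_FRAME_RATE} fps")

    def __len__(self) -> int:
        return int(self.dff.size)


@dataclass
class CalciumResponse:
    peak_time: float
    peak_amplitude: float
    onset_time: float
    decay_tau: Optional[float]
    responded: bool

    def __post_init__(self) -> None:
        if self.responded:
            if self.onset_time > self.peak_time:
                raise ValueError("onset must not follow the peak")
            if self.peak_amplitude <= 0:
                raise ValueError("responded requires positive peak amplitude")


@dataclass
class SomaOutline:
    """Simple polygon outlining a soma at one timepoint label."""

    vertices: np.ndarray
    label: str = "before"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline needs at least 3 (x, y) vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("outline must be a simple, non-degenerate polygon")
        self.vertices = v

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def compute_dff(frame_times: np.ndarray, intensity: np.ndarray,
                frame_rate: float, baseline_mode: str = "prestim_mean",
                stim_time: Optional[float] = None,
                percentile: float = 8.0) -> CalciumTrace:
    """ΔI/I = (I − I₀)/I₀ from a raw mean-intensity trace.

    ``baseline_mode`` 'prestim_mean' uses the mean intensity before
    ``stim_time`` (the whole trace when no stimulus is given);
    'percentile' uses a low percentile (8th by default) of the whole trace,
    which is robust when activity rides on the baseline throughout.
    """
    t = np.asarray(frame_times, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("intensities must be positive")
    if baseline_mode == "prestim_mean":
        sel = t < stim_time if stim_time is not None else slice(None)
        base = intensity[sel]
        if base.size == 0:
            raise ValueError("no pre-stimulus frames for baseline")
        i0 = float(np.mean(base))
    elif baseline_mode == "percentile":
        i0 = float(np.percentile(intensity, percentile))
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if i0 <= 0:
        raise ValueError("non-positive baseline intensity")
    return CalciumTrace(frame_times=t, dff=(intensity - i0) / i0, frame_rate=frame_rate)


def detect_ca_peaks(trace: CalciumTrace, window: float = 3.0) -> list[int]:
    """Frames that are the strict maximum of all frames within ±window/2.

    A frame qualifies only if it strictly exceeds every other frame whose
    time lies within half the window on either side (truncated at the trace
    edges); the first and last frame never qualify.  Deterministic, may be
    empty.
    """
    if window <= 1.0 / trace.frame_rate:
        raise ValueError("window must exceed the frame interval")
    t, y = trace.frame_times, trace.dff
    peaks = []
    half = window / 2.0
    for i in range(1, len(y) - 1):
        lo = int(np.searchsorted(t, t[i] - half, side="left"))
        hi = int(np.searchsorted(t, t[i] + half, side="right"))
        neighbours = np.concatenate((y[lo:i], y[i + 1:hi]))
        if neighbours.size and np.all(y[i] > neighbours):
            peaks.append(i)
    return peaks


def response_onset(trace: CalciumTrace, peak: int, fraction: float = 0.10
                   ) -> tuple[float, bool]:
    """Onset time where ΔI/I last rises through ``fraction`` × peak amplitude.

    Walking back from the peak, the onset is the latest crossing of the
    threshold below which the trace dips before the peak (so the rise is
    sustained from onset to peak), linearly interpolated between frames.
    Returns ``(onset_time, flagged)``; ``flagged`` marks a trace that never
    sits below threshold before the peak, whose onset defaults to the first
    frame.
    """
    t, y = trace.frame_times, trace.dff
    if not 0 <= peak < len(y):
        raise ValueError("peak index out of range")
    if peak == 0:
        raise ValueError("no pre-peak segment")
    level = fraction * y[peak]
    below = np.nonzero(y[:peak] < level)[0]
    if below.size == 0:
        return float(t[0]), True
    j = int(below[-1])
    t_on = _interp_time(t[j], y[j], t[j + 1], y[j + 1], level)
    return float(t_on), False


def _interp_time(t0, v0, t1, v1, level):
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def align_response_window(trace: CalciumTrace, t0: float, pre: float = 2.5,
                          post: float = 10.0) -> tuple[CalciumTrace, bool]:
    """Trace restricted to [t0 − pre, t0 + post] with time re-zeroed at t0.

    Returns ``(windowed_trace, truncated)``; ``truncated`` flags a window
    clipped by the trace boundaries.
    """
    t = trace.frame_times
    lo, hi = t0 - pre, t0 + post
    truncated = bool(lo < t[0] or hi > t[-1])
    if truncated:
        warnings.warn("alignment window truncated at trace boundary")
    sel = (t >= lo) & (t <= hi)
    return (CalciumTrace(frame_times=t[sel] - t0, dff=trace.dff[sel],
                         frame_rate=trace.frame_rate), truncated)


def fit_decay_tau(trace: CalciumTrace, peak: int, floor_fraction: float = 0.10,
                  min_frames: int = 10) -> Optional[float]:
    """Decay constant τ (s) of A·exp(−(t−t_peak)/τ) on the post-peak tail.

    The fit segment runs from the peak down to where ΔI/I first falls below
    ``floor_fraction`` of the peak (or to the trace end).  A non-decaying
    tail yields ``None`` with a warning rather than a spurious constant.
    """
    t, y = trace.frame_times, trace.dff
    if not 0 <= peak < len(y):
        raise ValueError("peak index out of range")
    amp = y[peak]
    if amp <= 0:
        warnings.warn("non-positive peak amplitude; no decay fit")
        return None
    tail = y[peak:]
    below = np.nonzero(tail < floor_fraction * amp)[0]
    end = peak + (int(below[0]) if below.size else tail.size)
    ts = t[peak:end] - t[peak]
    ys = y[peak:end]
    if ys.size < min_frames:
        warnings.warn("fewer than 10 post-peak frames; no decay fit")
        return None
    pos = ys > 0
    if pos.sum() < 2 or ys[-1] >= amp:
        warnings.warn("non-decaying tail; no decay fit")
        return None
    slope = np.polyfit(ts[pos], np.log(ys[pos]), 1)[0]
    if slope >= 0:
        warnings.warn("non-decaying tail; no decay fit")
        return None
    try:
        popt, _ = curve_fit(lambda x, A, tau: A * np.exp(-x / tau), ts, ys,
                            p0=(amp, -1.0 / slope), maxfev=10000)
    except RuntimeError:
        warnings.warn("decay fit did not converge")
        return None
    tau = float(popt[1])
    return tau if tau > 0 else None


def classify_responder(trace: CalciumTrace, stim, k: float = 5.0,
                       search_window: float = 10.0,
                       peak_window: float = 3.0) -> CalciumResponse:
    """Did the stimulus evoke a calcium transient?

    A unit responded iff a detected peak inside ``(contact_on,
    contact_on + search_window]`` exceeds ``k`` times the pre-stimulus ΔI/I
    standard deviation.  Requires a pre-stimulus baseline segment; every
    criterion (k, windows) travels with the result via the trace metadata of
    the caller.
    """
    t, y = trace.frame_times, trace.dff
    pre = y[t < stim.contact_on]
    if pre.size < 2:
        raise ValueError("no pre-stimulus baseline available")
    noise_sd = float(np.std(pre, ddof=1))
    threshold = k * noise_sd
    candidates = [i for i in detect_ca_peaks(trace, peak_window)
                  if stim.contact_on < t[i] <= stim.contact_on + search_window
                  and y[i] > threshold]
    if not candidates:
        return CalciumResponse(peak_time=float("nan"), peak_amplitude=0.0,
                               onset_time=float("nan"), decay_tau=None,
                               responded=False)
    best = max(candidates, key=lambda i: y[i])
    onset, _ = response_onset(trace, best)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau = fit_decay_tau(trace, best)
    return CalciumResponse(peak_time=float(t[best]), peak_amplitude=float(y[best]),
                           onset_time=onset, decay_tau=tau, responded=True)


def _projection_widths(vertices: np.ndarray, n_directions: int) -> np.ndarray:
    """Width of the polygon's projection onto directions θ_k = kπ/n."""
    theta = np.pi * np.arange(n_directions) / n_directions
    u = np.stack([np.cos(theta), np.sin(theta)])     # (2, n)
    proj = vertices @ u                              # (n_vertices, n)
    return proj.max(axis=0) - proj.min(axis=0)


def soma_diameter_change(before: SomaOutline, during: SomaOutline,
                         n_directions: int = 180) -> float:
    """Largest directional diameter increase of the soma under compression (µm).

    Both outlines are translated to their centroids, the diameter along each
    of ``n_directions`` uniformly sampled directions in [0, π) is the width
    of the polygon's projection, and the change is the maximum over
    directions of (during − before) — the densely sampled version of picking
    the diagonal with the largest diameter change.
    """
    if n_directions < 2:
        raise ValueError("need at least 2 directions")
    widths = []
    for outline in (before, during):
        c = outline.polygon.centroid
        v = outline.vertices - np.array([c.x, c.y])
        widths.append(_projection_widths(v, n_directions))
    return float(np.max(widths[1] - widths[0]))
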