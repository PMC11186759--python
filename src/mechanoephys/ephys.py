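"""Spike-train analytics for HD-MEA recordings.

Firing rates (windowed, binned and epoch-based), inter-spike-interval
statistics, spike-sorting quality filtering, network-burst detection on the
population rate, and evoked-spike latency relative to mechanical contact.

Times are seconds on the master (HD-MEA) clock.  Spike times are treated at
the acquisition resolution of 1/20000 s; trains carry their recording span
and all window conventions are left-closed / right-open unless stated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "EpochSet",
    "BurstSet",
    "QualityMetrics",
    "mean_firing_rate",
    "binned_firing_rate",
    "epoch_firing_rates",
    "percent_rate_change",
    "isi_distribution",
    "unit_quality_filter",
    "detect_network_bursts",
    "evoked_spike_latency",
]

SPIKE_TIME_RESOLUTION = 1.0 / 20000.0


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit within a recording span."""

    unit_id: str
    spike_times: np.ndarray
    recording_span: tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        start, stop = self.recording_span
        if not stop > start:
            raise ValueError("recording span must have positive length")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError("spike times must be sorted ascending")
            if t[0] < start or t[-1] > stop:
                raise ValueError("spike times must lie within the recording span")
            ticks = np.round(t / SPIKE_TIME_RESOLUTION).astype(np.int64)
            if np.unique(ticks).size != ticks.size:
                raise ValueError("duplicate spike times at 1/20000 s resolution")
        self.spike_times = t

    def __len__(self) -> int:
        return int(self.spike_times.size)

    def count_in(self, start: float, stop: float) -> int:
        """Number of spikes in [start, stop)."""
        lo, hi = np.searchsorted(self.spike_times, (start, stop), side="left")
        return int(hi - lo)


@dataclass(frozen=True)
class EpochSet:
    """Before / during / after analysis windows around one stimulus."""

    before: tuple[float, float]
    during: tuple[float, float]
    after: tuple[float, float]

    def __post_init__(self) -> None:
        windows = (self.before, self.during, self.after)
        for a, b in windows:
            if not b > a:
                raise ValueError("epoch windows must have positive length")
        for (_, end), (start, _) in zip(windows, windows[1:]):
            if start < end:
                raise ValueError("epochs must be ordered and non-overlapping")

    @classmethod
    def around(cls, stimulus, pre: float = 150.0, post: float = 150.0) -> "EpochSet":
        """Windows of ``pre`` s before contact, the contact itself, and
        ``post`` s after release (the 2.5 min / 60 s / 2.5 min layout)."""
        on, off = stimulus.contact_on, stimulus.contact_off
        return cls(before=(on - pre, on), during=(on, off), after=(off, off + post))


@dataclass
class BurstSet:
    """Sorted, non-overlapping network-burst intervals."""

    bursts: list[tuple[float, float]]

    def __post_init__(self) -> None:
        b = [(float(s), float(e)) for s, e in self.bursts]
        for s, e in b:
            if not e > s:
                raise ValueError("burst end must exceed start")
        for (_, e0), (s1, _) in zip(b, b[1:]):
            if s1 < e0:
                raise ValueError("bursts must be sorted and non-overlapping")
        self.bursts = b

    @property
    def ibis(self) -> list[tuple[float, float]]:
        """Inter-burst intervals: the gaps between consecutive bursts."""
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.bursts, self.bursts[1:])]

    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.bursts))

    def __len__(self) -> int:
        return len(self.bursts)


@dataclass(frozen=True)
class QualityMetrics:
    isi_violation_ratio: float
    snr: float
    passes: bool


def mean_firing_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count in [start, stop) divided by the window length, in Hz."""
    start, stop = window
    if not stop > start:
        raise ValueError("window must have positive length")
    return train.count_in(start, stop) / (stop - start)


def binned_firing_rate(train: SpikeTrain, bin_width: float = 30.0,
                       span: Optional[tuple[float, float]] = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Firing rate in consecutive ``bin_width`` s bins tiling the span.

    Returns ``(edges, rates)`` with ``len(edges) == len(rates) + 1``.  Bins
    are left-closed/right-open, so a spike exactly on an interior edge counts
    in the bin to its right; every spike lands in exactly one bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    start, stop = span if span is not None else train.recording_span
    n_bins = max(1, int(np.ceil((stop - start) / bin_width - 1e-12)))
    edges = start + bin_width * np.arange(n_bins + 1)
    t = train.spike_times
    t = t[(t >= start) & (t < edges[-1])]
    idx = np.floor((t - start) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts / bin_width


def epoch_firing_rates(train: SpikeTrain, epochs: EpochSet
                       ) -> tuple[float, float, float]:
    """Mean firing rate in the before, during and after windows (Hz)."""
    return (mean_firing_rate(train, epochs.before),
            mean_firing_rate(train, epochs.during),
            mean_firing_rate(train, epochs.after))


def percent_rate_change(r_ref: float, r_new: float) -> float:
    """Relative rate change 100·(r_new − r_ref)/r_ref, in percent."""
    if r_ref <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (r_new - r_ref) / r_ref


def isi_distribution(train: SpikeTrain) -> np.ndarray:
    """Consecutive inter-spike intervals (s); empty with a warning for <2 spikes."""
    if len(train) < 2:
        warnings.warn(f"unit {train.unit_id}: fewer than 2 spikes, no ISIs")
        return np.empty(0)
    return np.diff(train.spike_times)


def unit_quality_filter(train: SpikeTrain, footprint, noise_sd: float,
                        refractory: float = 0.002,
                        isi_threshold: float = 0.5,
                        snr_threshold: float = 5.0) -> QualityMetrics:
    """Spike-sorting curation metrics with the conservative thresholds
    (ISI-violation ratio ≤ 0.5, SNR ≥ 5.0).

    The violation ratio is the fraction of ISIs shorter than the refractory
    period (2 ms default); SNR is the largest template trough magnitude
    across the footprint's electrodes divided by ``noise_sd`` (µV).
    ``footprint`` may be a :class:`~mechanoephys.waveforms.UnitFootprint` or
    a bare (electrodes × samples) template array.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    isis = np.diff(train.spike_times) if len(train) >= 2 else np.empty(0)
    ratio = float(np.mean(isis < refractory)) if isis.size else 0.0

    templates = getattr(footprint, "templates", footprint)
    if isinstance(templates, dict):
        templates = next(iter(templates.values()))
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    n_lead = max(1, int(round(templates.shape[1] * 0.1)))
    baseline = templates[:, :n_lead].mean(axis=1)
    trough = float(np.max(baseline - templates.min(axis=1)))
    snr = trough / noise_sd
    return QualityMetrics(isi_violation_ratio=ratio, snr=snr,
                          passes=bool(ratio <= isi_threshold and snr >= snr_threshold))


def detect_network_bursts(trains: Sequence[SpikeTrain], bin: float = 0.025,
                          rate_threshold: float = 3.0,
                          min_duration: float = 0.05,
                          merge_gap: float = 0.1,
                          smooth_bins: int = 3,
                          baseline_percentile: float = 25.0) -> BurstSet:
    """Network bursts from a population-rate threshold.

    The per-unit-normalised population rate (summed counts per bin divided
    by ``n_units·bin``), boxcar-smoothed over ``smooth_bins`` bins, is
    compared against ``rate_threshold`` times a baseline reference rate —
    the ``baseline_percentile``-th percentile of the *nonzero* raw bin
    rates.  A lower-quartile reference estimates the out-of-burst rate
    robustly even when bursts occupy a large fraction of the recording
    (the median of nonzero bins drifts up with burst occupancy and then
    fragments bursts firing just above it).  Supra-threshold runs of bins
    are merged when separated by less than ``merge_gap`` and discarded when
    shorter than ``min_duration`` (hysteresis-like smoothing).
    Deterministic; an empty or silent population yields an empty burst set.
    """
    if not trains:
        return BurstSet([])
    start = min(t.recording_span[0] for t in trains)
    stop = max(t.recording_span[1] for t in trains)
    n_bins = max(1, int(np.ceil((stop - start) / bin - 1e-12)))
    counts = np.zeros(n_bins)
    for tr in trains:
        idx = np.floor((tr.spike_times - start) / bin).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        counts += np.bincount(idx, minlength=n_bins)
    rate = counts / (len(trains) * bin)
    nonzero = rate[rate > 0]
    if nonzero.size == 0:
        return BurstSet([])
    threshold = rate_threshold * float(np.percentile(nonzero, baseline_percentile))
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        smoothed = np.convolve(rate, kernel, mode="same")
    else:
        smoothed = rate
    active = smoothed >= threshold
    if not active.any():
        return BurstSet([])

    # runs of active bins → intervals
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    intervals = [(start + a * bin, start + b * bin)
                 for a, b in zip(edges[::2], edges[1::2])]
    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    kept = [(s, e) for s, e in merged if e - s >= min_duration]
    return BurstSet(kept)


def evoked_spike_latency(contact_on: float, train: SpikeTrain,
                         search_window: float = 0.5) -> Optional[float]:
    """Latency (s) from contact to the first spike in (contact_on, contact_on+w].

    ``None`` when no spike falls in the window — an unevoked stimulus is
    reported as missing, never imputed.  The contact sample itself is
    excluded (strictly later spikes only).
    """
    t = train.spike_times
    i = int(np.searchsorted(t, contact_on, side="right"))
    if i >= t.size:
        return None
    lat = t[i] - contact_on
    return float(lat) if lat <= search_window else None
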