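"""Extracellular spike-waveform features and epoch-relative change analysis.

Templates are mean extracellular waveforms (µV, 20 kHz unless stated) on the
electrodes of a unit's footprint — the spatial pattern of its spike across a
high-density electrode grid.  Features follow the negative-trough convention
of extracellular spikes: amplitude is the baseline-to-trough magnitude,
halfwidth the full width of the trough at half depth, and the repolarization
slope the linear rate of return from the trough to the baseline re-crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnitFootprint",
    "WaveformFeatures",
    "extract_features",
    "epoch_mean_template",
    "relative_feature_change",
    "amplitude_change_vs_distance",
]


class FlatTemplateError(ValueError):
    """Raised for templates with no spike deflection."""


@dataclass
class UnitFootprint:
    """Per-electrode mean templates of one unit, per epoch.

    ``templates`` maps an epoch label ('before', 'during', 'after', ...) to
    an (n_electrodes × n_samples) µV array; ``electrode_xy`` holds µm
    coordinates on the pitch grid and ``target_electrode`` marks the
    electrode under the compression site.
    """

    unit_id: str
    electrode_ids: np.ndarray
    electrode_xy: np.ndarray
    templates: dict[str, np.ndarray]
    sampling: float = 20000.0
    target_electrode: Optional[int] = None

    def __post_init__(self) -> None:
        self.electrode_ids = np.asarray(self.electrode_ids)
        self.electrode_xy = np.asarray(self.electrode_xy, dtype=float)
        if self.electrode_xy.shape != (self.electrode_ids.size, 2):
            raise ValueError("electrode_xy must be (n_electrodes, 2)")
        n_samples = None
        for epoch, tpl in self.templates.items():
            tpl = np.asarray(tpl, dtype=float)
            if tpl.shape[0] != self.electrode_ids.size:
                raise ValueError(f"epoch {epoch!r}: template rows != n_electrodes")
            if n_samples is None:
                n_samples = tpl.shape[1]
            elif tpl.shape[1] != n_samples:
                raise ValueError("all epoch templates must have equal length")
            self.templates[epoch] = tpl
        if self.target_electrode is not None and \
                self.target_electrode not in set(self.electrode_ids.tolist()):
            raise ValueError("target_electrode not in electrode_ids")

    def electrode_index(self, electrode_id) -> int:
        idx = np.nonzero(self.electrode_ids == electrode_id)[0]
        if idx.size == 0:
            raise KeyError(f"electrode {electrode_id} not in footprint")
        return int(idx[0])


@dataclass(frozen=True)
class WaveformFeatures:
    amplitude: float             # µV, baseline→trough (or peak-to-peak)
    halfwidth: float             # ms, FWHM of the trough
    repolarization_slope: float  # µV/ms, trough → baseline re-crossing


def _interp_crossing(t0, v0, t1, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def extract_features(template: np.ndarray, sampling: float,
                     baseline_fraction: float = 0.1,
                     amplitude_mode: str = "trough",
                     slope_mode: str = "recross") -> WaveformFeatures:
    """Amplitude, halfwidth and repolarization slope of one mean waveform.

    Baseline is the mean of the first ``baseline_fraction`` of samples.
    The half-depth crossings are linearly interpolated, taking the first
    crossing on each side walking outward from the trough.  ``amplitude_mode``
    'peak_to_peak' replaces the baseline-to-trough amplitude with max-min;
    ``slope_mode`` 'max_derivative' replaces the linear-fit repolarization
    slope with the steepest post-trough derivative.
    """
    w = np.asarray(template, dtype=float)
    if sampling <= 0:
        raise ValueError("sampling must be positive")
    if w.size < 4 or np.ptp(w) == 0:
        raise FlatTemplateError("no spike deflection in template")
    dt_ms = 1000.0 / sampling
    t = np.arange(w.size) * dt_ms
    n_lead = max(1, int(round(w.size * baseline_fraction)))
    baseline = float(np.mean(w[:n_lead]))

    i_min = int(np.argmin(w))
    depth = baseline - w[i_min]
    if depth <= 0:
        raise FlatTemplateError("no spike deflection in template")
    amplitude = float(np.max(w) - w[i_min]) if amplitude_mode == "peak_to_peak" else float(depth)

    half = baseline - depth / 2.0
    # left crossing
    t_left = t[0]
    for i in range(i_min, 0, -1):
        if w[i - 1] >= half > w[i] or (w[i - 1] >= half and w[i] < half):
            t_left = _interp_crossing(t[i - 1], w[i - 1], t[i], w[i], half)
            break
    # right crossing
    t_right = t[-1]
    for i in range(i_min, w.size - 1):
        if w[i] < half <= w[i + 1]:
            t_right = _interp_crossing(t[i], w[i], t[i + 1], w[i + 1], half)
            break
    halfwidth = float(t_right - t_left)

    # repolarization: trough → first baseline re-crossing
    j = i_min
    while j < w.size - 1 and w[j + 1] < baseline:
        j += 1
    j = min(j + 1, w.size - 1)
    if slope_mode == "max_derivative":
        seg = w[i_min:j + 1]
        slope = float(np.max(np.diff(seg)) / dt_ms) if seg.size > 1 else 0.0
    else:
        ts, vs = t[i_min:j + 1], w[i_min:j + 1]
        slope = float(np.polyfit(ts, vs, 1)[0]) if ts.size > 1 else 0.0
    return WaveformFeatures(amplitude=amplitude, halfwidth=halfwidth,
                            repolarization_slope=slope)


def epoch_mean_template(waveforms: Sequence[np.ndarray]
                        ) -> tuple[Optional[np.ndarray], int]:
    """Pointwise mean of spike-aligned waveforms; (None, 0) for an empty epoch."""
    if len(waveforms) == 0:
        warnings.warn("empty epoch: no waveforms to average")
        return None, 0
    stack = np.asarray(waveforms, dtype=float)
    return stack.mean(axis=0), int(stack.shape[0])


def relative_feature_change(before: WaveformFeatures, during: WaveformFeatures
                            ) -> dict[str, float]:
    """Per-feature during/before ratios (the epoch-relative change statistic)."""
    ratios = {}
    for name in ("amplitude", "halfwidth", "repolarization_slope"):
        b = getattr(before, name)
        if b == 0:
            raise ValueError(f"before-epoch {name} is zero; ratio undefined")
        ratios[name] = getattr(during, name) / b
    return ratios


def amplitude_change_vs_distance(footprint: UnitFootprint,
                                 before_epoch: str = "before",
                                 during_epoch: str = "during",
                                 amplitude_mode: str = "trough") -> pd.DataFrame:
    """Waveform-feature ratios per electrode against distance from the target.

    For every electrode of the footprint the Euclidean distance (µm) from
    the target electrode and the during/before feature ratios are tabulated,
    sorted by distance.  The target row sits at distance zero.
    """
    if footprint.target_electrode is None:
        raise ValueError("footprint has no target electrode")
    for epoch in (before_epoch, during_epoch):
        if epoch not in footprint.templates:
            raise ValueError(f"missing {epoch!r} templates")
    if footprint.electrode_ids.size < 2:
        raise ValueError("need templates on at least 2 electrodes")
    xy = footprint.electrode_xy
    target_xy = xy[footprint.electrode_index(footprint.target_electrode)]
    dist = np.hypot(*(xy - target_xy).T)

    rows = []
    for i, eid in enumerate(footprint.electrode_ids):
        fb = extract_features(footprint.templates[before_epoch][i],
                              footprint.sampling, amplitude_mode=amplitude_mode)
        fd = extract_features(footprint.templates[during_epoch][i],
                              footprint.sampling, amplitude_mode=amplitude_mode)
        r = relative_feature_change(fb, fd)
        rows.append({"electrode_id": eid, "distance_from_target_um": dist[i],
                     "amplitude_ratio": r["amplitude"],
                     "halfwidth_ratio": r["halfwidth"],
                     "repolarization_slope_ratio": r["repolarization_slope"]})
    table = pd.DataFrame(rows).sort_values(
        ["distance_from_target_um", "electrode_id"], kind="stable")
    return table.reset_index(drop=True)
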