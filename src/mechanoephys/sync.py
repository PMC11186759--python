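"""TTL time-base alignment of instrument streams onto the master clock.

The HD-MEA acquisition (20 kHz) is the master clock; AFM and camera events
are TTL-stamped on both their own clock and the master, and a linear map
``t_master = drift · t_stream + offset`` is recovered per stream by least
squares over greedily paired events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyncMap", "build_sync_map", "map_time", "invert_time"]


@dataclass
class SyncMap:
    stream: str
    offset: float          # s
    drift: float           # dimensionless, master = drift*stream + offset
    n_paired_events: int
    rms_residual: float    # s
    unpaired_stream: list = field(default_factory=list)
    unpaired_master: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.rms_residual):
            raise ValueError("residual must be finite")
        if not 0.99 <= self.drift <= 1.01:
            warnings.warn(f"stream {self.stream!r}: drift {self.drift} outside [0.99, 1.01]")


def build_sync_map(stream_events, master_events, pairing_tolerance: float = 0.05,
                   stream: str = "stream") -> SyncMap:
    """Linear clock map from TTL event times stamped on both clocks.

    Events are paired greedily in order: the offset guess from the first
    event pair anchors the expected master time of each stream event, and
    the next unused master event within ``pairing_tolerance`` is taken.
    Offset and drift follow from a least-squares line through the pairs;
    unpaired events on either side are reported on the map.
    """
    s = np.sort(np.asarray(stream_events, dtype=float))
    m = np.sort(np.asarray(master_events, dtype=float))
    if s.size < 2 or m.size < 2:
        raise ValueError("cannot align: need at least 2 events per stream")
    offset0 = m[0] - s[0]
    pairs_s, pairs_m = [], []
    unpaired_m = []
    j = 0
    for si in s:
        expected = si + offset0
        while j < m.size and m[j] < expected - pairing_tolerance:
            unpaired_m.append(float(m[j]))
            j += 1
        if j < m.size and abs(m[j] - expected) <= pairing_tolerance:
            pairs_s.append(si)
            pairs_m.append(m[j])
            j += 1
    unpaired_m.extend(float(x) for x in m[j:])
    if len(pairs_s) < 2:
        raise ValueError("cannot align: fewer than 2 paired events")
    ps, pm = np.array(pairs_s), np.array(pairs_m)
    drift, offset = np.polyfit(ps, pm, 1)
    resid = pm - (drift * ps + offset)
    unpaired_s = sorted(set(s.tolist()) - set(ps.tolist()))
    return SyncMap(stream=stream, offset=float(offset), drift=float(drift),
                   n_paired_events=int(ps.size),
                   rms_residual=float(np.sqrt(np.mean(resid**2))),
                   unpaired_stream=unpaired_s, unpaired_master=unpaired_m)


def map_time(sync: SyncMap, t_stream):
    """Stream-clock time(s) → master-clock time(s)."""
    return sync.drift * np.asarray(t_stream, dtype=float) + sync.offset


def invert_time(sync: SyncMap, t_master):
    """Master-clock time(s) → stream-clock time(s)."""
    return (np.asarray(t_master, dtype=float) - sync.offset) / sync.drift
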