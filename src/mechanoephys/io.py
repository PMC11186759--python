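"""Readers and writers for the on-disk experiment formats.

* Force curves: tab-separated text with ``#`` header metadata lines
  (``spring_constant_N_per_m``, ``bead_radius_um``, ``speed_um_per_s``,
  ``timestamp_s``) and columns ``time_s, height_um, deflection_nm,
  segment`` — the text-export layout of AFM control software.
* Spikes and templates: one HDF5 file with ``/units/<id>/spike_times`` (s),
  ``/units/<id>/templates/<epoch>`` (electrodes × samples, µV) and
  ``/electrodes/xy`` (µm); plus a CSV fallback for spike times.
* Calcium traces, TTL event tables: CSV.  Stimulus schedules and
  ground-truth manifests: JSON.

All writers are deterministic (sorted keys, fixed float formatting, HDF5
object timestamps disabled) so a fixed seed reproduces byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .ephys import SpikeTrain
from .mechanics import ForceCurve, MechStimulus
from .optical import CalciumTrace
from .waveforms import UnitFootprint

__all__ = [
    "write_force_curve", "read_force_curve",
    "write_spikes_h5", "read_spikes_h5",
    "write_spike_times_csv", "read_spike_times_csv",
    "write_calcium_csv", "read_calcium_csv",
    "write_ttl_csv", "read_ttl_csv",
    "write_schedule_json", "read_schedule_json",
    "write_manifest_json", "read_manifest_json",
    "write_bundle",
]

_FLOAT_FMT = "%.10g"


def write_force_curve(path, curve: ForceCurve) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# spring_constant_N_per_m={curve.spring_constant!r}\n")
        fh.write(f"# bead_radius_um={curve.bead_radius!r}\n")
        fh.write(f"# speed_um_per_s={curve.speed!r}\n")
        fh.write(f"# timestamp_s={curve.timestamp!r}\n")
        fh.write("time_s\theight_um\tdeflection_nm\tsegment\n")
        for t, z, d, s in zip(curve.time, curve.height, curve.deflection, curve.segment):
            fh.write(f"{float(t)!r}\t{float(z)!r}\t{float(d)!r}\t{s}\n")


def read_force_curve(path) -> ForceCurve:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = float(val)
            elif line and not line.startswith("time_s"):
                rows.append(line.split("\t"))
    arr = np.array([[r[0], r[1], r[2]] for r in rows], dtype=float)
    seg = np.array([r[3] for r in rows], dtype=object)
    return ForceCurve(time=arr[:, 0], height=arr[:, 1], deflection=arr[:, 2],
                      segment=seg,
                      spring_constant=meta["spring_constant_N_per_m"],
                      bead_radius=meta["bead_radius_um"],
                      speed=meta["speed_um_per_s"],
                      timestamp=meta.get("timestamp_s", 0.0))


def write_spikes_h5(path, trains: list[SpikeTrain],
                    footprints: Optional[list[UnitFootprint]] = None) -> None:
    fps = {fp.unit_id: fp for fp in footprints} if footprints else {}
    with h5py.File(path, "w", track_order=False) as f:
        units = f.create_group("units")
        for tr in trains:
            g = units.create_group(tr.unit_id)
            g.create_dataset("spike_times", data=tr.spike_times, track_times=False)
            g.attrs["span_start"] = tr.recording_span[0]
            g.attrs["span_stop"] = tr.recording_span[1]
            fp = fps.get(tr.unit_id)
            if fp is not None:
                tg = g.create_group("templates")
                for epoch in sorted(fp.templates):
                    tg.create_dataset(epoch, data=fp.templates[epoch],
                                      track_times=False)
                g.attrs["target_electrode"] = -1 if fp.target_electrode is None \
                    else int(fp.target_electrode)
                g.attrs["sampling"] = fp.sampling
                eg = g.create_group("electrodes")
                eg.create_dataset("xy", data=fp.electrode_xy, track_times=False)
                eg.create_dataset("ids", data=np.asarray(fp.electrode_ids, dtype=np.int64),
                                  track_times=False)


def read_spikes_h5(path) -> tuple[list[SpikeTrain], list[UnitFootprint]]:
    trains, footprints = [], []
    with h5py.File(path, "r") as f:
        for uid in sorted(f["units"]):
            g = f["units"][uid]
            span = (float(g.attrs["span_start"]), float(g.attrs["span_stop"]))
            trains.append(SpikeTrain(unit_id=uid, spike_times=g["spike_times"][...],
                                     recording_span=span))
            if "templates" in g:
                templates = {ep: g["templates"][ep][...] for ep in g["templates"]}
                target = int(g.attrs["target_electrode"])
                footprints.append(UnitFootprint(
                    unit_id=uid, electrode_ids=g["electrodes"]["ids"][...],
                    electrode_xy=g["electrodes"]["xy"][...], templates=templates,
                    sampling=float(g.attrs["sampling"]),
                    target_electrode=None if target < 0 else target))
    return trains, footprints


def write_spike_times_csv(path, trains: list[SpikeTrain]) -> None:
    rows = [(tr.unit_id, t, tr.recording_span[0], tr.recording_span[1])
            for tr in trains for t in tr.spike_times]
    df = pd.DataFrame(rows, columns=["unit_id", "spike_time_s", "span_start", "span_stop"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spike_times_csv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        span = (float(grp["span_start"].iloc[0]), float(grp["span_stop"].iloc[0]))
        trains.append(SpikeTrain(unit_id=str(uid),
                                 spike_times=np.sort(grp["spike_time_s"].to_numpy()),
                                 recording_span=span))
    return trains


def write_calcium_csv(path, trace: CalciumTrace) -> None:
    df = pd.DataFrame({"frame_time_s": trace.frame_times, "dff": trace.dff})
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_fps={trace.frame_rate!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_calcium_csv(path) -> CalciumTrace:
    frame_rate = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            frame_rate = float(first.partition("=")[2])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    t = df["frame_time_s"].to_numpy()
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(t)))
    return CalciumTrace(frame_times=t, dff=df["dff"].to_numpy(), frame_rate=frame_rate)


def write_ttl_csv(path, ttl_events: dict) -> None:
    rows = [(stream, t, label)
            for stream in sorted(ttl_events)
            for t, label in ttl_events[stream]]
    pd.DataFrame(rows, columns=["stream", "event_time_s", "label"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_ttl_csv(path) -> dict:
    df = pd.read_csv(path)
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(row["stream"], []).append(
            (float(row["event_time_s"]), str(row["label"])))
    return out


def write_schedule_json(path, schedule: list[MechStimulus]) -> None:
    data = []
    for s in schedule:
        d = dataclasses.asdict(s)
        if not np.isfinite(d.get("nominal_pressure", float("nan"))):
            d["nominal_pressure"] = None
        data.append(d)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_schedule_json(path) -> list[MechStimulus]:
    with open(path) as fh:
        data = json.load(fh)
    for d in data:
        if d.get("nominal_pressure") is None:
            d["nominal_pressure"] = float("nan")
    return [MechStimulus(**d) for d in data]


def write_manifest_json(path, manifest) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest_json(path):
    from .synthetic import GroundTruthManifest
    with open(path) as fh:
        return GroundTruthManifest.from_dict(json.load(fh))


def write_bundle(out_dir, bundle) -> dict:
    """Write a synthetic experiment bundle to a directory tree.

    Returns a dict of the paths written.  Layout::

        curves/curve_0000.txt ...
        spikes.h5
        spike_times.csv
        calcium.csv
        ttl_events.csv
        schedule.json
        manifest.json
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    curve_dir = out / "curves"
    curve_dir.mkdir(exist_ok=True)
    for i, curve in enumerate(bundle.force_curves):
        write_force_curve(curve_dir / f"curve_{i:04d}.txt", curve)
    paths["curves"] = str(curve_dir)
    write_spikes_h5(out / "spikes.h5", bundle.spike_trains, bundle.footprints)
    paths["spikes"] = str(out / "spikes.h5")
    write_spike_times_csv(out / "spike_times.csv", bundle.spike_trains)
    paths["spike_times_csv"] = str(out / "spike_times.csv")
    if bundle.calcium is not None:
        write_calcium_csv(out / "calcium.csv", bundle.calcium)
        paths["calcium"] = str(out / "calcium.csv")
    write_ttl_csv(out / "ttl_events.csv", bundle.ttl_events)
    paths["ttl"] = str(out / "ttl_events.csv")
    write_schedule_json(out / "schedule.json", bundle.schedule)
    paths["schedule"] = str(out / "schedule.json")
    write_manifest_json(out / "manifest.json", bundle.manifest)
    paths["manifest"] = str(out / "manifest.json")
    return paths
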