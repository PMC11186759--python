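"""Seeded generator of a complete synthetic mechano-electrophysiology experiment.

Emulates the synchronized data streams of a combined AFM / high-density
microelectrode array / fluorescence experiment with known ground truth:

* Hertzian force curves — the cantilever deflection past contact solves the
  implicit cantilever-sample force balance, so synthetic curves are
  physically consistent with what the stiffness fitter assumes;
* bursty multi-unit spike trains — each unit is an inhomogeneous Poisson
  process whose rate switches between a base and an in-burst rate on a
  *shared* two-state Markov schedule (shared switching is what makes the
  bursts network-synchronous), with optional evoked spikes and
  multiplicative rate changes tied to mechanical stimuli;
* electrode-grid footprints — a stereotyped biphasic template scaled by a
  monotone distance decay, with an epoch-dependent amplitude factor during
  compression;
* spike-convolved calcium traces — linear-rise / exponential-decay kernel
  sampled at the camera frame rate;
* TTL event tables on per-stream clocks that differ from the master clock
  by a configured offset (and optional linear drift).

Every artefact's true parameters are recorded in a
:class:`GroundTruthManifest` so each analysis stage can be verified by
parameter recovery.  All randomness derives from one master seed through
fixed per-artefact child streams: adding one artefact type never perturbs
the others, and a fixed configuration reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ephys import SPIKE_TIME_RESOLUTION, BurstSet, SpikeTrain
from .mechanics import ForceCurve, MechStimulus, hertz_force_nN
from .optical import CalciumTrace
from .waveforms import UnitFootprint

__all__ = [
    "BurstModel",
    "CaKernel",
    "ClockModel",
    "StimulusEffect",
    "SegmentPlan",
    "SynthConfig",
    "GroundTruthManifest",
    "ExperimentBundle",
    "solve_deflection",
    "gen_force_curve",
    "gen_spike_population",
    "gen_footprint",
    "gen_calcium_trace",
    "gen_experiment",
]

# fixed child-stream keys: one RNG stream per artefact family
_STREAM_CURVES, _STREAM_SPIKES, _STREAM_CALCIUM, _STREAM_LAYOUT = 0, 1, 2, 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class BurstModel:
    """Two-state Markov rate switch shared by all units.

    ``rate_in`` is the IBI→burst switching rate (so 1/rate_in is the mean
    inter-burst interval), ``rate_out`` the burst→IBI rate (1/rate_out the
    mean burst duration), ``burst_rate`` the per-unit firing rate inside a
    burst.  The defaults (mean IBI 20 s, mean burst 3 s, 30 Hz in-burst)
    give the rhythmic, clearly separated network bursts of a mature
    dissociated culture; no quantitative burst statistics are prescribed by
    the assay itself, so these are documented free parameters.
    """

    rate_in: float = 0.05
    rate_out: float = 1.0 / 3.0
    burst_rate: float = 30.0

    def __post_init__(self) -> None:
        if min(self.rate_in, self.rate_out, self.burst_rate) < 0:
            raise ValueError("burst-model rates must be non-negative")


@dataclass(frozen=True)
class CaKernel:
    """Causal calcium-indicator kernel: linear rise then exponential decay.

    Defaults model a slow genetically encoded indicator under strong
    stimulation: 0.5 s rise, 26.2 s decay constant, unit-transient
    amplitude 0.3 ΔI/I.
    """

    rise: float = 0.5
    decay_tau: float = 26.2
    amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.rise <= 0 or self.decay_tau <= 0 or self.amplitude <= 0:
            raise ValueError("kernel parameters must be positive")


@dataclass(frozen=True)
class ClockModel:
    """Stream clock: t_master = drift * t_stream + offset."""

    offset: float = 0.0
    drift: float = 1.0

    def to_stream(self, t_master):
        return (np.asarray(t_master, dtype=float) - self.offset) / self.drift

    def to_master(self, t_stream):
        return self.drift * np.asarray(t_stream, dtype=float) + self.offset


@dataclass(frozen=True)
class StimulusEffect:
    """Ground-truth effect of one stimulus on the spike trains.

    ``evoked_latency_mean``/``sd`` (s) inject one evoked spike per unit at
    contact + latency; ``rate_factor_during``/``after`` multiply the firing
    rate in the during epoch / an ``after_window`` following release.  A
    ``block_background`` stimulus silences spontaneous firing for the whole
    peri-stimulus window (the pharmacological-blockade condition under which
    evoked responses are isolated).
    """

    evoked_latency_mean: Optional[float] = None
    evoked_latency_sd: float = 0.0
    rate_factor_during: float = 1.0
    rate_factor_after: float = 1.0
    after_window: float = 150.0
    block_background: bool = False

    def __post_init__(self) -> None:
        if self.rate_factor_during < 0 or self.rate_factor_after < 0:
            raise ValueError("rate factors must be non-negative")


@dataclass(frozen=True)
class SegmentPlan:
    """Durations (s) of the approach / dwell / retract segments of one curve,
    plus the true contact height along the approach."""

    approach_s: float
    dwell_s: float = 0.0
    retract_s: Optional[float] = None     # defaults to approach_s
    contact_height: Optional[float] = None  # µm; default 60 % of the approach span

    def __post_init__(self) -> None:
        if self.approach_s <= 0 or self.dwell_s < 0:
            raise ValueError("segment durations must be non-negative (approach > 0)")

    @classmethod
    def for_depth(cls, config: "SynthConfig", depth_nm: float = 900.0,
                  baseline_um: float = 1.0, dwell_s: float = 0.0) -> "SegmentPlan":
        """Plan whose deepest point reaches ``depth_nm`` of true indentation.

        The piezo overtravel past contact is the target depth plus the
        cantilever deflection the Hertz force produces there, so the curve
        ends at (approximately, up to one sample) the requested depth.
        """
        F_nN = hertz_force_nN(depth_nm, config.E_true, config.bead_radius,
                              config.poisson_ratio)
        d_nm = F_nN / config.spring_constant
        span_um = baseline_um + (depth_nm + d_nm) * 1e-3
        return cls(approach_s=span_um / config.approach_speed, dwell_s=dwell_s,
                   contact_height=baseline_um)


@dataclass(frozen=True)
class SynthConfig:
    """All generator parameters; the ground truth of a synthetic experiment.

    Defaults describe the study conditions: soft neuronal soma (1 kPa
    apparent modulus probed with a 5 µm bead on a 0.02 N/m cantilever at
    10 µm/s), a 17.5 µm electrode pitch with ~200 µV spikes, a 1.13-fold
    template amplitude factor during compression, a slow calcium indicator
    (τ = 26.2 s) imaged at 45 fps, and spontaneously active units at 2 Hz
    with shared network bursts.
    """

    seed: int = 0
    n_units: int = 10
    duration: float = 300.0            # s
    base_rate: float = 2.0             # Hz per unit
    burst_model: Optional[BurstModel] = BurstModel()
    E_true: float = 1000.0             # Pa
    bead_radius: float = 2.5           # µm
    poisson_ratio: float = 0.5
    spring_constant: float = 0.02      # N/m
    approach_speed: float = 10.0       # µm/s
    afm_sampling: float = 2000.0       # Hz
    force_noise_sd: float = 10e-12     # N
    force_drift: float = 0.0           # N/s linear baseline drift
    grid_pitch: float = 17.5           # µm
    footprint_decay_length: float = 30.0   # µm
    base_amplitude: float = 200.0      # µV trough at the soma
    during_scale: float = 1.13         # template fold-change during compression
    ca_kernel: CaKernel = CaKernel()
    ca_noise_sd: float = 0.01          # ΔI/I frame noise
    frame_rate: float = 45.0           # fps
    clock_models: dict = field(default_factory=lambda: {
        "afm": ClockModel(offset=0.5), "camera": ClockModel(offset=0.25)})
    stimulus_schedule: tuple = ()
    stimulus_effects: tuple = ()
    n_stiffness_curves: int = 10
    curve_interval: float = 0.2        # s between curve starts (5 Hz protocol)

    def __post_init__(self) -> None:
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")
        if not (0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if min(self.base_rate, self.afm_sampling, self.approach_speed) < 0:
            raise ValueError("rates and speeds must be non-negative")
        if self.spring_constant <= 0 or self.bead_radius <= 0:
            raise ValueError("spring_constant and bead_radius must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.grid_pitch <= 0 or self.footprint_decay_length <= 0:
            raise ValueError("grid geometry must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.stimulus_effects and \
                len(self.stimulus_effects) != len(self.stimulus_schedule):
            raise ValueError("stimulus_effects must match stimulus_schedule")
        for stim in self.stimulus_schedule:
            if stim.contact_off > self.duration or stim.contact_on < 0:
                raise ValueError("stimulus schedule extends past the recording")

    def effects(self) -> tuple:
        if self.stimulus_effects:
            return self.stimulus_effects
        return tuple(StimulusEffect() for _ in self.stimulus_schedule)


@dataclass
class GroundTruthManifest:
    """True generator parameters for parameter-recovery tests."""

    true_E: float
    z_contacts: list = field(default_factory=list)        # µm per curve
    curve_timestamps: list = field(default_factory=list)  # s, master clock
    curve_epoch_labels: list = field(default_factory=list)
    unit_base_rates: dict = field(default_factory=dict)
    burst_intervals: list = field(default_factory=list)
    evoked_latencies: dict = field(default_factory=dict)  # stim idx -> unit -> s
    rate_factors: dict = field(default_factory=dict)      # stim idx -> factor
    during_scale: float = 1.0
    ca_peak_times: list = field(default_factory=list)
    ca_onset_times: list = field(default_factory=list)
    clock_models: dict = field(default_factory=dict)      # stream -> (offset, drift)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        d = dict(d)
        d["evoked_latencies"] = {int(k): v for k, v in d.get("evoked_latencies", {}).items()}
        d["rate_factors"] = {int(k): v for k, v in d.get("rate_factors", {}).items()}
        return cls(**d)


@dataclass
class ExperimentBundle:
    config: SynthConfig
    force_curves: list
    spike_trains: list
    footprints: list
    calcium: Optional[CalciumTrace]
    ttl_events: dict          # stream -> list of (time_s, label), stream clock
    schedule: list
    bursts: BurstSet
    manifest: GroundTruthManifest


# ---------------------------------------------------------------------------
# force curves

def solve_deflection(separation_um, config: SynthConfig) -> np.ndarray:
    """Deflection (nm) solving the implicit cantilever-sample force balance.

    For piezo travel past contact ``s`` the deflection ``d`` satisfies
    ``k d = (4/3)(E/(1-ν²))√R (s - d)^{3/2}``.  Solved per sample by a
    vectorised Newton iteration on the indentation δ = s − d (the residual
    is monotone and convex in δ, so Newton from δ = s converges
    monotonically); non-convergence is a hard error, never silent clipping.
    Relative tolerance 1e-12.
    """
    s = np.atleast_1d(np.asarray(separation_um, dtype=float)) * 1e-6
    if np.any(s < 0):
        raise ValueError("separation must be non-negative")
    k = config.spring_constant
    c = (4.0 / 3.0) * (config.E_true / (1.0 - config.poisson_ratio**2)) \
        * math.sqrt(config.bead_radius * 1e-6)
    delta = s.copy()
    for _ in range(200):
        g = c * delta**1.5 + k * delta - k * s
        gp = 1.5 * c * np.sqrt(delta) + k
        step = g / gp
        delta = delta - step
        if np.all(np.abs(step) <= 1e-12 * np.maximum(delta, 1e-18)):
            break
    else:
        raise RuntimeError("cantilever-sample balance did not converge")
    resid = c * delta**1.5 + k * delta - k * s
    if np.any(np.abs(resid) > 1e-10 * np.maximum(k * s, 1e-18)):
        raise RuntimeError("cantilever-sample balance residual too large")
    return (s - delta) * 1e9


def gen_force_curve(config: SynthConfig, plan: SegmentPlan,
                    rng: Optional[np.random.Generator] = None,
                    timestamp: float = 0.0) -> tuple[ForceCurve, dict]:
    """One synthetic approach[-dwell]-retract curve plus its ground truth.

    The piezo moves at ``approach_speed`` monotonically within each segment;
    past the true contact height the deflection follows the implicit
    cantilever-sample balance.  The baseline has zero mean force before
    noise; Gaussian force noise of sd ``force_noise_sd`` (and an optional
    linear drift) is added last, as deflection noise through the spring
    constant.  Returns ``(curve, truth)`` with the true contact height and
    modulus in ``truth``.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_CURVES)
    fs, v = config.afm_sampling, config.approach_speed
    n_app = int(round(plan.approach_s * fs)) + 1
    if n_app < 2:
        raise ValueError("approach too short for the sampling rate")
    t_app = np.arange(n_app) / fs
    z_app = v * t_app
    span = z_app[-1]
    z0 = plan.contact_height if plan.contact_height is not None else 0.6 * span
    if not 0 < z0 < span:
        raise ValueError("contact height must lie within the approach span")

    retract_s = plan.retract_s if plan.retract_s is not None else plan.approach_s
    n_dwell = int(round(plan.dwell_s * fs))
    n_ret = int(round(retract_s * fs))
    z_dwell = np.full(n_dwell, span)
    z_ret = span - v * (np.arange(1, n_ret + 1) / fs)
    z = np.concatenate([z_app, z_dwell, z_ret])
    seg = np.array(["approach"] * n_app + ["dwell"] * n_dwell + ["retract"] * n_ret,
                   dtype=object)
    t = np.arange(z.size) / fs

    d = np.zeros(z.size)
    contact = z > z0
    if contact.any():
        d[contact] = solve_deflection(z[contact] - z0, config)

    if config.force_drift:
        d = d + (config.force_drift * t) / config.spring_constant * 1e9
    if config.force_noise_sd:
        d = d + rng.normal(0.0, config.force_noise_sd, z.size) / config.spring_constant * 1e9

    curve = ForceCurve(time=t, height=z, deflection=d, segment=seg,
                       spring_constant=config.spring_constant,
                       bead_radius=config.bead_radius, speed=v,
                       timestamp=timestamp)
    truth = {"z_contact": float(z0), "E_true": config.E_true,
             "max_depth_nm": float(((z.max() - z0) * 1e3
                                    - d[np.argmax(z)]) if contact.any() else 0.0)}
    return curve, truth


# ---------------------------------------------------------------------------
# spike trains

def _burst_schedule(config: SynthConfig, rng: np.random.Generator
                    ) -> list[tuple[float, float]]:
    bm = config.burst_model
    if bm is None or bm.rate_in == 0 or bm.burst_rate == 0:
        return []
    intervals = []
    t = 0.0
    in_burst = False
    while t < config.duration:
        rate = bm.rate_out if in_burst else bm.rate_in
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_next = min(t + dwell, config.duration)
        if in_burst:
            intervals.append((t, t_next))
        t = t_next
        in_burst = not in_burst
    return intervals


def _piecewise_rate(config: SynthConfig, bursts: Sequence[tuple[float, float]]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoints and per-piece rates combining bursts and stimulus effects."""
    cuts = {0.0, config.duration}
    for s, e in bursts:
        cuts.update((s, e))
    for stim, eff in zip(config.stimulus_schedule, config.effects()):
        cuts.update((stim.contact_on, stim.contact_off))
        if eff.rate_factor_after != 1.0:
            cuts.add(min(stim.contact_off + eff.after_window, config.duration))
        if eff.block_background:
            cuts.add(max(stim.contact_on - eff.after_window, 0.0))
            cuts.add(min(stim.contact_off + eff.after_window, config.duration))
    edges = np.array(sorted(c for c in cuts if 0.0 <= c <= config.duration))
    mids = 0.5 * (edges[:-1] + edges[1:])
    rates = np.full(mids.size, config.base_rate)
    bm = config.burst_model
    if bm is not None:
        for s, e in bursts:
            rates[(mids > s) & (mids < e)] = bm.burst_rate
    for stim, eff in zip(config.stimulus_schedule, config.effects()):
        during = (mids > stim.contact_on) & (mids < stim.contact_off)
        rates[during] = rates[during] * eff.rate_factor_during
        if eff.rate_factor_after != 1.0:
            after = (mids > stim.contact_off) & \
                    (mids < stim.contact_off + eff.after_window)
            rates[after] = rates[after] * eff.rate_factor_after
        if eff.block_background:
            blocked = (mids > stim.contact_on - eff.after_window) & \
                      (mids < stim.contact_off + eff.after_window)
            rates[blocked] = 0.0
    return edges, rates


def gen_spike_population(config: SynthConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> tuple[list[SpikeTrain], BurstSet, dict]:
    """Bursty multi-unit spike trains with stimulus effects and ground truth.

    Returns ``(trains, true_bursts, truth)`` where ``truth`` carries the
    injected evoked latencies (per stimulus × unit) and rate factors.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_SPIKES)
    bursts = _burst_schedule(config, rng)
    edges, rates = _piecewise_rate(config, bursts)

    truth = {"burst_intervals": [list(b) for b in bursts],
             "evoked_latencies": {}, "rate_factors": {}}
    for i, eff in enumerate(config.effects()):
        truth["rate_factors"][i] = eff.rate_factor_during

    trains = []
    for u in range(config.n_units):
        times = []
        for t0, t1, rate in zip(edges[:-1], edges[1:], rates):
            if rate <= 0 or t1 <= t0:
                continue
            n = rng.poisson(rate * (t1 - t0))
            if n:
                times.append(rng.uniform(t0, t1, n))
        for i, (stim, eff) in enumerate(zip(config.stimulus_schedule, config.effects())):
            if eff.evoked_latency_mean is None:
                continue
            lat = eff.evoked_latency_mean if eff.evoked_latency_sd == 0 else \
                rng.normal(eff.evoked_latency_mean, eff.evoked_latency_sd)
            lat = max(lat, SPIKE_TIME_RESOLUTION)
            truth["evoked_latencies"].setdefault(i, {})[f"unit{u:03d}"] = float(lat)
            times.append(np.array([stim.contact_on + lat]))
        t = np.concatenate(times) if times else np.empty(0)
        ticks = np.unique(np.round(t / SPIKE_TIME_RESOLUTION).astype(np.int64))
        t = ticks * SPIKE_TIME_RESOLUTION
        t = t[(t > 0) & (t < config.duration)]
        trains.append(SpikeTrain(unit_id=f"unit{u:03d}", spike_times=t,
                                 recording_span=(0.0, config.duration)))
    return trains, BurstSet(bursts), truth


# ---------------------------------------------------------------------------
# footprints

# biphasic template shape parameters (ms): Gaussian trough then smaller,
# broader Gaussian rebound; chosen so trough FWHM ≈ 0.31 ms at 20 kHz
TEMPLATE_WINDOW_MS = 4.0
TROUGH_T0_MS = 1.2
TROUGH_SIGMA_MS = 0.31 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
REBOUND_FRACTION = 0.25
REBOUND_DELAY_MS = 0.7
REBOUND_SIGMA_MS = 0.25
TEMPLATE_SAMPLING = 20000.0


def template_shape(n_samples: Optional[int] = None,
                   sampling: float = TEMPLATE_SAMPLING) -> np.ndarray:
    """Unit biphasic waveform with trough depth exactly 1 (dimensionless)."""
    if n_samples is None:
        n_samples = int(round(TEMPLATE_WINDOW_MS * 1e-3 * sampling))
    t = np.arange(n_samples) / sampling * 1e3
    w = -np.exp(-((t - TROUGH_T0_MS) ** 2) / (2 * TROUGH_SIGMA_MS**2)) \
        + REBOUND_FRACTION * np.exp(-((t - TROUGH_T0_MS - REBOUND_DELAY_MS) ** 2)
                                    / (2 * REBOUND_SIGMA_MS**2))
    return w / abs(w.min())


def gen_footprint(config: SynthConfig, unit_center: tuple[float, float],
                  epoch: str = "before", n_side: int = 7,
                  epochs: Optional[Sequence[str]] = None) -> UnitFootprint:
    """Noise-free per-electrode templates of one unit on the pitch grid.

    The template on each electrode is the stereotyped biphasic waveform
    scaled by ``base_amplitude * exp(-distance / footprint_decay_length)``
    (monotone non-increasing, exactly ``base_amplitude`` at the soma); for
    the ``during`` epoch every template is additionally multiplied by
    ``during_scale``.  ``epochs`` generates several epochs at once; the
    target electrode is the grid point nearest the unit centre.
    """
    pitch = config.grid_pitch
    cx = round(unit_center[0] / pitch) * pitch
    cy = round(unit_center[1] / pitch) * pitch
    half = n_side // 2
    offs = (np.arange(n_side) - half) * pitch
    xx, yy = np.meshgrid(offs + cx, offs + cy, indexing="ij")
    xy = np.column_stack([xx.ravel(), yy.ravel()])
    ids = np.arange(xy.shape[0])
    dist = np.hypot(xy[:, 0] - unit_center[0], xy[:, 1] - unit_center[1])
    gain = config.base_amplitude * np.exp(-dist / config.footprint_decay_length)

    shape = template_shape()
    base = gain[:, None] * shape[None, :]
    templates = {}
    for ep in (epochs if epochs is not None else [epoch]):
        scale = config.during_scale if ep == "during" else 1.0
        templates[ep] = scale * base
    target = int(ids[np.argmin(dist)])
    return UnitFootprint(unit_id="", electrode_ids=ids, electrode_xy=xy,
                         templates=templates, sampling=TEMPLATE_SAMPLING,
                         target_electrode=target)


# ---------------------------------------------------------------------------
# calcium

def gen_calcium_trace(train: SpikeTrain, config: SynthConfig,
                      rng: Optional[np.random.Generator] = None,
                      duration: Optional[float] = None
                      ) -> tuple[CalciumTrace, dict]:
    """Spike-convolved ΔI/I trace at the camera frame rate plus ground truth.

    Each spike contributes a causal kernel rising linearly to the unit
    amplitude over ``rise`` seconds and decaying as exp(−t/τ) after; frame
    noise is Gaussian.  The truth records, per spike, the kernel peak time
    (spike + rise) and the 10 %-of-peak onset time on the rising flank.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_CALCIUM)
    kern = config.ca_kernel
    duration = duration if duration is not None else train.recording_span[1]
    n = int(math.floor(duration * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    dff = np.zeros(n)
    for s in train.spike_times:
        rel = t - s
        rise = (rel > 0) & (rel <= kern.rise)
        decay = rel > kern.rise
        dff[rise] += kern.amplitude * rel[rise] / kern.rise
        dff[decay] += kern.amplitude * np.exp(-(rel[decay] - kern.rise) / kern.decay_tau)
    if config.ca_noise_sd:
        dff = dff + rng.normal(0.0, config.ca_noise_sd, n)
    truth = {"peak_times": [float(s + kern.rise) for s in train.spike_times],
             "onset_times": [float(s + 0.1 * kern.rise) for s in train.spike_times]}
    return CalciumTrace(frame_times=t, dff=dff, frame_rate=config.frame_rate), truth


# ---------------------------------------------------------------------------
# the full experiment

def gen_experiment(config: SynthConfig) -> ExperimentBundle:
    """Compose all synthetic streams into one bundle with a manifest.

    Streams are generated on the master clock and TTL event tables are
    emitted per stream on that stream's own clock (master + configured
    offset/drift): stimulus contact on/off for the AFM and camera streams,
    plus two session sync pulses so alignment is possible even with an
    empty schedule.
    """
    layout_rng = _rng(config.seed, _STREAM_LAYOUT)
    trains, bursts, spike_truth = gen_spike_population(config)

    manifest = GroundTruthManifest(
        true_E=config.E_true,
        unit_base_rates={tr.unit_id: config.base_rate for tr in trains},
        burst_intervals=spike_truth["burst_intervals"],
        evoked_latencies=spike_truth["evoked_latencies"],
        rate_factors=spike_truth["rate_factors"],
        during_scale=config.during_scale,
        clock_models={name: [cm.offset, cm.drift]
                      for name, cm in config.clock_models.items()},
    )

    # stiffness curves at the 5 Hz protocol rate, timestamped on the master clock
    curve_rng = _rng(config.seed, _STREAM_CURVES)
    plan = SegmentPlan.for_depth(config, depth_nm=900.0, baseline_um=1.0)
    curves = []
    t_start = 10.0
    for i in range(config.n_stiffness_curves):
        ts = t_start + i * config.curve_interval
        curve, truth = gen_force_curve(config, plan, rng=curve_rng, timestamp=ts)
        curves.append(curve)
        manifest.z_contacts.append(truth["z_contact"])
        manifest.curve_timestamps.append(ts)
        manifest.curve_epoch_labels.append(
            "burst" if any(s <= ts <= e for s, e in bursts.bursts) else "ibi")

    # footprints on grid positions spread around the array centre
    footprints = []
    for tr in trains:
        pos = tuple(config.grid_pitch * layout_rng.integers(-20, 21, 2).astype(float))
        fp = gen_footprint(config, pos, epochs=["before", "during", "after"])
        fp.unit_id = tr.unit_id
        footprints.append(fp)

    calcium, ca_truth = (None, {"peak_times": [], "onset_times": []})
    if trains:
        calcium, ca_truth = gen_calcium_trace(trains[0], config)
    manifest.ca_peak_times = ca_truth["peak_times"]
    manifest.ca_onset_times = ca_truth["onset_times"]

    master_events = [(1.0, "sync_start"), (config.duration - 1.0, "sync_end")]
    for i, stim in enumerate(config.stimulus_schedule):
        master_events.append((stim.contact_on, f"stim{i}_on"))
        master_events.append((stim.contact_off, f"stim{i}_off"))
    master_events.sort()
    ttl = {"master": master_events}
    for name, cm in config.clock_models.items():
        ttl[name] = [(float(cm.to_stream(t)), label) for t, label in master_events]

    return ExperimentBundle(config=config, force_curves=curves,
                            spike_trains=trains, footprints=footprints,
                            calcium=calcium, ttl_events=ttl,
                            schedule=list(config.stimulus_schedule),
                            bursts=bursts, manifest=manifest)
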