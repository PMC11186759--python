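# Methods

`mechanoephys` analyses experiments in which an AFM probe mechanically
characterises or stimulates a neuron while a high-density microelectrode
array (HD-MEA) records its extracellular activity and a fluorescence camera
records a calcium indicator. This note describes the models implemented,
the choices made where the procedure was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Clocks and units

The HD-MEA acquisition (20 kHz) is the master clock. Every other stream
(AFM, camera) relates to it linearly, `t_master = drift · t_stream +
offset`, and the map is estimated by least squares over TTL event pairs
(`sync.build_sync_map`), paired greedily in order within a tolerance.
Noiseless events recover offset and drift to numerical precision; jittered
events degrade the residual monotonically. Units are practical lab units
throughout: s, µm, nm, nN, Pa, µV, ΔI/I.

## Hertzian stiffness estimation

A rigid sphere (radius `R`, default 2.5 µm — a 5 µm bead) indenting an
elastic, incompressible half-space obeys

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2}

with indentation depth `δ`, apparent Young's modulus `E` and Poisson ratio
`ν = 0.5` by default (the standard incompressible-cell assumption; the
value is recorded in every fit result). The processing chain per curve is:

1. **Baseline**: mean and sd of the force over the first 30 % of the
   approach segment (configurable; an optional linear detrend makes the sd
   drift-robust). At least 20 samples are required.
2. **Contact point**: the first approach sample whose baseline-subtracted
   force exceeds 5× the baseline sd *and stays above it to the end of the
   approach* (the persistence rule is the deterministic stand-in for manual
   curation; a crossing in the last 5 % of the approach raises a review
   flag instead of being silently trusted). The contact height is the
   x-intercept of the line through that sample and the interpolated
   threshold crossing.
3. **Indentation**: `δ = (z − z₀) − (d − d₀)`, with the deflection
   reference `d₀` taken from the baseline side of the contact point (the
   deflection kinks at contact, so interpolating across the kink would
   bias the reference by up to half a sample).
4. **Depth cutoff**: samples with `δ > 750 nm` are discarded (inclusive
   boundary), bounding the strain range over which the half-space model is
   trusted; the number of discarded samples is reported.
5. **Fit**: linear least squares of `F` against `δ^{3/2}` through the
   origin — convex, initialisation-free, and exactly scale-equivariant —
   on the approach segment only. Fewer than 10 samples makes the fit
   unusable rather than an error.

**Contact-offset refinement.** A fixed force threshold registers contact
late on soft samples: for a 3/2-power force law the 5×SD crossing occurs at
`δ* = (5σ/c)^{2/3}` (tens to hundreds of nm at 0.1–1 kPa and σ = 10 pN),
and a straight-line back-extrapolation of a power-law curve recovers only
about two-thirds of that, which propagates into a multiplicative bias of
roughly `1 + 2Δ/δ_max` on `E` (6–30 % in the soft regime). The high-level
path (`estimate_stiffness`, `refine_contact=True`) therefore profiles a
contact shift `δ₀` out of the fit: for each candidate shift the amplitude
has a closed form, and a coarse-grid-plus-bounded-1-D search minimises the
residual sum of squares over `δ₀ ∈ [−750, +375] nm` (deterministic,
`xatol` 10⁻⁴ nm). On noiseless data the refinement is exact; under 10 pN
noise it brings the median recovery error to ≲ 2 % at 0.1 kPa and ≲ 0.2 %
at 1 kPa. The plain through-origin fit remains available
(`refine_contact=False`) and is what step 5 describes.

A measurement cycle aggregates five curves (mean ± sample sd); fewer than
three usable fits is an error, matching the convention that one reported
stiffness dot represents at least three estimates.

**Pressure.** The nominal pressure of a setpoint force is `F/A`. Two area
models are exposed and always recorded: the bead cross-section `πR²`
(default; 200 nN on a 2.5 µm bead ≈ 10.2 kPa) and a user-supplied
effective contact area (40 µm² reproduces the ≈5 kPa pairing quoted for
200 nN). The effective area a given experiment assumed is not derivable
from first principles here, so neither model is silently preferred.

## Spike-train analysis

Rates are counts over half-open windows divided by window length. Binned
rates tile the recording span with left-closed/right-open bins (default
30 s; an edge spike belongs to the bin on its right), so bin counts always
sum to the train length. Epoch analysis uses before / during / after
windows around a stimulus (default 2.5 min / contact interval / 2.5 min)
and reports the percent change `100·(r_new − r_ref)/r_ref` (undefined, and
an error, at zero reference rate). ISIs are consecutive differences.

**Quality filtering** mirrors spike-sorting curation: ISI-violation ratio
(fraction of ISIs below a 2 ms refractory period; the refractory window is
our choice, the 0.5 ratio threshold is the protocol's) and SNR (largest
template trough magnitude over electrode noise sd, threshold 5.0).

**Network bursts** are detected on the per-unit-normalised population rate
in 25 ms bins, boxcar-smoothed over 3 bins. The threshold is 3× a baseline
reference rate, taken as the 25th percentile of the nonzero raw bin rates:
a lower-quartile reference estimates the out-of-burst rate robustly even
when bursts occupy a large fraction of the recording, where a nonzero-bin
median drifts up toward the in-burst rate and fragments detection.
Supra-threshold runs are merged across gaps < 100 ms and runs shorter than
50 ms are dropped. All five knobs are exposed. Burst/IBI labels for
force-curve timestamps use closed intervals (a timestamp exactly on a
burst edge is a burst).

**Evoked latency** is the time from contact to the first spike strictly
after it within a 500 ms search window (the scale of a transient
stimulus); stimuli that evoke nothing are reported missing, never imputed.
The estimator is contaminated by whatever spontaneous spikes precede the
evoked one, which is why latency experiments are run under synaptic
blockade; the generator models that blockade explicitly (see below).

## Waveform features

Features are extracted from mean templates (µV, 20 kHz): baseline = mean
of the first 10 % of samples; **amplitude** = baseline-to-trough magnitude
(the field's convention for negative extracellular spikes; peak-to-peak is
an option); **halfwidth** = full width of the trough at half depth with
linear interpolation, taking the first crossing on each side walking
outward from the trough; **repolarization slope** = least-squares slope
from the trough to the first baseline re-crossing (steepest post-trough
derivative available behind a flag). Epoch comparisons divide the during
feature by the before feature per electrode; the distance table uses
Euclidean distances from the target electrode (the one under the
compression site) on the 17.5 µm pitch grid. Amplitude ratios are linear
in a pure template scaling while halfwidth ratios are invariant to it,
which is what makes the pair diagnostic.

## Calcium analysis

ΔI/I = (I − I₀)/I₀ with I₀ the pre-stimulus mean by default (an 8th-
percentile option serves recordings with activity throughout). **Peaks**
are frames that strictly exceed every other frame within ±1.5 s (a 3 s
local-maximum window, centred; edge frames are never peaks); the
implementation is verified against an exhaustive scan. **Onset** is the
latest pre-peak crossing of 10 % of the peak amplitude that is sustained
to the peak, linearly interpolated — robust to baseline noise where the
first-ever crossing is not. Responses are aligned on a −2.5 s/+10 s window
re-zeroed at onset. **Decay** is a single-exponential
`A·exp(−(t−t_peak)/τ)` least-squares fit (initialised from the log-linear
slope) on the post-peak segment down to 10 % of the peak; a non-decaying
tail yields a missing τ with a warning. **Responder classification**: a
unit responded iff a detected peak within 10 s of contact exceeds 5× the
pre-stimulus ΔI/I sd; both knobs are configurable and recorded.

**Soma morphometry.** Outlines are simple polygons. Both are translated
to their centroids and the diameter along each of 180 uniformly sampled
directions in [0, π) is the width of the vertex projection; the reported
change is the maximum over directions of (during − before). This is the
dense-sampling limit of picking the diagonal with the largest change, is
vertex-count independent, and is invariant to rigid motion up to the
angular sampling step.

## Statistics

Paired comparisons use the Wilcoxon signed-rank test, independent AFM
groups the two-tailed Mann-Whitney U, stiffness-rate association Pearson's
r (t-distribution p, n−2 df), and responder proportions a Pearson χ² on
the 2×k table (df = k−1, no continuity correction). The signed-rank and U
tests compute exact two-sided p values at small n (n ≤ 25 pairs after
dropping zero differences; m+n ≤ 12) via the rank-sum generating
polynomial over doubled midranks / enumeration of group assignments —
identical to brute-force enumeration, ties included — and use the normal
approximation with tie correction above. Zero differences are dropped and
reported. p > 0.05 is read as non-significant and no multiple-testing
correction is applied, matching the analysis conventions the pipeline
reproduces; the report states this.

## The synthetic-data generator

The generator emulates the full synchronized experiment with known ground
truth, written to a manifest so every stage is verified by parameter
recovery rather than against unavailable laboratory data.

* **Force curves**: the piezo moves at constant speed; past the true
  contact height the deflection solves the implicit cantilever-sample
  balance `k·d = (4/3)(E/(1−ν²))√R(s−d)^{3/2}` by a vectorised Newton
  iteration on `δ = s − d` (monotone convex residual, convergence to
  1e−12 relative, non-convergence is a hard error). Solving the balance —
  rather than evaluating the closed form on a depth grid — makes the
  synthetic curves physically consistent with what the fitter assumes.
  Gaussian force noise (default 10 pN, a good cantilever in liquid) and
  optional linear drift are added last, as deflection through `k`.
  Defaults: E = 1 kPa (soma-like), k = 0.02 N/m, 10 µm/s, 2 kHz sampling.
* **Spike trains**: each unit is an inhomogeneous Poisson process whose
  rate switches between a base rate (2 Hz) and an in-burst rate (30 Hz)
  on a *shared* two-state Markov schedule — the simplest process that
  yields network-synchronous bursts with tunable statistics (mean IBI
  20 s, mean burst 3 s; no quantitative burst statistics are prescribed
  by the assay, so these are documented free parameters). Stimuli can
  inject an evoked spike at contact + latency (fixed or normal),
  multiply the rate during/after the stimulus, or silence the background
  in a peri-stimulus window (`block_background`) — the
  glutamate-receptor-antagonist condition under which evoked latencies
  are measured. Spike times are quantised to the 1/20000 s acquisition
  grid and deduplicated.
* **Footprints**: a stereotyped biphasic template (Gaussian trough of
  0.31 ms FWHM plus a smaller, broader rebound, normalised to unit trough)
  scaled by `base_amplitude · exp(−distance/λ)` (λ = 30 µm) on a local
  7×7 patch of the 17.5 µm grid; during-epoch templates are multiplied by
  `during_scale` (default 1.13). Trough depth and FWHM are analytically
  known, so feature extraction is testable to interpolation error.
* **Calcium**: ΔI/I is the spike-convolved causal kernel (linear rise of
  0.5 s to amplitude 0.3, exponential decay τ = 26.2 s — a slow indicator
  under strong stimulation) sampled at 45 fps plus Gaussian frame noise.
  The manifest records each transient's peak time and 10 %-onset time.
* **Clocks/TTL**: all streams are generated on the master clock; TTL
  tables carry stimulus contacts (plus two session sync pulses) on each
  stream's own clock (`master = drift·stream + offset`).

One RNG stream per artefact family, all spawned from the master seed with
fixed keys, so adding an artefact type never perturbs the others; a fixed
config reproduces byte-identical bundles (HDF5 object timestamps are
disabled for this reason).

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: raw 20 kHz voltage with spike
collisions and sorting errors (templates and times are taken as given);
viscoelastic or adhesive contact mechanics (pure Hertz, so the fitter is
tested under its own model assumptions); cell-to-cell modulus
heterogeneity within a curve set; photobleaching, motion and segmentation
error in the fluorescence stream; non-linear clock wander beyond linear
drift. Real-data performance on those axes must be established separately.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen to keep
statistical margins comfortable: 100 curves per stiffness condition,
10–20 units over 300–1020 s of spiking, 500 spikes per waveform epoch,
100 calcium replicates, 100-cell responder cohorts. The full simulated
pipeline run uses a 400 s recording with one 60 s static compression and
completes in seconds.

## Known limitations

* The contact-offset refinement assumes the Hertz exponent is correct; on
  strongly non-Hertzian curves it will absorb model error into the offset.
* The burst detector is a population-rate threshold; it is not designed
  for single-unit burstiness or for populations with strongly
  heterogeneous rates.
* The latency estimator is first-spike-in-window; without background
  suppression its mean is biased low by spontaneous contamination
  (quantified in the module documentation) and should then be treated as
  a lower bound.
* Exact statistics switch to normal approximations above the enumeration
  thresholds; at moderate n with heavy ties the approximation is the
  usual midrank-corrected one, not exact.
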