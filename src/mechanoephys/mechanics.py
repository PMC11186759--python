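"""AFM force-curve processing: baseline statistics, contact-point detection,
indentation, depth-cutoff filtering, Hertz spherical fitting and
measurement-cycle aggregation.

Conventions
-----------
Arrays use practical AFM units throughout: time in s, piezo height in µm
(increasing toward the sample, so contact happens at some height ``z0`` and
samples with ``height > z0`` are in contact), cantilever deflection in nm,
force in nN (``force = spring_constant [N/m] * deflection [nm]``, which is
numerically nN), Young's modulus in Pa.

The contact model is Hertzian contact of a rigid sphere (radius ``R``) on an
elastic half-space::

    F = (4/3) * (E / (1 - nu**2)) * sqrt(R) * delta**1.5

with indentation depth ``delta`` and Poisson ratio ``nu`` (default 0.5,
the incompressible-cell limit customary in cell mechanics).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ForceCurve",
    "ContactPoint",
    "HertzFitResult",
    "StiffnessMeasurement",
    "MechStimulus",
    "PressureResult",
    "hertz_force_nN",
    "estimate_baseline",
    "detect_contact_point",
    "compute_indentation",
    "apply_depth_cutoff",
    "fit_hertz_sphere",
    "cycle_stiffness",
    "classify_curve_epoch",
    "nominal_pressure",
    "estimate_stiffness",
]

SEGMENT_ORDER = ("approach", "dwell", "retract")


class ContactNotFoundError(ValueError):
    """Raised when no sustained crossing of the contact threshold exists."""


@dataclass
class ForceCurve:
    """One AFM approach[-dwell]-retract cycle with probe metadata.

    Parameters
    ----------
    time : array, s
    height : array, µm — piezo extension toward the sample.
    deflection : array, nm
    segment : array of {'approach', 'dwell', 'retract'} labels, contiguous
        and in that order.
    spring_constant : N/m
    bead_radius : µm
    speed : µm/s
    timestamp : s — curve start on the AFM clock.
    """

    time: np.ndarray
    height: np.ndarray
    deflection: np.ndarray
    segment: np.ndarray
    spring_constant: float
    bead_radius: float
    speed: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        n = self.time.size
        if not (self.height.size == self.deflection.size == self.segment.size == n):
            raise ValueError("time, height, deflection and segment must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        labels = [s for s, _ in _runs(self.segment)]
        if any(lab not in SEGMENT_ORDER for lab in labels):
            raise ValueError(f"unknown segment label in {labels}")
        order = [SEGMENT_ORDER.index(lab) for lab in labels]
        if order != sorted(order) or len(set(labels)) != len(labels):
            raise ValueError("segments must be contiguous in approach[, dwell][, retract] order")

    @property
    def force(self) -> np.ndarray:
        """Force in nN (spring constant [N/m] × deflection [nm])."""
        return self.spring_constant * self.deflection

    def segment_mask(self, label: str) -> np.ndarray:
        return self.segment == label


def _runs(labels: np.ndarray):
    """Yield (label, slice) for maximal runs of equal labels."""
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            yield labels[start], slice(start, i)
            start = i


@dataclass(frozen=True)
class ContactPoint:
    z_contact: float          # µm
    needs_review: bool        # crossing in the last 5 % of the approach
    baseline_mean: float      # nN
    baseline_sd: float        # nN
    crossing_index: int       # index (within approach) of the persistent crossing


@dataclass
class HertzFitResult:
    E_apparent: float            # Pa
    z_contact: float             # µm
    baseline_mean: float         # nN
    baseline_sd: float           # nN
    n_points_fit: int
    max_indentation_used: float  # nm
    residual_rms: float          # nN
    usable: bool
    nu: float = 0.5
    bead_radius: float = float("nan")   # µm
    contact_offset_nm: float = 0.0      # refinement shift applied to indentation
    needs_review: bool = False


@dataclass
class StiffnessMeasurement:
    neuron_id: str
    cycle_time: float   # s
    E_mean: float       # Pa
    E_sd: float         # Pa
    n_curves: int


@dataclass(frozen=True)
class MechStimulus:
    """One mechanical stimulation event.

    ``kind`` is one of ``transient`` (bead retracted immediately on reaching
    the setpoint), ``static`` (setpoint held, typically 60 s) or
    ``staircase`` (setpoint stepped, e.g. 50→400 nN in 50 nN increments).
    """

    kind: str
    setpoint_force: float          # nN
    approach_speed: float          # µm/s
    contact_on: float              # s, master clock
    contact_off: float             # s, master clock
    nominal_pressure: float = float("nan")   # kPa
    staircase: Optional[dict] = None         # {start, stop, step (nN), interval (s)}

    def __post_init__(self) -> None:
        if self.kind not in ("transient", "static", "staircase"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not self.contact_on < self.contact_off:
            raise ValueError("contact_on must precede contact_off")
        if (self.staircase is not None) != (self.kind == "staircase"):
            raise ValueError("staircase parameters require kind='staircase'")


@dataclass(frozen=True)
class PressureResult:
    pressure_kPa: float
    area_um2: float
    area_model: str   # 'bead_cross_section' or 'effective_area'


def hertz_force_nN(delta_nm, E_Pa: float, R_um: float, nu: float = 0.5):
    """Closed-form Hertz force (nN) of a sphere at indentation ``delta_nm``.

    Direct evaluation of F = (4/3)(E/(1-ν²))√R δ^{3/2}; this is the forward
    model the fitter inverts and the independent oracle used in tests.
    """
    if R_um <= 0:
        raise ValueError("bead radius must be positive")
    if not nu * nu < 1:
        raise ValueError("Poisson ratio must satisfy nu**2 < 1")
    delta_m = np.asarray(delta_nm, dtype=float) * 1e-9
    F = (4.0 / 3.0) * (E_Pa / (1.0 - nu**2)) * math.sqrt(R_um * 1e-6) * np.maximum(delta_m, 0.0) ** 1.5
    return F * 1e9


def estimate_baseline(curve: ForceCurve, baseline_fraction: float = 0.3,
                      detrend: bool = False) -> tuple[float, float]:
    """Mean and sd (nN) of the force over the leading part of the approach.

    The window is the first ``baseline_fraction`` of the approach segment and
    must contain at least 20 samples.  With ``detrend=True`` a straight line
    is removed before the sd is computed (drift-robust noise estimate); the
    mean reported is always the raw mean.
    """
    if not 0 < baseline_fraction <= 1:
        raise ValueError("baseline_fraction must be in (0, 1]")
    mask = curve.segment_mask("approach")
    force = curve.force[mask]
    n = int(round(force.size * baseline_fraction))
    if n < 20:
        raise ValueError("insufficient baseline: fewer than 20 approach samples in window")
    window = force[:n]
    mean = float(np.mean(window))
    if detrend:
        t = curve.time[mask][:n]
        resid = window - np.polyval(np.polyfit(t, window, 1), t)
        sd = float(np.std(resid, ddof=1))
    else:
        sd = float(np.std(window, ddof=1))
    return mean, sd


def detect_contact_point(curve: ForceCurve, threshold_multiple: float = 5.0,
                         baseline_fraction: float = 0.3,
                         detrend: bool = False) -> ContactPoint:
    """Contact point from the 5×baseline-SD crossing of the approach force.

    The first approach sample whose baseline-subtracted force exceeds
    ``threshold_multiple × baseline_sd`` *and stays above it to the end of
    the approach* anchors the crossing; the piezo height at zero force is
    found by linear back-extrapolation of the line through that sample and
    the interpolated threshold crossing.  A curve whose crossing falls in
    the last 5 % of the approach is flagged for review (the stand-in for
    manual curation).
    """
    mean, sd = estimate_baseline(curve, baseline_fraction, detrend=detrend)
    mask = curve.segment_mask("approach")
    z = curve.height[mask]
    f = curve.force[mask] - mean
    thr = threshold_multiple * sd

    above = f > thr
    if not above.any():
        raise ContactNotFoundError("no contact detected")
    below_idx = np.nonzero(~above)[0]
    if below_idx.size == 0:
        raise ContactNotFoundError("no contact detected: curve never below threshold "
                                   "(approach entirely in contact)")
    i0 = below_idx[-1] + 1
    if i0 >= f.size:
        raise ContactNotFoundError("no contact detected: no sustained crossing")

    # interpolated threshold crossing between samples i0-1 and i0
    f_lo, f_hi = f[i0 - 1], f[i0]
    if f_hi > f_lo:
        frac = (thr - f_lo) / (f_hi - f_lo)
    else:
        frac = 1.0
    z_cross = z[i0 - 1] + frac * (z[i0] - z[i0 - 1])

    # back-extrapolate the (crossing, first-persistent-sample) line to F = 0
    if f[i0] > thr and z[i0] > z_cross:
        slope = (f[i0] - thr) / (z[i0] - z_cross)
        z0 = z_cross - thr / slope if slope > 0 else z_cross
    else:
        z0 = z_cross

    needs_review = i0 >= 0.95 * f.size
    return ContactPoint(z_contact=float(z0), needs_review=bool(needs_review),
                        baseline_mean=mean, baseline_sd=sd, crossing_index=int(i0))


def compute_indentation(curve: ForceCurve, z_contact: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Indentation depth (nm) and force (nN) of the in-contact approach samples.

    δ = (z − z_contact)·1000 − (d − d_contact), with the deflection at contact
    interpolated on the approach; the sample of maximal force is the deepest
    indentation (the zeroing convention of the protocol).  Only approach
    samples with z ≥ z_contact are returned, with small negative δ clipped
    to zero.
    """
    mask = curve.segment_mask("approach")
    z = curve.height[mask]
    d = curve.deflection[mask]
    if not (z.min() <= z_contact <= z.max()):
        raise ValueError("z_contact lies outside the approach height range")
    # deflection reference taken from the baseline side of the contact point:
    # the deflection kinks at contact, so interpolating across it would bias
    # the reference by up to half a sample of contact deflection
    idx = int(np.searchsorted(z, z_contact, side="left")) - 1
    d0 = float(d[max(idx, 0)])
    contact = z >= z_contact
    delta = (z[contact] - z_contact) * 1000.0 - (d[contact] - d0)
    force = curve.force[mask][contact]
    return np.maximum(delta, 0.0), force


def apply_depth_cutoff(force: np.ndarray, indentation: np.ndarray,
                       cutoff: float = 750.0
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Discard samples whose indentation exceeds the depth cutoff (nm).

    Returns (force, indentation, n_discarded); samples with δ ≤ cutoff are
    kept (inclusive).
    """
    force = np.asarray(force, dtype=float)
    indentation = np.asarray(indentation, dtype=float)
    if force.shape != indentation.shape:
        raise ValueError("force and indentation must be aligned")
    keep = indentation <= cutoff
    return force[keep], indentation[keep], int((~keep).sum())


def _hertz_slope_SI(E_Pa: float, R_um: float, nu: float) -> float:
    return (4.0 / 3.0) * (E_Pa / (1.0 - nu**2)) * math.sqrt(R_um * 1e-6)


def _slope_to_E(slope_SI: float, R_um: float, nu: float) -> float:
    return slope_SI * (1.0 - nu**2) / ((4.0 / 3.0) * math.sqrt(R_um * 1e-6))


def fit_hertz_sphere(force: np.ndarray, indentation: np.ndarray, R: float,
                     nu: float = 0.5, min_points: int = 10,
                     refine_contact: bool = False,
                     max_shift_nm: float = 750.0) -> HertzFitResult:
    """Least-squares Hertz fit of force (nN) against indentation (nm).

    With ``refine_contact=False`` the fit is linear in δ^{3/2} through the
    origin (amplitude-only, convex, sign-safe).  With ``refine_contact=True``
    an additional contact shift ``δ0`` is profiled out over
    ``[-max_shift_nm, +max_shift_nm/2]``: for each candidate shift the
    amplitude has a closed form, and the shift minimising the residual sum of
    squares is kept.  Threshold-based contact detection necessarily registers
    contact late on soft samples (the force stays inside the noise band for
    tens to hundreds of nm of indentation), and the refinement recovers that
    offset from the curvature of the force-indentation data itself — the
    deterministic counterpart of manually curating the contact point.

    Fewer than ``min_points`` samples, or data incompatible with a positive
    modulus, yield ``usable=False`` rather than an exception.
    """
    force = np.asarray(force, dtype=float)
    indentation = np.asarray(indentation, dtype=float)
    if R <= 0:
        raise ValueError("bead radius must be positive")
    if not nu * nu < 1:
        raise ValueError("Poisson ratio must satisfy nu**2 < 1")
    n = force.size
    empty = HertzFitResult(E_apparent=float("nan"), z_contact=float("nan"),
                           baseline_mean=0.0, baseline_sd=0.0, n_points_fit=n,
                           max_indentation_used=float(indentation.max()) if n else 0.0,
                           residual_rms=float("nan"), usable=False, nu=nu, bead_radius=R)
    if n < min_points:
        return empty

    F_SI = force * 1e-9
    d_SI = indentation * 1e-9

    def rss_at(shift_nm: float):
        x = np.maximum(d_SI - shift_nm * 1e-9, 0.0) ** 1.5
        sxx = float(x @ x)
        if sxx <= 0:
            return np.inf, 0.0
        slope = float(x @ F_SI) / sxx
        if slope <= 0:
            return np.inf, slope
        resid = F_SI - slope * x
        return float(resid @ resid), slope

    if refine_contact:
        lo, hi = -max_shift_nm, min(max_shift_nm / 2.0, 0.9 * float(indentation.max()))
        grid = np.linspace(lo, hi, 97)
        rss_grid = np.array([rss_at(s)[0] for s in grid])
        k = int(np.argmin(rss_grid))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, grid.size - 1)]
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda s: rss_at(s)[0], bounds=(a, b),
                              method="bounded", options={"xatol": 1e-4})
        shift = float(res.x) if np.isfinite(res.fun) else float(grid[k])
        if not np.isfinite(rss_at(shift)[0]):
            shift = 0.0
    else:
        shift = 0.0

    rss, slope = rss_at(shift)
    if not np.isfinite(rss):
        return empty
    E = _slope_to_E(slope, R, nu)
    x = np.maximum(d_SI - shift * 1e-9, 0.0) ** 1.5
    resid_nN = (F_SI - slope * x) * 1e9
    return HertzFitResult(
        E_apparent=float(E), z_contact=float("nan"), baseline_mean=0.0,
        baseline_sd=0.0, n_points_fit=n,
        max_indentation_used=float(indentation.max()),
        residual_rms=float(np.sqrt(np.mean(resid_nN**2))), usable=True,
        nu=nu, bead_radius=R, contact_offset_nm=shift)


def estimate_stiffness(curve: ForceCurve, cutoff_nm: float = 750.0,
                       threshold_multiple: float = 5.0, nu: float = 0.5,
                       baseline_fraction: float = 0.3,
                       refine_contact: bool = True,
                       detrend_baseline: bool = False) -> HertzFitResult:
    """Full single-curve pipeline: baseline → contact → indentation → cutoff → fit.

    Convenience wrapper chaining the module's operations with the protocol
    defaults (750 nm depth cutoff, 5×SD contact rule, ν = 0.5, contact
    refinement on).  Force is baseline-subtracted before fitting.
    """
    cp = detect_contact_point(curve, threshold_multiple, baseline_fraction,
                              detrend=detrend_baseline)
    delta, force = compute_indentation(curve, cp.z_contact)
    force = force - cp.baseline_mean
    force, delta, _ = apply_depth_cutoff(force, delta, cutoff_nm)
    fit = fit_hertz_sphere(force, delta, R=curve.bead_radius, nu=nu,
                           refine_contact=refine_contact)
    fit.z_contact = cp.z_contact
    fit.baseline_mean = cp.baseline_mean
    fit.baseline_sd = cp.baseline_sd
    fit.needs_review = cp.needs_review
    return fit


def cycle_stiffness(fits: Sequence[HertzFitResult], min_curves: int = 3,
                    neuron_id: str = "", cycle_time: float = 0.0
                    ) -> StiffnessMeasurement:
    """Aggregate one measurement cycle (nominally five curves) into mean ± sd.

    Only usable fits count; fewer than ``min_curves`` of them is an error —
    a cycle dot represents at least three stiffness estimates.
    """
    E = np.array([f.E_apparent for f in fits if f.usable], dtype=float)
    if E.size < min_curves:
        raise ValueError(f"insufficient curves: {E.size} usable < {min_curves}")
    sd = float(np.std(E, ddof=1)) if E.size > 1 else 0.0
    return StiffnessMeasurement(neuron_id=neuron_id, cycle_time=cycle_time,
                                E_mean=float(np.mean(E)), E_sd=sd, n_curves=int(E.size))


def classify_curve_epoch(curve_timestamp: float, bursts) -> str:
    """Label a curve timestamp 'burst' or 'ibi' against closed burst intervals."""
    intervals = getattr(bursts, "bursts", bursts)
    for start, end in intervals:
        if start <= curve_timestamp <= end:
            return "burst"
    return "ibi"


def nominal_pressure(setpoint_force: float, R: Optional[float] = None,
                     effective_area: Optional[float] = None) -> PressureResult:
    """Nominal pressure (kPa) of a setpoint force (nN) on a contact area.

    The default area model is the bead cross-section πR² (R in µm); an
    ``effective_area`` in µm² overrides it.  1 nN/µm² = 1 kPa, so the result
    is simply F/A in those units.  The area model used is recorded in the
    result — the two models differ by about a factor two for a 2.5 µm bead
    at 200 nN, and which one a given experiment assumed must stay auditable.
    """
    if setpoint_force < 0:
        raise ValueError("force must be non-negative")
    if effective_area is not None:
        if effective_area <= 0:
            raise ValueError("effective area must be positive")
        return PressureResult(setpoint_force / effective_area, effective_area, "effective_area")
    if R is None or R <= 0:
        raise ValueError("bead radius must be positive when no effective area is given")
    area = math.pi * R * R
    return PressureResult(setpoint_force / area, area, "bead_cross_section")
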