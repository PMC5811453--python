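"""AFM force-curve analysis: rupture detection, Hertz fits, series assembly.

One acquisition cycle indents the cell (approach) and pulls away (retract).
The approach segment yields cell stiffness by fitting a spherical-indenter
Hertz contact model; the retract segment yields adhesion as discrete rupture
events — each receptor-ligand unbinding is a sudden positive jump in
cantilever deflection whose height times the spring constant is the rupture
force.  Repeating the cycle at a fixed rate turns per-curve metrics into the
adhesion-force and E-modulus time series the SSA pipeline consumes.

Units: z and deflection in nm, spring constant in pN/nm, force in pN,
E-modulus in kPa (1 kPa = 1e-3 pN/nm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitError, ParameterError, SegmentError
from .io import Quantity, TimeSeries

__all__ = [
    "ForceCurve",
    "RuptureEvent",
    "HertzFitResult",
    "AdhesionMetrics",
    "detect_ruptures",
    "adhesion_metrics",
    "fit_hertz",
    "curves_to_timeseries",
    "sampling_cycle_frequency",
    "expected_curve_count",
    "hertz_force",
]

KPA_TO_PN_PER_NM2 = 1e-3

#: Default probe geometry: 5 um glass microbead.
DEFAULT_PROBE_RADIUS = 2500.0  # nm
#: Incompressible-cell Poisson ratio.
DEFAULT_POISSON_RATIO = 0.5
#: Rupture jump threshold, in multiples of the robust local noise scale.
DEFAULT_RUPTURE_THRESHOLD = 5.0
#: Baseline window (samples) over which the local noise scale is estimated.
BASELINE_WINDOW = 20


@dataclass(frozen=True)
class ForceCurve:
    """One segment (approach or retract) of a force curve."""

    z: np.ndarray  # piezo displacement, nm, monotone within the segment
    deflection: np.ndarray  # cantilever deflection, nm
    segment: str  # "approach" | "retract"
    spring_constant: float  # pN/nm
    timestamp: float = 0.0  # s

    def __post_init__(self) -> None:
        z = np.asarray(self.z, float)
        d = np.asarray(self.deflection, float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "deflection", d)
        if self.segment not in ("approach", "retract"):
            raise ParameterError(f"unknown segment {self.segment!r}")
        if len(z) != len(d):
            raise ParameterError("z and deflection lengths differ")
        if self.spring_constant <= 0:
            raise ParameterError("spring constant must be positive")
        dz = np.diff(z)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ParameterError("z must be monotone within a segment")

    @property
    def force(self) -> np.ndarray:
        """Cantilever force in pN (spring constant times deflection)."""
        return self.spring_constant * self.deflection


@dataclass(frozen=True)
class RuptureEvent:
    """A single unbinding event in a retract curve."""

    force: float  # pN
    z_position: float  # nm
    height: float  # deflection jump, nm

    def __post_init__(self) -> None:
        if self.force <= 0:
            raise ParameterError("rupture force must be positive")


@dataclass(frozen=True)
class HertzFitResult:
    """Spherical-indenter Hertz fit of an approach curve."""

    e_modulus: float  # kPa
    contact_point: float  # nm
    indentation_depth: float  # nm, max indentation on the fitted region
    probe_radius: float  # nm
    poisson_ratio: float
    residual_rms: float  # pN


@dataclass(frozen=True)
class AdhesionMetrics:
    """Per-curve adhesion summary."""

    total_force: float  # pN
    mean_force: float  # pN
    count: int
    probability_flag: bool


def detect_ruptures(
    curve: ForceCurve,
    threshold: float = DEFAULT_RUPTURE_THRESHOLD,
    baseline_window: int = BASELINE_WINDOW,
) -> list[RuptureEvent]:
    """Find sustained positive deflection jumps in a retract curve.

    Increments are measured relative to the median increment of the
    preceding ``baseline_window`` samples (so a smooth drift does not
    register); a rupture must exceed ``threshold`` times the robust noise
    scale (1.4826*MAD) of that local baseline.  Consecutive above-threshold
    increments are merged into one event whose height is the summed jump and
    whose force is spring constant times height.  Events are ordered by z.
    """
    if curve.segment != "retract":
        raise SegmentError("rupture detection requires a retract segment")
    if len(curve.z) < 20:
        raise ParameterError("need at least 20 samples in the retract segment")
    d = curve.deflection
    dd = np.diff(d)

    def baseline(i: int) -> tuple[float, float]:
        lo = max(0, i - baseline_window)
        window = dd[lo:i] if i - lo >= 5 else dd[:baseline_window]
        med = float(np.median(window))
        mad = float(np.median(np.abs(window - med)))
        return med, 1.4826 * mad

    events: list[RuptureEvent] = []
    i = 0
    while i < len(dd):
        med, scale = baseline(i)
        limit = max(threshold * scale, 1e-12)
        if dd[i] - med > limit:
            j = i
            height = 0.0
            while j < len(dd) and dd[j] - med > limit:
                height += dd[j] - med
                j += 1
            events.append(
                RuptureEvent(
                    force=curve.spring_constant * height,
                    z_position=float(curve.z[i]),
                    height=float(height),
                )
            )
            i = j
        else:
            i += 1
    events.sort(key=lambda e: e.z_position)
    return events


def adhesion_metrics(events: list[RuptureEvent]) -> AdhesionMetrics:
    """Total and mean rupture force per curve plus the adhesion flag."""
    total = float(sum(e.force for e in events))
    count = len(events)
    return AdhesionMetrics(
        total_force=total,
        mean_force=total / count if count else 0.0,
        count=count,
        probability_flag=count > 0,
    )


def hertz_force(
    indentation: np.ndarray,
    e_modulus: float,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
) -> np.ndarray:
    """Spherical Hertz force law F = (4/3)(E/(1-nu^2)) sqrt(R) delta^{3/2} (pN)."""
    delta = np.clip(np.asarray(indentation, float), 0.0, None)
    e_pn = e_modulus * KPA_TO_PN_PER_NM2
    return (4.0 / 3.0) * (e_pn / (1.0 - poisson_ratio**2)) * np.sqrt(
        probe_radius
    ) * delta**1.5


def fit_hertz(
    curve: ForceCurve,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
) -> HertzFitResult:
    """Fit (E, contact point) to an approach curve by nonlinear least squares.

    Indentation is delta = (z - z_contact) - deflection; the model force
    k*deflection = (4/3)(E/(1-nu^2)) sqrt(R) delta^{3/2} is fitted on the
    post-contact region.
    """
    if curve.segment != "approach":
        raise SegmentError("Hertz fitting requires an approach segment")
    z, d = curve.z, curve.deflection
    if z[0] > z[-1]:  # normalize to increasing z (toward the cell)
        z, d = z[::-1], d[::-1]
    force = curve.spring_constant * d

    # initial contact guess: first sustained rise above the early baseline
    base = force[: max(5, len(force) // 10)]
    noise = float(np.std(base)) or 1e-6
    above = np.nonzero(force > base.mean() + 3 * noise)[0]
    z0_guess = z[above[0]] if len(above) else z[len(z) // 2]

    def model(zz, e_mod, z_c):
        delta = (zz - z_c) - np.interp(zz, z, d)
        return hertz_force(delta, e_mod, probe_radius, poisson_ratio)

    e0 = 10.0  # kPa, typical live-cell scale
    try:
        popt, _ = optimize.curve_fit(
            model,
            z,
            force,
            p0=[e0, z0_guess],
            bounds=([1e-6, z.min() - (z.max() - z.min())], [1e6, z.max()]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Hertz fit failed: {exc}") from exc
    e_fit, z_c = float(popt[0]), float(popt[1])
    if not np.isfinite(e_fit) or e_fit <= 0:
        raise FitError(f"Hertz fit returned non-physical modulus {e_fit}")

    delta = (z - z_c) - d
    post = delta > 0
    if post.sum() < 10:
        raise FitError("fewer than 10 post-contact samples")
    resid = force[post] - hertz_force(delta[post], e_fit, probe_radius, poisson_ratio)
    return HertzFitResult(
        e_modulus=e_fit,
        contact_point=z_c,
        indentation_depth=float(delta[post].max()),
        probe_radius=probe_radius,
        poisson_ratio=poisson_ratio,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def curves_to_timeseries(
    curves: list[tuple[ForceCurve | None, ForceCurve | None]],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
) -> tuple[TimeSeries | None, TimeSeries | None]:
    """Assemble (adhesion, stiffness) time series from (approach, retract) pairs.

    One sample per curve pair: the retract curve contributes its total
    rupture force, the approach curve its fitted E-modulus.  Pairs whose
    Hertz fit fails are skipped in the stiffness series (the resulting gap is
    closed later by resampling).  Returns None for a series with fewer than
    two usable samples.
    """
    adh_t, adh_v, stf_t, stf_v = [], [], [], []
    for approach, retract in curves:
        if retract is not None:
            events = detect_ruptures(retract)
            adh_t.append(retract.timestamp)
            adh_v.append(adhesion_metrics(events).total_force)
        if approach is not None:
            try:
                fit = fit_hertz(approach, probe_radius, poisson_ratio)
            except FitError:
                continue
            stf_t.append(approach.timestamp)
            stf_v.append(fit.e_modulus)
    def assemble(t, v, quantity):
        if len(t) < 2:
            return None
        t, v = np.asarray(t, float), np.asarray(v, float)
        dt = np.diff(t)
        rate = 1.0 / dt.mean() if np.max(np.abs(dt - dt.mean())) < 1e-6 else None
        return TimeSeries(t, v, quantity, sampling_rate=rate)

    return (
        assemble(adh_t, adh_v, Quantity.ADHESION_FORCE),
        assemble(stf_t, stf_v, Quantity.E_MODULUS),
    )


def sampling_cycle_frequency(velocity_nm_per_s: float, travel_nm: float) -> float:
    """Cycle rate (Hz) of one indentation + retraction at constant velocity.

    One cycle covers the travel distance twice (in and out), so the rate is
    velocity / (2 * travel).  At 1 um/s over 1000 nm this is 0.5 Hz.
    """
    if velocity_nm_per_s <= 0 or travel_nm <= 0:
        raise ParameterError("velocity and travel must be positive")
    return velocity_nm_per_s / (2.0 * travel_nm)


def expected_curve_count(duration_s: float, rate_hz: float) -> int:
    """Number of force curves collected in a session at a fixed cycle rate."""
    if duration_s <= 0 or rate_hz <= 0:
        raise ParameterError("duration and rate must be positive")
    return int(round(duration_s * rate_hz))
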