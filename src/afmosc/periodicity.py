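"""FFT periodicity detection, plausibility filtering, and sinusoid synthesis.

After SSA filtering, each oscillatory component is essentially a narrowband
sinusoid.  The discrete Fourier transform

    X_k = sum_{n=0}^{N-1} x_n exp(-i 2 pi k n / N)

locates it: the frequency bin with the largest |X_k| gives the component
frequency, 2|X_k|/N its amplitude, and arg(X_k) its phase.  Candidate peaks
are screened for physiological plausibility — components faster than a
frequency cutoff are instrument artifacts (live-cell biomechanical
oscillations sit in the mHz range), and peaks closer than a few FFT bins are
unresolved duplicates of one component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import Quantity, TimeSeries
from .preprocess import StandardizedSeries
from .ssa import ComponentSeries

__all__ = [
    "Spectrum",
    "DetectedPeak",
    "OscillatoryComponent",
    "GroupOscillationSummary",
    "compute_spectrum",
    "detect_components",
    "estimate_sinusoid",
    "reconstruct_sinusoid",
    "sum_components",
    "summarize_group",
]

logger = logging.getLogger(__name__)

#: Default plausibility cutoff: oscillations faster than this are rejected
#: as non-physiological instrument artifacts.
DEFAULT_MAX_FREQ = 0.1  # Hz
#: Default peak separation, in FFT bins; nearer peaks are unresolved duplicates.
DEFAULT_MIN_SEPARATION_BINS = 5
#: Default number of leading oscillatory components to keep per cell.
DEFAULT_MAX_COUNT = 2


@dataclass(frozen=True)
class Spectrum:
    """DFT of a length-N series sampled at fs Hz.

    ``coefficients`` holds all N complex X_k; ``frequencies`` the full axis
    k*fs/N.  The one-sided views (up to Nyquist) are what peak detection and
    PSD exports use.
    """

    frequencies: np.ndarray  # (N,) Hz
    coefficients: np.ndarray  # (N,) complex
    N: int
    sampling_rate: float

    @property
    def power(self) -> np.ndarray:
        """|X_k|^2 over the full axis."""
        return np.abs(self.coefficients) ** 2

    @property
    def bin_width(self) -> float:
        return self.sampling_rate / self.N

    def one_sided(self) -> tuple[np.ndarray, np.ndarray]:
        """(frequency, power) for k = 0 .. floor(N/2)."""
        half = self.N // 2 + 1
        return self.frequencies[:half], self.power[:half]

    def nearest_bin(self, frequency: float) -> int:
        k = int(round(frequency / self.bin_width))
        return min(max(k, 0), self.N // 2)


@dataclass(frozen=True)
class DetectedPeak:
    """A local PSD maximum surviving the plausibility filters."""

    frequency: float  # Hz
    power: float
    bin: int


@dataclass(frozen=True)
class OscillatoryComponent:
    """Stationary sinusoid parameters of one detected component.

    Reconstruction convention: x(t) = offset + amplitude*sin(2*pi*f*t + phase).
    """

    frequency: float  # Hz
    amplitude: float  # pN or kPa
    phase: float  # rad
    offset: float  # pN or kPa
    source: int = 0  # component rank (1 = highest power)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be non-negative")
        if self.frequency < 0:
            raise ParameterError("frequency must be non-negative")


@dataclass(frozen=True)
class GroupOscillationSummary:
    """Across-cell arithmetic means of component parameters, per rank."""

    mean_frequency: np.ndarray  # (ranks,) Hz
    mean_amplitude: np.ndarray
    mean_offset: np.ndarray
    n_cells: int
    rank_count: int


def compute_spectrum(
    series: ComponentSeries | StandardizedSeries | TimeSeries | np.ndarray,
    fs: float,
) -> Spectrum:
    """Discrete Fourier transform with a physical frequency axis."""
    x = np.asarray(series.values if hasattr(series, "values") else series, float)
    N = len(x)
    if N < 4:
        raise ParameterError("need N >= 4 for a spectrum")
    if fs <= 0:
        raise ParameterError("sampling rate must be positive")
    X = np.fft.fft(x)
    freqs = np.arange(N) * fs / N
    return Spectrum(frequencies=freqs, coefficients=X, N=N, sampling_rate=fs)


def detect_components(
    spec: Spectrum,
    max_freq: float = DEFAULT_MAX_FREQ,
    min_separation: float | None = None,
    max_count: int | None = DEFAULT_MAX_COUNT,
) -> list[DetectedPeak]:
    """Plausibility-filtered PSD peaks, sorted by descending power.

    Local maxima of the one-sided power spectrum (excluding DC) are culled
    in three stages: of any two peaks closer than ``min_separation`` (default
    5 FFT bins) only the higher-power one is kept; peaks above ``max_freq``
    are discarded as too fast to be physiological; at most ``max_count``
    survive.  An empty result is a logged warning, not an error.
    """
    if min_separation is None:
        min_separation = DEFAULT_MIN_SEPARATION_BINS * spec.bin_width
    freqs, power = spec.one_sided()
    # strict local maxima over the interior; k=0 (DC) excluded
    interior = np.arange(1, len(power) - 1)
    is_max = (power[interior] > power[interior - 1]) & (
        power[interior] >= power[interior + 1]
    )
    bins = interior[is_max]
    if len(power) >= 2 and power[-1] > power[-2]:
        bins = np.append(bins, len(power) - 1)
    order = bins[np.argsort(power[bins])[::-1]]

    kept: list[int] = []
    for k in order:  # greedy duplicate suppression, strongest first
        if all(abs(freqs[k] - freqs[j]) >= min_separation for j in kept):
            kept.append(int(k))
    peaks = [
        DetectedPeak(frequency=float(freqs[k]), power=float(power[k]), bin=k)
        for k in kept
        if freqs[k] <= max_freq
    ]
    peaks.sort(key=lambda pk: -pk.power)
    if max_count is not None:
        peaks = peaks[: int(max_count)]
    if not peaks:
        logger.warning("no plausible oscillatory component detected")
    return peaks


def estimate_sinusoid(
    series: TimeSeries | np.ndarray,
    frequency: float,
    fs: float | None = None,
    offset: float | None = None,
) -> OscillatoryComponent:
    """Estimate (amplitude, phase, offset) of the sinusoid at a given frequency.

    Reads the DFT at the bin nearest ``frequency``: amplitude = 2|X_k|/N and
    phase mapped so that offset + A*sin(2*pi*f*t + phase) reproduces the
    tone.  The offset defaults to the series mean.
    """
    if hasattr(series, "values"):
        x = np.asarray(series.values, float)
        fs = float(series.sampling_rate) if fs is None else fs
    else:
        x = np.asarray(series, float)
        if fs is None:
            raise ParameterError("fs required for a bare array")
    spec = compute_spectrum(x, fs)
    if not 0 < frequency < fs / 2:
        raise ParameterError("frequency must lie in (0, Nyquist)")
    k = spec.nearest_bin(frequency)
    Xk = spec.coefficients[k]
    amplitude = 2.0 * np.abs(Xk) / spec.N
    # X_k of A*sin(theta) is (N A / 2) e^{i(phase - pi/2)} at the tone bin
    phase = float(np.angle(Xk) + np.pi / 2.0)
    phase = float((phase + np.pi) % (2 * np.pi) - np.pi)
    return OscillatoryComponent(
        frequency=float(spec.frequencies[k]),
        amplitude=float(amplitude),
        phase=phase,
        offset=float(x.mean()) if offset is None else float(offset),
    )


def reconstruct_sinusoid(
    c: OscillatoryComponent,
    N: int,
    fs: float,
    quantity: Quantity | str = Quantity.ADHESION_FORCE,
) -> TimeSeries:
    """Synthesize x_n = offset + A*sin(2*pi*f*n/fs + phase), n = 0..N-1."""
    t = np.arange(N) / fs
    values = c.offset + c.amplitude * np.sin(2 * np.pi * c.frequency * t + c.phase)
    return TimeSeries(t, values, Quantity(quantity), sampling_rate=fs)


def sum_components(
    components: list[OscillatoryComponent],
    N: int,
    fs: float,
    quantity: Quantity | str = Quantity.ADHESION_FORCE,
) -> TimeSeries:
    """Sum of component sinusoids oscillating about the shared mean level.

    Each component carries the series mean as its offset; the sum counts
    that shared level once (each of the m components contributes offset/m),
    so single components and their sum oscillate about the same average.
    """
    if not components:
        raise ParameterError("need at least one component")
    t = np.arange(N) / fs
    m = len(components)
    values = np.zeros(N)
    for c in components:
        values += c.offset / m + c.amplitude * np.sin(
            2 * np.pi * c.frequency * t + c.phase
        )
    return TimeSeries(t, values, Quantity(quantity), sampling_rate=fs)


def summarize_group(
    per_cell: list[list[OscillatoryComponent]],
) -> GroupOscillationSummary:
    """Arithmetic mean of frequency/amplitude/offset per component rank.

    Rank 1 is each cell's highest-power component.  Cells missing a rank
    (fewer detected components) simply do not contribute to that rank's mean.
    """
    if not per_cell:
        raise ParameterError("need at least one cell")
    rank_count = max(len(cs) for cs in per_cell)
    if rank_count == 0:
        raise ParameterError("no components detected in any cell")
    mf, ma, mo = [], [], []
    for r in range(rank_count):
        at_rank = [cs[r] for cs in per_cell if len(cs) > r]
        mf.append(np.mean([c.frequency for c in at_rank]))
        ma.append(np.mean([c.amplitude for c in at_rank]))
        mo.append(np.mean([c.offset for c in at_rank]))
    return GroupOscillationSummary(
        mean_frequency=np.array(mf),
        mean_amplitude=np.array(ma),
        mean_offset=np.array(mo),
        n_cells=len(per_cell),
        rank_count=rank_count,
    )
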