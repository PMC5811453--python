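"""End-to-end pipeline: resample -> detrend/standardize -> SSA -> FFT -> report.

`analyze_series` is the library entry point; `run_single` / `run_group` add
file output on top and back the command-line driver.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import periodicity, preprocess, ssa
from .errors import ParameterError
from .io import Quantity, TimeSeries, read_timeseries, resample_uniform
from .periodicity import (
    DEFAULT_MAX_COUNT,
    DEFAULT_MAX_FREQ,
    DEFAULT_MIN_SEPARATION_BINS,
    GroupOscillationSummary,
    OscillatoryComponent,
    Spectrum,
)

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_series", "run_single", "run_group"]

logger = logging.getLogger(__name__)

#: Accumulated-eigenvalue-fraction thresholds separating signal from the
#: noise floor, per measured quantity.
DEFAULT_THRESHOLDS = {
    Quantity.ADHESION_FORCE: 0.1,
    Quantity.E_MODULUS: 0.6,
}


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable pipeline configuration."""

    quantity: str = "adhesion_force"
    resample_rate: float = 0.5  # Hz
    ssa_threshold: float | None = None  # None -> per-quantity default
    embedding_order: int | str = "auto"  # p; "auto" = floor(N/2)
    max_freq: float = DEFAULT_MAX_FREQ  # Hz, plausibility cutoff
    min_separation_bins: int = DEFAULT_MIN_SEPARATION_BINS
    max_count: int = DEFAULT_MAX_COUNT
    probe_radius: float = 2500.0  # nm
    poisson_ratio: float = 0.5
    seed: int = 0
    output_dir: str = "afmosc_out"

    def effective_threshold(self) -> float:
        if self.ssa_threshold is not None:
            return float(self.ssa_threshold)
        return DEFAULT_THRESHOLDS[Quantity(self.quantity)]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the pipeline computes for one cell."""

    standardized: preprocess.StandardizedSeries
    spectrum_table: np.ndarray  # (index, eigenvalue, fraction, cumulative)
    filtered: ssa.ComponentSeries
    ssa_components: list[ssa.ComponentSeries]
    raw_spectrum: Spectrum
    filtered_spectrum: Spectrum
    components: list[OscillatoryComponent]  # ranked, physical scale
    n_leading: int
    threshold: float


def analyze_series(ts: TimeSeries, config: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full SSA -> FFT extraction on one time series.

    Steps: resample to a uniform grid if needed; OLS detrend and standardize;
    SSA filter at the per-quantity eigenvalue-fraction threshold (retaining
    at least one eigentriple pair per requested component so the component
    count is well-posed); FFT the filtered series; keep the plausible peaks;
    estimate each component's amplitude and phase on the physical-scale
    filtered series, with the raw series mean as its offset.
    """
    config = config or PipelineConfig(quantity=ts.quantity.value)
    if ts.sampling_rate is None or not ts.is_uniform():
        ts = resample_uniform(ts, config.resample_rate)
        logger.info("resampled to %.3g Hz (N=%d)", config.resample_rate, ts.N)

    std = preprocess.detrend_standardize(ts)
    threshold = config.effective_threshold()
    filtered, comps, spec = ssa.ssa_filter(
        std,
        threshold,
        p=config.embedding_order,
        min_pairs=config.max_count,
    )
    logger.info(
        "SSA threshold %.3g kept %d eigentriples (%d groups)",
        threshold,
        len(filtered.member_indices),
        len(comps),
    )

    fs = float(ts.sampling_rate)
    raw_spec = periodicity.compute_spectrum(std, fs)
    filt_spec = periodicity.compute_spectrum(filtered, fs)
    min_sep = config.min_separation_bins * filt_spec.bin_width
    peaks = periodicity.detect_components(
        filt_spec,
        max_freq=config.max_freq,
        min_separation=min_sep,
        max_count=config.max_count,
    )
    for pk in peaks:
        logger.info("detected component at %.4g Hz (power %.3g)", pk.frequency, pk.power)

    # physical-scale filtered signal recentred at the raw series mean, so
    # amplitudes come out in pN/kPa and offsets equal the series average
    physical = filtered.values * std.trend.std + std.trend.mean
    offset = float(ts.values.mean())
    components = []
    for rank, pk in enumerate(peaks, start=1):
        c = periodicity.estimate_sinusoid(physical, pk.frequency, fs=fs, offset=offset)
        components.append(dataclasses.replace(c, source=rank))

    return AnalysisResult(
        standardized=std,
        spectrum_table=spec.to_table(),
        filtered=filtered,
        ssa_components=comps,
        raw_spectrum=raw_spec,
        filtered_spectrum=filt_spec,
        components=components,
        n_leading=len(filtered.member_indices),
        threshold=threshold,
    )


def _write_result(result: AnalysisResult, ts: TimeSeries, outdir: Path, cell_id: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fs = result.standardized.sampling_rate
    N = result.standardized.N

    pd.DataFrame(
        {"time_s": result.standardized.times, "standardized": result.standardized.values}
    ).to_csv(outdir / f"{cell_id}_standardized.csv", index=False)

    pd.DataFrame(
        result.spectrum_table,
        columns=["index", "eigenvalue", "fraction", "cumulative_fraction"],
    ).to_csv(outdir / f"{cell_id}_singular_spectrum.csv", index=False)

    comp_cols = {"time_s": result.standardized.times, "filtered": result.filtered.values}
    for c in result.ssa_components:
        comp_cols[f"group_{c.group_index}"] = c.values
    pd.DataFrame(comp_cols).to_csv(outdir / f"{cell_id}_ssa_components.csv", index=False)

    for label, spec in (("raw", result.raw_spectrum), ("filtered", result.filtered_spectrum)):
        f, p = spec.one_sided()
        pd.DataFrame({"frequency_hz": f, "power": p}).to_csv(
            outdir / f"{cell_id}_psd_{label}.csv", index=False
        )

    unit = ts.quantity.unit
    pd.DataFrame(
        [
            {
                "cell_id": cell_id,
                "rank": c.source,
                "frequency_hz": c.frequency,
                f"amplitude_{unit}": c.amplitude,
                "phase_rad": c.phase,
                f"offset_{unit}": c.offset,
            }
            for c in result.components
        ]
    ).to_csv(outdir / f"{cell_id}_components.csv", index=False)

    if result.components:
        recon = {"time_s": np.arange(N) / fs}
        for c in result.components:
            recon[f"rank_{c.source}"] = periodicity.reconstruct_sinusoid(
                c, N, fs, ts.quantity
            ).values
        recon["sum"] = periodicity.sum_components(
            result.components, N, fs, ts.quantity
        ).values
        pd.DataFrame(recon).to_csv(outdir / f"{cell_id}_reconstruction.csv", index=False)


def run_single(
    config: PipelineConfig, input_path, cell_id: str | None = None
) -> AnalysisResult:
    """Analyze one file and write the full report bundle to the output dir."""
    ts = read_timeseries(input_path, config.quantity)
    result = analyze_series(ts, config)
    cell = cell_id or Path(input_path).stem
    _write_result(result, ts, Path(config.output_dir), cell)
    return result


def run_group(
    config: PipelineConfig, input_paths: list
) -> tuple[GroupOscillationSummary, list[AnalysisResult]]:
    """Analyze several cells and summarize component parameters across them."""
    if not input_paths:
        raise ParameterError("need at least one input")
    results = [run_single(config, p) for p in input_paths]
    summary = periodicity.summarize_group([r.components for r in results])

    unit = Quantity(config.quantity).unit
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "rank": np.arange(1, summary.rank_count + 1),
            "mean_frequency_hz": summary.mean_frequency,
            f"mean_amplitude_{unit}": summary.mean_amplitude,
            f"mean_offset_{unit}": summary.mean_offset,
            "n_cells": summary.n_cells,
        }
    ).to_csv(outdir / "group_summary.csv", index=False)
    return summary, results
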