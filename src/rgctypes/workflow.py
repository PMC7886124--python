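"""Orchestration: spike trains -> metrics -> profiles -> cluster records.

This module wires the analysis modules together for the CLI, the analysis
scripts and the tests. All scientific computation lives in
:mod:`~rgctypes.metrics`, :mod:`~rgctypes.indices`,
:mod:`~rgctypes.clustering` and :mod:`~rgctypes.population`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import stimuli as st
from .clustering import CellRecord, PipelineResult, TemplateLibrary, run_pipeline
from .indices import build_profile
from .metrics import (
    BIN_WIDTH_S,
    ChirpSpectrum,
    FlashPSTH,
    GratingResponseMap,
    SpikeTrain,
    bin_spikes,
    chirp_spectrum,
    flash_psth,
    grating_map,
    grating_response_strength,
    trial_rate,
)
from .synthetic import ClusterTemplate, make_templates

__all__ = ["AnalysisConfig", "UnitAnalysis", "analyze_unit", "analyze_population",
           "records_from_analyses", "cluster_population"]

#: multiple of the pooled spontaneous SD a chirp response peak must exceed
CHIRP_RESPONSE_SD = 3.0
#: multiple for single-sweep bar responses (single trials are noisier)
BAR_RESPONSE_SD = 4.0


@dataclass
class AnalysisConfig:
    kernel_sigma: float = 0.040  # s
    spont_window: float = 2.0  # s of grey before the first contrast step
    chirp_band: tuple[float, float] = (0.5, 8.0)
    chirp_response_sd: float = CHIRP_RESPONSE_SD
    bar_response_sd: float = BAR_RESPONSE_SD
    contrast_pre_grey: float = 2.0  # s
    template_dt: float = 0.01  # s; time base of cluster templates
    bar_speeds: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass
class UnitAnalysis:
    """All per-unit derived objects in one place."""

    unit_id: str
    profile: object
    flash: Optional[FlashPSTH] = None
    grating_map: Optional[GratingResponseMap] = None
    spectrum: Optional[ChirpSpectrum] = None
    chirp_trace: Optional[np.ndarray] = None
    flash_trace: Optional[np.ndarray] = None
    chirp_probed: bool = False
    responds_to_chirp: bool = False
    spont_mean: float = 0.0
    spont_sd: float = 0.0


def _downsample(x: np.ndarray, dt_in: float, dt_out: float) -> np.ndarray:
    stride = int(round(dt_out / dt_in))
    return x[: x.size // stride * stride].reshape(-1, stride).mean(axis=1)


def _max_normalize(x: np.ndarray) -> np.ndarray:
    peak = x.max()
    return x / peak if peak > 0 else x


def analyze_unit(train: SpikeTrain, config: AnalysisConfig | None = None) -> UnitAnalysis:
    """Compute every response representation available from the unit's epochs."""
    config = config or AnalysisConfig()
    ids = set(train.stimulus_ids())
    out = UnitAnalysis(unit_id=train.unit_id, profile=None)

    # --- flash
    if "flash" in ids:
        out.flash = flash_psth(train, sigma=config.kernel_sigma,
                               spont_window=config.spont_window)
        out.spont_mean, out.spont_sd = out.flash.spont_mean, out.flash.spont_sd
        out.flash_trace = _max_normalize(
            _downsample(out.flash.rate, BIN_WIDTH_S, config.template_dt))

    # --- chirp frequency ramp
    contrast_rate = None
    contrast_bg = None
    if "chirp_freq" in ids:
        out.chirp_probed = True
        chirp = st.ChirpStimulus(kind="frequency_ramp")
        binned = bin_spikes(train, "chirp_freq")
        stim_trace = chirp.trace()[: binned.trials.shape[1]]
        out.spectrum = chirp_spectrum(binned, stim_trace, band=config.chirp_band)
        mean_rate, _ = trial_rate(train, "chirp_freq", sigma=config.kernel_sigma)
        out.chirp_trace = _max_normalize(
            _downsample(mean_rate, BIN_WIDTH_S, config.template_dt))
        spont_mean, spont_sd = _spontaneous_stats(train, out, config)
        out.responds_to_chirp = bool(
            mean_rate.max() > spont_mean + config.chirp_response_sd * spont_sd)

    # --- contrast ramp
    if "chirp_contrast" in ids:
        contrast_rate, _ = trial_rate(train, "chirp_contrast", sigma=config.kernel_sigma)
        n_bg = int(round(config.contrast_pre_grey / BIN_WIDTH_S))
        contrast_bg = float(contrast_rate[:n_bg].mean()) if n_bg else 0.0

    # --- gratings
    strengths: dict[tuple[float, float], tuple[float, bool]] = {}
    for p in st.GRATING_PERIODS_UM:
        for f in st.GRATING_FREQS_HZ:
            sid = st.grating_id(p, f)
            if sid in ids:
                binned = bin_spikes(train, sid)
                strengths[(p, f)] = grating_response_strength(binned, f)
    if strengths:
        out.grating_map = grating_map(strengths)

    # --- moving bars
    peaks_by_speed: dict[float, float] | None = None
    spont_mean, spont_sd = _spontaneous_stats(train, out, config)
    medians = []
    for pol in ("black", "white"):
        peaks: dict[float, float] = {}
        responded = False
        for speed in config.bar_speeds:
            sid = f"bar_{pol}_s{speed:g}"
            if sid not in ids:
                continue
            rate, _ = trial_rate(train, sid, sigma=config.kernel_sigma)
            peak = float(rate.max())
            if peak > spont_mean + config.bar_response_sd * spont_sd:
                responded = True
            peaks[speed] = max(peak - spont_mean, 0.0)
        if responded and len(peaks) >= 2 and sum(peaks.values()) > 0:
            from .indices import median_speed_preference
            medians.append(median_speed_preference(peaks))
            peaks_by_speed = peaks
    median_speed = max(medians) if medians else None

    out.profile = build_profile(
        train.unit_id,
        flash=out.flash,
        rmap=out.grating_map,
        spectrum=out.spectrum if out.responds_to_chirp else None,
        contrast_rate=contrast_rate if out.responds_to_chirp else None,
        contrast_background=contrast_bg,
        peaks_by_speed=None,
        contrast_ramp_start=config.contrast_pre_grey,
    )
    out.profile.median_speed_mm_s = median_speed
    return out


def _spontaneous_stats(train: SpikeTrain, analysis: UnitAnalysis,
                       config: AnalysisConfig) -> tuple[float, float]:
    """Pooled spontaneous mean/SD: flash baseline when available, else the
    grey lead-in of the contrast ramp, else the low quantile of the chirp."""
    if analysis.flash is not None:
        return analysis.flash.spont_mean, analysis.flash.spont_sd
    ids = set(train.stimulus_ids())
    if "chirp_contrast" in ids:
        _, per_trial = trial_rate(train, "chirp_contrast", sigma=config.kernel_sigma)
        n = int(round(config.contrast_pre_grey / BIN_WIDTH_S))
        seg = per_trial[:, :n]
        if seg.size:
            return float(seg.mean()), float(seg.std())
    if "chirp_freq" in ids:
        _, per_trial = trial_rate(train, "chirp_freq", sigma=config.kernel_sigma)
        flat = per_trial.ravel()
        lo = flat[flat <= np.quantile(flat, 0.2)]
        return float(lo.mean()), float(flat.std())
    return 0.0, 0.0


def analyze_population(trains: Sequence[SpikeTrain],
                       config: AnalysisConfig | None = None) -> list[UnitAnalysis]:
    return [analyze_unit(t, config) for t in trains]


def records_from_analyses(analyses: Sequence[UnitAnalysis]) -> list[CellRecord]:
    return [
        CellRecord(
            unit_id=a.unit_id, profile=a.profile, grating_map=a.grating_map,
            chirp_spectrum=a.spectrum, chirp_trace=a.chirp_trace,
            flash_trace=a.flash_trace, flash_psth=a.flash,
            chirp_probed=a.chirp_probed, responds_to_chirp=a.responds_to_chirp,
        )
        for a in analyses
    ]


def cluster_population(analyses: Sequence[UnitAnalysis],
                       templates: Sequence[ClusterTemplate] | None = None,
                       seed: int = 0,
                       k_range: tuple[int, int] = (2, 12),
                       repetitions: int = 1000) -> PipelineResult:
    """Records -> template library -> 5-step cascade."""
    templates = list(templates) if templates is not None else make_templates()
    records = records_from_analyses(analyses)
    library = TemplateLibrary(templates=templates)
    return run_pipeline(records, library, seed=seed, k_range=k_range,
                        repetitions=repetitions)
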