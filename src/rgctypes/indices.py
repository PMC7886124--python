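"""Per-cell scalar response descriptors.

* polarity: ON / OFF / ON-OFF / none from flash transition peaks against the
  spontaneous mean + 2 SD criterion,
* transiency: time from the response peak back to baseline + 2 SD (capped at
  the 2 s step duration),
* median speed preference: first speed at which the cumulative sum of
  per-speed peak responses crosses 50%,
* contrast preference index CPI = (high - low)/(high + low) over the first
  and last thirds of the contrast ramp,
* chirp frequency index CFI, same form over the 6-7.2 Hz and 0.7-3 Hz bands
  of the FFT-ratio spectrum,
* moment-based Gaussian fit to the 6x4 grating heatmap (weighted centroid
  and second moments; the squared eigenvalues of [[a, b], [b, c]] are the
  major axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .metrics import ChirpSpectrum, FlashPSTH, GratingResponseMap, _moving_average

__all__ = [
    "CellProfile",
    "GaussianFitResult",
    "polarity",
    "transiency",
    "median_speed_preference",
    "contrast_preference_index",
    "chirp_frequency_index",
    "fit_gaussian_heatmap",
    "build_profile",
]

#: CFI bands (Hz): high 6-7.2, low 0.7-3
CFI_HIGH_BAND = (6.0, 7.2)
CFI_LOW_BAND = (0.7, 3.0)
CFI_SMOOTH_HZ = 0.3

TRANSIENCY_CAP_MS = 2000.0


@dataclass
class CellProfile:
    """Derived per-cell quantities; ``None`` marks a stimulus not measured."""

    unit_id: str
    polarity: Optional[str] = None
    transiency_ms: Optional[float] = None
    median_speed_mm_s: Optional[float] = None
    cpi: Optional[float] = None
    cfi: Optional[float] = None
    sf_preference_um: Optional[float] = None
    tf_preference_hz: Optional[float] = None
    peak_rate_hz: Optional[float] = None
    spontaneous_rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("cpi", "cfi"):
            v = getattr(self, name)
            if v is not None and not (-1.0 - 1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        if self.transiency_ms is not None and self.transiency_ms < 0:
            raise ValueError("transiency must be non-negative")


@dataclass
class GaussianFitResult:
    csf: float  # centroid on the spatial axis (um)
    ctf: float  # centroid on the temporal axis (Hz)
    a: float
    b: float
    c: float
    major_axes: tuple[float, float]  # squared eigenvalues of [[a, b], [b, c]]
    edge_peak: bool = False  # strongest entry sits on the grid border


# ---------------------------------------------------------------------------
# flash-derived indices
# ---------------------------------------------------------------------------

def polarity(psth: FlashPSTH) -> str:
    """ON / OFF / ON-OFF / none from the per-transition peak rates.

    Positive-contrast transitions are grey->white and black->grey; negative
    are grey->black and white->grey. A transition responds when its peak
    exceeds spontaneous mean + 2 SD.
    """
    thr = psth.threshold + 1e-9  # epsilon guards exactly-flat noise-free traces
    pos = any(p > thr for _, sign, p, _ in psth.transition_peaks if sign > 0)
    neg = any(p > thr for _, sign, p, _ in psth.transition_peaks if sign < 0)
    if pos and neg:
        return "ON-OFF"
    if pos:
        return "ON"
    if neg:
        return "OFF"
    return "none"


def transiency(psth: FlashPSTH, step_duration: float = 2.0) -> float:
    """Time (ms) from the preferred-transition peak back to baseline + 2 SD.

    Measured on the strongest responding transition; capped at the step
    duration when the rate never returns within the step.
    """
    thr = psth.threshold
    responding = [(t, s, p, pt) for t, s, p, pt in psth.transition_peaks if p > thr]
    if not responding:
        raise ValueError("cell has no responding transition")
    t_step, _, _, peak_time = max(responding, key=lambda r: r[2])
    dt = psth.time[1] - psth.time[0]
    i_peak = int(round(peak_time / dt))
    i_end = min(int(round((t_step + step_duration) / dt)), psth.rate.size)
    below = np.nonzero(psth.rate[i_peak:i_end] <= thr)[0]
    if below.size == 0:
        return TRANSIENCY_CAP_MS
    return min(float(below[0] * dt * 1000.0), TRANSIENCY_CAP_MS)


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------

def median_speed_preference(peaks_by_speed: dict[float, float]) -> float:
    """First speed at which the cumulative response fraction reaches 50%.

    No interpolation: the crossing speed itself is returned. For a cell
    responding to both bar polarities, call per polarity and report the
    higher of the two medians (population convention).
    """
    if len(peaks_by_speed) < 2:
        raise ValueError("need responses at >= 2 speeds")
    speeds = sorted(peaks_by_speed)
    vals = np.asarray([peaks_by_speed[s] for s in speeds], dtype=float)
    total = vals.sum()
    if total <= 0:
        raise ValueError("all-zero speed responses")
    cum = np.cumsum(vals) / total
    return float(speeds[int(np.argmax(cum >= 0.5))])


# ---------------------------------------------------------------------------
# chirp-derived indices
# ---------------------------------------------------------------------------

def contrast_preference_index(rate: np.ndarray, background: float,
                              dt: float = 0.001,
                              ramp_start: float = 0.0,
                              ramp_duration: float = 8.0) -> float:
    """CPI = (high - low)/(high + low) over the contrast-ramp thirds.

    ``low``/``high`` are the summed absolute background-subtracted rates over
    the first and last thirds of the ramp.
    """
    i0 = int(round(ramp_start / dt))
    n = int(round(ramp_duration / dt))
    seg = np.abs(rate[i0:i0 + n] - background)
    third = n // 3
    low = float(seg[:third].sum())
    high = float(seg[-third:].sum())
    if low + high == 0:
        raise ValueError("zero total modulation on the contrast ramp")
    return (high - low) / (high + low)


def chirp_frequency_index(spectrum: ChirpSpectrum,
                          high_band: tuple[float, float] = CFI_HIGH_BAND,
                          low_band: tuple[float, float] = CFI_LOW_BAND,
                          smooth_hz: float = CFI_SMOOTH_HZ) -> float:
    """CFI = (high - low)/(high + low) on the 0.3 Hz-smoothed FFT ratio."""
    df = float(spectrum.freqs[1] - spectrum.freqs[0])
    window = max(1, int(round(smooth_hz / df)))
    if window % 2 == 0:
        window += 1  # keep the average centered
    smoothed = _moving_average(spectrum.raw_ratio, window)
    hi_m = (spectrum.freqs >= high_band[0]) & (spectrum.freqs <= high_band[1])
    lo_m = (spectrum.freqs >= low_band[0]) & (spectrum.freqs <= low_band[1])
    if not hi_m.any() or not lo_m.any():
        raise ValueError("spectrum does not cover the CFI bands")
    high = float(smoothed[hi_m].mean())
    low = float(smoothed[lo_m].mean())
    if high + low == 0:
        return 0.0
    return (high - low) / (high + low)


# ---------------------------------------------------------------------------
# Gaussian fit to the grating heatmap
# ---------------------------------------------------------------------------

def fit_gaussian_heatmap(rmap: GratingResponseMap,
                         log_axes: bool = False) -> GaussianFitResult:
    """Moment 'Gaussian fit': weighted centroid and second moments of the map.

    Weights are the valid map entries normalized to sum 1 (a plain dot
    product with the frequency meshes has no centroid interpretation).
    Axes are the native linear units (um, Hz) by default; ``log_axes``
    switches to log2 axes and returns centers transformed back.
    """
    w = np.where(rmap.valid, rmap.strengths, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no valid entries in the response map")
    w = w / total
    sf_axis = np.asarray(rmap.periods, dtype=float)
    tf_axis = np.asarray(rmap.freqs, dtype=float)
    if log_axes:
        sf_axis = np.log2(sf_axis)
        tf_axis = np.log2(tf_axis)
    sf_mesh, tf_mesh = np.meshgrid(sf_axis, tf_axis, indexing="ij")
    csf = float((w * sf_mesh).sum())
    ctf = float((w * tf_mesh).sum())
    a = float((w * (sf_mesh - csf) ** 2).sum())
    b = float((w * (sf_mesh - csf) * (tf_mesh - ctf)).sum())
    c = float((w * (tf_mesh - ctf) ** 2).sum())
    eig = np.linalg.eigvalsh(np.array([[a, b], [b, c]]))
    axes = (float(eig[0] ** 2), float(eig[1] ** 2))

    rows, cols = np.nonzero(w == w.max())
    edge = bool(rows[0] in (0, w.shape[0] - 1) or cols[0] in (0, w.shape[1] - 1))
    if log_axes:
        csf, ctf = float(2.0 ** csf), float(2.0 ** ctf)
    return GaussianFitResult(csf=csf, ctf=ctf, a=a, b=b, c=c,
                             major_axes=axes, edge_peak=edge)


# ---------------------------------------------------------------------------
# profile assembly
# ---------------------------------------------------------------------------

def build_profile(unit_id: str,
                  flash: FlashPSTH | None = None,
                  rmap: GratingResponseMap | None = None,
                  spectrum: ChirpSpectrum | None = None,
                  contrast_rate: np.ndarray | None = None,
                  contrast_background: float | None = None,
                  peaks_by_speed: dict[float, float] | None = None,
                  contrast_ramp_start: float = 2.0) -> CellProfile:
    """Assemble a :class:`CellProfile`; absent stimuli stay ``None``."""
    if all(x is None for x in (flash, rmap, spectrum, contrast_rate, peaks_by_speed)):
        raise ValueError(f"unit {unit_id}: no stimulus measured")
    prof = CellProfile(unit_id=unit_id)
    if flash is not None:
        prof.polarity = polarity(flash)
        prof.peak_rate_hz = flash.peak_rate()
        prof.spontaneous_rate_hz = flash.spont_mean
        if prof.polarity != "none":
            prof.transiency_ms = transiency(flash)
    if rmap is not None and rmap.responsive:
        fit = fit_gaussian_heatmap(rmap)
        prof.sf_preference_um = fit.csf
        prof.tf_preference_hz = fit.ctf
    if spectrum is not None:
        prof.cfi = chirp_frequency_index(spectrum)
    if contrast_rate is not None and contrast_background is not None:
        try:
            prof.cpi = contrast_preference_index(
                contrast_rate, contrast_background, ramp_start=contrast_ramp_start)
        except ValueError:
            prof.cpi = None
    if peaks_by_speed:
        try:
            prof.median_speed_mm_s = median_speed_preference(peaks_by_speed)
        except ValueError:
            prof.median_speed_mm_s = None
    return prof
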