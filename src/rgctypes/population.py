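"""Population-level summaries.

Mean spatio-temporal heatmap, distributions of preferred spatial period and
temporal frequency, population spatial/temporal response curves with the
10%-of-maximum resolution threshold (in cyc/deg), binned chirp FFT-ratio
statistics, and the ON/OFF/ON-OFF polarity split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import stimuli as st
from .indices import CellProfile
from .metrics import ChirpSpectrum, GratingResponseMap

__all__ = [
    "PopulationCurves",
    "population_heatmap",
    "preferred_frequency_distributions",
    "response_curves",
    "chirp_population_bins",
    "polarity_proportions",
]


@dataclass
class PopulationCurves:
    spatial_freqs_cpd: np.ndarray  # ascending cyc/deg
    spatial_curve: np.ndarray  # mean normalized response per spatial frequency
    temporal_freqs_hz: np.ndarray
    temporal_curve: np.ndarray
    threshold_cpd: Optional[float]  # first drop below 10% of max, interpolated
    threshold_extrapolated: bool
    n_cells: int


def population_heatmap(maps: Sequence[GratingResponseMap]) -> np.ndarray:
    """Entrywise mean of per-cell max-normalized maps (invalid entries are 0)."""
    if not maps:
        raise ValueError("no maps")
    normed = [m if m.normalized else m.normalize() for m in maps]
    return np.mean([np.where(m.valid, m.strengths, 0.0) for m in normed], axis=0)


def preferred_frequency_distributions(
    maps: Sequence[GratingResponseMap],
) -> tuple[dict[float, int], dict[float, int]]:
    """Histograms of per-cell preferred period and temporal frequency.

    Ties break toward the lower frequency and larger period.
    """
    usable = [m for m in maps if m.responsive]
    if not usable:
        raise ValueError("no map with a valid maximum")
    period_hist = {p: 0 for p in usable[0].periods}
    freq_hist = {f: 0 for f in usable[0].freqs}
    for m in usable:
        p, f = m.argmax_entry()
        period_hist[p] += 1
        freq_hist[f] += 1
    return period_hist, freq_hist


def _first_crossing(x: np.ndarray, y: np.ndarray, level: float
                    ) -> tuple[Optional[float], bool]:
    """First x (ascending) where y drops below level, linearly interpolated."""
    below = y < level
    if not below.any():
        return None, True
    i = int(np.argmax(below))
    if i == 0:
        return float(x[0]), True
    x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
    return float(x0 + (y0 - level) / (y0 - y1) * (x1 - x0)), False


def response_curves(maps: Sequence[GratingResponseMap],
                    factor: float = st.UM_PER_DEGREE,
                    threshold_fraction: float = 0.1) -> PopulationCurves:
    """Population spatial/temporal response curves.

    Per cell the spatial profile is the row at the cell's optimal temporal
    frequency (max-normalized), and dually for the temporal profile; cells
    without a valid optimum are excluded. The spatial threshold is the first
    spatial frequency (cyc/deg, ascending = finer gratings) at which the
    mean curve drops below ``threshold_fraction`` of its maximum, linearly
    interpolated between grid points.
    """
    spatial_profiles, temporal_profiles = [], []
    for m in maps:
        if not m.responsive:
            continue
        mm = m if m.normalized else m.normalize()
        s = np.where(mm.valid, mm.strengths, 0.0)
        i_p, i_f = np.unravel_index(np.argmax(s), s.shape)
        row = s[:, i_f]  # spatial profile at the optimal temporal frequency
        col = s[i_p, :]
        spatial_profiles.append(row / row.max())
        temporal_profiles.append(col / col.max())
    if not spatial_profiles:
        raise ValueError("no responsive cells")
    spatial = np.mean(spatial_profiles, axis=0)
    temporal = np.mean(temporal_profiles, axis=0)

    periods = np.asarray(maps[0].periods, dtype=float)
    cpd = factor / periods  # descending period -> ascending cyc/deg
    order = np.argsort(cpd)
    cpd_sorted, spatial_sorted = cpd[order], spatial[order]
    level = threshold_fraction * spatial_sorted.max()
    thr, extrap = _first_crossing(cpd_sorted, spatial_sorted, level)
    return PopulationCurves(
        spatial_freqs_cpd=cpd_sorted, spatial_curve=spatial_sorted,
        temporal_freqs_hz=np.asarray(maps[0].freqs, dtype=float),
        temporal_curve=temporal, threshold_cpd=thr,
        threshold_extrapolated=extrap, n_cells=len(spatial_profiles))


def chirp_population_bins(spectra: Sequence[ChirpSpectrum],
                          bin_width_hz: float = 1.0,
                          band: tuple[float, float] = (0.5, 8.0)) -> list[dict]:
    """Distribution statistics of per-cell mean FFT ratio per frequency bin.

    Returns one dict per bin with mean, quartiles, min and max across cells.
    The display bin width defaults to 1 Hz; other widths (e.g. 2.6 Hz) are
    supported through ``bin_width_hz``.
    """
    if not spectra:
        raise ValueError("no spectra")
    edges = np.arange(band[0], band[1] + 1e-9, bin_width_hz)
    if edges[-1] < band[1]:
        edges = np.append(edges, band[1])
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        per_cell = []
        for s in spectra:
            m = (s.freqs >= lo) & (s.freqs < hi)
            if m.any():
                per_cell.append(float(s.ratio[m].mean()))
        v = np.asarray(per_cell)
        out.append({
            "lo_hz": float(lo), "hi_hz": float(hi), "n": int(v.size),
            "mean": float(v.mean()), "min": float(v.min()), "max": float(v.max()),
            "q25": float(np.percentile(v, 25)), "median": float(np.median(v)),
            "q75": float(np.percentile(v, 75)),
        })
    return out


def polarity_proportions(profiles: Sequence[CellProfile]) -> dict[str, float]:
    """Fractions of ON / OFF / ON-OFF among flash responders; sums to 1."""
    responders = [p for p in profiles if p.polarity in ("ON", "OFF", "ON-OFF")]
    if not responders:
        raise ValueError("no flash responders")
    n = len(responders)
    return {
        pol: sum(1 for p in responders if p.polarity == pol) / n
        for pol in ("ON", "OFF", "ON-OFF")
    }
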