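"""Spike-train response representations.

Converts spike times into the representations the typing pipeline consumes:

* per-trial binary vectors at 1 ms resolution,
* Gaussian-kernel firing rates (unit-area kernels, so traces integrate to
  the spike count),
* drifting-grating F1 response strengths (Fourier amplitude of the
  trial-mean binary vector at the stimulus frequency) with a spectral
  peak-validity rule,
* chirp FFT-ratio spectra norm(FT_response)/FT_stimulus on a 0.125 Hz grid,
* flash PSTHs with spontaneous statistics and per-transition peaks,
* recording-quality reports (refractory violations, block stability,
  duplicate-unit detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from . import stimuli as st

__all__ = [
    "Epoch",
    "SpikeTrain",
    "BinnedResponse",
    "GratingResponseMap",
    "ChirpSpectrum",
    "FlashPSTH",
    "QCReport",
    "bin_spikes",
    "firing_rate",
    "grating_response_strength",
    "grating_map",
    "chirp_spectrum",
    "flash_psth",
    "flash_psth_from_rate",
    "qc_report",
]

BIN_WIDTH_S = 0.001
#: target frequency resolution of all Fourier analyses (Hz)
FT_RESOLUTION_HZ = 0.125
#: chirp analysis band (Hz): the nominal extent of the frequency ramp
CHIRP_BAND_HZ = (0.5, 8.0)
DEFAULT_KERNEL_SIGMA_S = 0.040


class Epoch(NamedTuple):
    stimulus_id: str
    onset: float  # s; windows are half-open [onset, offset)
    offset: float
    repeat: int


@dataclass
class SpikeTrain:
    """One unit's spike times with its stimulus-epoch alignment."""

    unit_id: str
    spike_times: np.ndarray  # s, sorted ascending
    recording_duration: float
    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def epochs_for(self, stimulus_id: str) -> list[Epoch]:
        eps = [e for e in self.epochs if e.stimulus_id == stimulus_id]
        return sorted(eps, key=lambda e: e.repeat)

    def stimulus_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.epochs:
            seen.setdefault(e.stimulus_id, None)
        return list(seen)

    def spikes_in(self, onset: float, offset: float) -> np.ndarray:
        i0, i1 = np.searchsorted(self.spike_times, [onset, offset])
        return self.spike_times[i0:i1] - onset


@dataclass
class BinnedResponse:
    """Per-trial binary vectors aligned to stimulus onset."""

    trials: np.ndarray  # (n_trials, n_bins), entries in {0, 1}
    bin_width: float = BIN_WIDTH_S

    @property
    def n_trials(self) -> int:
        return int(self.trials.shape[0])

    @property
    def duration(self) -> float:
        return self.trials.shape[1] * self.bin_width

    def trial_mean(self) -> np.ndarray:
        return self.trials.mean(axis=0)


@dataclass
class GratingResponseMap:
    """6x4 matrix of response strengths (periods ascending x freqs ascending)."""

    strengths: np.ndarray  # (6, 4), >= 0; invalid entries carry 0
    valid: np.ndarray  # (6, 4) bool
    periods: tuple[float, ...] = st.GRATING_PERIODS_UM
    freqs: tuple[float, ...] = st.GRATING_FREQS_HZ
    normalized: bool = False

    @property
    def responsive(self) -> bool:
        return bool(self.valid.any())

    def normalize(self) -> "GratingResponseMap":
        """Scale so the best valid response is 1; invalid entries stay 0."""
        out = np.where(self.valid, self.strengths, 0.0)
        peak = out.max()
        if self.responsive and peak > 0:
            out = out / peak
        return GratingResponseMap(strengths=out, valid=self.valid.copy(),
                                  periods=self.periods, freqs=self.freqs,
                                  normalized=True)

    def vector(self) -> np.ndarray:
        """Flattened 24-entry representation (row-major, periods x freqs)."""
        return np.where(self.valid, self.strengths, 0.0).ravel()

    def argmax_entry(self) -> tuple[float, float]:
        """(period, frequency) of the strongest valid entry.

        Ties break toward larger period / lower frequency.
        """
        m = np.where(self.valid, self.strengths, -1.0)
        best = m.max()
        rows, cols = np.nonzero(m == best)
        i = np.lexsort((-rows, cols))[0]  # lowest freq, then largest period
        return self.periods[rows[i]], self.freqs[cols[i]]


@dataclass
class ChirpSpectrum:
    """FFT-ratio tuning curve on the chirp analysis band."""

    freqs: np.ndarray  # Hz, 0.125 Hz spacing
    ratio: np.ndarray  # smoothed norm(FT_response)/FT_stimulus
    raw_ratio: np.ndarray  # before the 3-point moving average
    smoothing: str = "3-point (0.375 Hz) moving average"

    def band_median(self, lo: float, hi: float) -> float:
        m = (self.freqs >= lo) & (self.freqs < hi)
        if not m.any():
            raise ValueError(f"band [{lo}, {hi}) not covered by the spectrum")
        return float(np.median(self.ratio[m]))


@dataclass
class FlashPSTH:
    """Trial-averaged firing rate over one flash sequence."""

    time: np.ndarray
    rate: np.ndarray  # Hz
    spont_mean: float
    spont_sd: float
    # per transition: (time_s, sign, peak_rate, peak_time)
    transition_peaks: list[tuple[float, int, float, float]]
    sigma: float = DEFAULT_KERNEL_SIGMA_S

    @property
    def threshold(self) -> float:
        return self.spont_mean + 2.0 * self.spont_sd

    def peak_rate(self) -> float:
        return max((p for _, _, p, _ in self.transition_peaks), default=0.0)


@dataclass
class QCReport:
    refractory_violation_fraction: float
    block_peak_rates: list[float]
    block_spontaneous_rates: list[float]
    duplicate_pairs: list[tuple[str, str, float]]


# ---------------------------------------------------------------------------
# binning and rates
# ---------------------------------------------------------------------------

def bin_spikes(train: SpikeTrain, stimulus_id: str,
               bin_width: float = BIN_WIDTH_S) -> BinnedResponse:
    """Binary vectors (1 = at least one spike in the bin) per stimulus repeat."""
    eps = train.epochs_for(stimulus_id)
    if not eps:
        raise KeyError(f"stimulus {stimulus_id!r} not present in epochs of {train.unit_id}")
    duration = min(e.offset - e.onset for e in eps)
    n_bins = int(round(duration / bin_width))
    out = np.zeros((len(eps), n_bins), dtype=float)
    for i, e in enumerate(eps):
        rel = train.spikes_in(e.onset, e.onset + n_bins * bin_width)
        idx = np.minimum((rel / bin_width).astype(int), n_bins - 1)
        out[i, idx] = 1.0
    return BinnedResponse(trials=out, bin_width=bin_width)


def _gauss_kernel(sigma: float, dt: float) -> np.ndarray:
    radius = int(np.ceil(6 * sigma / dt))
    x = np.arange(-radius, radius + 1) * dt
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / (k.sum() * dt)  # unit area on the dt grid


def firing_rate(spike_times: np.ndarray, duration: float,
                sigma: float = DEFAULT_KERNEL_SIGMA_S,
                dt: float = BIN_WIDTH_S) -> np.ndarray:
    """Gaussian-kernel rate estimate on a 1 ms grid; integrates to the
    spike count (unit-area kernels)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n = int(round(duration / dt))
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float),
                             bins=n, range=(0.0, n * dt))
    return np.convolve(counts.astype(float), _gauss_kernel(sigma, dt), mode="same")


def trial_rate(train: SpikeTrain, stimulus_id: str,
               sigma: float = DEFAULT_KERNEL_SIGMA_S,
               dt: float = BIN_WIDTH_S) -> tuple[np.ndarray, np.ndarray]:
    """(trial-averaged rate trace, per-trial rate matrix) for one stimulus."""
    eps = train.epochs_for(stimulus_id)
    if not eps:
        raise KeyError(f"stimulus {stimulus_id!r} not present in epochs of {train.unit_id}")
    duration = min(e.offset - e.onset for e in eps)
    rates = np.stack([
        firing_rate(train.spikes_in(e.onset, e.onset + duration), duration, sigma, dt)
        for e in eps
    ])
    return rates.mean(axis=0), rates


# ---------------------------------------------------------------------------
# drifting-grating F1 analysis
# ---------------------------------------------------------------------------

def _padded_length(n: int, bin_width: float) -> int:
    """Smallest length reaching the 0.125 Hz resolution grid (zero-padding)."""
    block = int(round(1.0 / (FT_RESOLUTION_HZ * bin_width)))
    return int(np.ceil(n / block)) * block


def amplitude_spectrum(x: np.ndarray, bin_width: float = BIN_WIDTH_S
                       ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of ``x`` zero-padded to the 0.125 Hz grid.

    Amplitudes are scaled by 2/len(x) so a sinusoid of amplitude A in ``x``
    appears with height ~A at its frequency.
    """
    n = x.size
    n_pad = _padded_length(n, bin_width)
    amp = np.abs(np.fft.rfft(x, n_pad)) * 2.0 / n
    freqs = np.fft.rfftfreq(n_pad, bin_width)
    return freqs, amp


def _local_maxima(amp: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of the spectrum."""
    inner = (amp[1:-1] > amp[:-2]) & (amp[1:-1] > amp[2:])
    return np.nonzero(inner)[0] + 1


def grating_response_strength(binned: BinnedResponse, stim_freq: float
                              ) -> tuple[float, bool]:
    """F1 response strength and the peak-validity flag.

    Strength is the Fourier amplitude of the trial-mean binary vector at the
    stimulus frequency. The response is valid only if the spectrum has a
    local peak at the stimulus frequency (within one grid bin) and no higher
    local peak elsewhere, excluding DC (+-2 bins) and harmonics of the
    stimulus frequency (+-1 bin).
    """
    if binned.n_trials < 1:
        raise ValueError("need at least one trial")
    mean = binned.trial_mean()
    if mean.size * binned.bin_width < 1.0 / stim_freq:
        raise ValueError("trial shorter than one stimulus cycle")
    freqs, amp = amplitude_spectrum(mean, binned.bin_width)
    df = freqs[1] - freqs[0]
    idx0 = int(round(stim_freq / df))
    if idx0 >= amp.size or not np.isclose(idx0 * df, stim_freq, atol=df / 4):
        raise ValueError("stimulus frequency not resolvable on the FT grid")
    strength = float(amp[idx0])

    peaks = _local_maxima(amp)
    has_own_peak = np.any(np.abs(peaks - idx0) <= 1)
    n_harm = (amp.size - 1) // idx0 if idx0 > 0 else 0
    harmonics = np.arange(1, n_harm + 1) * idx0
    excluded = peaks <= 2  # DC region
    if harmonics.size:
        excluded |= (np.abs(peaks[:, None] - harmonics[None, :]) <= 1).any(axis=1)
    competing = peaks[~excluded]
    valid = bool(has_own_peak and strength > 0 and not np.any(amp[competing] > strength))
    return strength, valid


def grating_map(
    strengths_by_stim: dict[tuple[float, float], tuple[float, bool]],
    periods: Sequence[float] = st.GRATING_PERIODS_UM,
    freqs: Sequence[float] = st.GRATING_FREQS_HZ,
    normalize: bool = True,
) -> GratingResponseMap:
    """Assemble the 6x4 response map from per-stimulus (strength, valid)."""
    plist, flist = list(periods), list(freqs)
    s = np.zeros((len(plist), len(flist)))
    v = np.zeros((len(plist), len(flist)), dtype=bool)
    for (p, f), (strength, valid) in strengths_by_stim.items():
        i, j = plist.index(p), flist.index(f)
        s[i, j] = strength if valid else 0.0
        v[i, j] = valid
    m = GratingResponseMap(strengths=s, valid=v, periods=tuple(periods), freqs=tuple(freqs))
    return m.normalize() if normalize else m


# ---------------------------------------------------------------------------
# chirp FFT-ratio spectrum
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the available samples."""
    kernel = np.ones(window)
    return np.convolve(x, kernel, "same") / np.convolve(np.ones_like(x), kernel, "same")


def chirp_spectrum(binned: BinnedResponse, stimulus_trace: np.ndarray,
                   band: tuple[float, float] = CHIRP_BAND_HZ,
                   stimulus_floor: float = 1e-6) -> ChirpSpectrum:
    """norm(FT_response)/FT_stimulus on the chirp ramp band.

    Both amplitude spectra are max-normalized on the band so the ratio is
    dimensionless and O(1); the ratio is then smoothed with a centered
    3-point (0.375 Hz) moving average. Outside the ramp band the stimulus
    spectrum vanishes and the ratio is not computed.
    """
    mean = binned.trial_mean()
    if mean.size != stimulus_trace.size:
        raise ValueError("response and stimulus must be sampled on the same grid")
    freqs, amp_r = amplitude_spectrum(mean, binned.bin_width)
    _, amp_s = amplitude_spectrum(np.asarray(stimulus_trace, dtype=float), binned.bin_width)
    m = (freqs >= band[0]) & (freqs <= band[1])
    amp_s_band = amp_s[m]
    s_peak = amp_s_band.max()
    if s_peak <= 0 or np.any(amp_s_band < stimulus_floor * s_peak):
        raise ValueError("stimulus FT amplitude below floor on the analysis band")
    amp_r_band = amp_r[m]
    r_peak = amp_r_band.max()
    norm_r = amp_r_band / r_peak if r_peak > 0 else amp_r_band
    raw = norm_r / (amp_s_band / s_peak)
    return ChirpSpectrum(freqs=freqs[m], ratio=_moving_average(raw, 3), raw_ratio=raw)


# ---------------------------------------------------------------------------
# flash PSTH
# ---------------------------------------------------------------------------

def flash_psth(train: SpikeTrain, flash: st.FlashStimulus | None = None,
               stimulus_id: str = "flash",
               sigma: float = DEFAULT_KERNEL_SIGMA_S,
               spont_window: float | None = None,
               dt: float = BIN_WIDTH_S) -> FlashPSTH:
    """Trial-averaged flash response with spontaneous statistics.

    The spontaneous mean and SD are taken over the pooled per-trial rate
    samples in the grey window preceding the first contrast step (the SD of
    single-trial firing rates, not of the trial average), so the
    "mean + 2 SD" response criterion keeps a low false-positive rate under
    Poisson variability.
    """
    flash = flash or st.FlashStimulus()
    mean_rate, per_trial = trial_rate(train, stimulus_id, sigma=sigma, dt=dt)
    return flash_psth_from_rate(mean_rate, per_trial=per_trial, flash=flash,
                                sigma=sigma, spont_window=spont_window, dt=dt)


def flash_psth_from_rate(mean_rate: np.ndarray,
                         per_trial: np.ndarray | None = None,
                         flash: st.FlashStimulus | None = None,
                         sigma: float = DEFAULT_KERNEL_SIGMA_S,
                         spont_window: float | None = None,
                         dt: float = BIN_WIDTH_S) -> FlashPSTH:
    """Flash PSTH statistics from an existing rate trace.

    With ``per_trial`` rates the spontaneous SD is pooled over single-trial
    samples; for a deterministic (noise-free) trace it is the SD of the
    trace itself.
    """
    flash = flash or st.FlashStimulus()
    # the smoothing kernel bleeds each response ~3 sigma backward across the
    # preceding transition; trim that guard off the end of every window
    guard = int(round(3 * sigma / dt))
    spont_window = flash.step_duration if spont_window is None else spont_window
    n_spont = int(round(spont_window / dt)) - guard
    if n_spont < 1 or n_spont > mean_rate.size:
        raise ValueError("no pre-stimulus baseline window available")
    spont_samples = (per_trial if per_trial is not None else mean_rate[None, :])[:, :n_spont]
    spont_mean = float(spont_samples.mean())
    spont_sd = float(spont_samples.std())

    time = np.arange(mean_rate.size) * dt
    peaks = []
    for t_step, _, _, sign in flash.transitions():
        i0 = int(round(t_step / dt))
        i1 = min(int(round((t_step + flash.step_duration) / dt)) - guard,
                 mean_rate.size)
        if i1 <= i0:
            continue
        seg = mean_rate[i0:i1]
        # a decaying leading edge that continues the previous window's trace
        # downward is the smoothed tail of the previous transition's
        # response, not a response to this one; a genuine response enters
        # the window rising (the kernel spreads its onset backward across
        # the transition) or as a fresh jump above the pre-transition level.
        j = 0
        if i0 > 0 and seg[0] <= mean_rate[i0 - 1]:
            rises = np.nonzero(np.diff(seg) > 0)[0]
            j = int(rises[0]) if rises.size else seg.size - 1
        k = j + int(np.argmax(seg[j:]))
        peaks.append((t_step, sign, float(seg[k]), float(time[i0 + k])))
    return FlashPSTH(time=time, rate=mean_rate, spont_mean=spont_mean,
                     spont_sd=spont_sd, transition_peaks=peaks, sigma=sigma)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def refractory_violation_fraction(spike_times: np.ndarray,
                                  refractory: float = 0.0015) -> float:
    """Fraction of inter-spike intervals at or below the refractory bound."""
    if spike_times.size < 2:
        return 0.0
    isi = np.diff(spike_times)
    return float(np.mean(isi <= refractory))


def coincidence_fraction(a: np.ndarray, b: np.ndarray,
                         window: float = 0.001) -> float:
    """Fraction of the smaller train's spikes with a partner within +-window."""
    if a.size == 0 or b.size == 0:
        return 0.0
    small, big = (a, b) if a.size <= b.size else (b, a)
    idx = np.searchsorted(big, small)
    near = np.full(small.shape, np.inf)
    left = idx > 0
    near[left] = np.abs(small[left] - big[idx[left] - 1])
    right = idx < big.size
    near[right] = np.minimum(near[right], np.abs(small[right] - big[idx[right]]))
    return float(np.mean(near <= window))


def qc_report(train: SpikeTrain, all_trains: Sequence[SpikeTrain] = (),
              flash_id: str = "flash", block_size: int = 5,
              duplicate_threshold: float = 0.3,
              coincidence_window: float = 0.001,
              refractory: float = 0.0015,
              sigma: float = DEFAULT_KERNEL_SIGMA_S) -> QCReport:
    """Refractory, stability-over-blocks and duplicate-unit checks."""
    frac = refractory_violation_fraction(train.spike_times, refractory)

    block_peaks: list[float] = []
    block_spont: list[float] = []
    eps = train.epochs_for(flash_id) if any(
        e.stimulus_id == flash_id for e in train.epochs) else []
    flash = st.FlashStimulus()
    for start in range(0, len(eps) - block_size + 1, block_size):
        block = eps[start:start + block_size]
        duration = min(e.offset - e.onset for e in block)
        rates = np.stack([
            firing_rate(train.spikes_in(e.onset, e.onset + duration), duration, sigma)
            for e in block
        ])
        mean = rates.mean(axis=0)
        n_spont = int(round(flash.step_duration / BIN_WIDTH_S))
        block_spont.append(float(mean[:n_spont].mean()))
        block_peaks.append(float(mean[n_spont:].max(initial=0.0)))

    duplicates: list[tuple[str, str, float]] = []
    for other in all_trains:
        if other.unit_id == train.unit_id:
            continue
        f = coincidence_fraction(train.spike_times, other.spike_times, coincidence_window)
        if f > duplicate_threshold:
            duplicates.append((train.unit_id, other.unit_id, f))
    return QCReport(refractory_violation_fraction=frac,
                    block_peak_rates=block_peaks,
                    block_spontaneous_rates=block_spont,
                    duplicate_pairs=duplicates)


def drop_duplicates(trains: Sequence[SpikeTrain],
                    duplicate_threshold: float = 0.3,
                    coincidence_window: float = 0.001) -> list[SpikeTrain]:
    """Keep the unit with more spikes from each duplicate pair."""
    keep = list(trains)
    dropped: set[str] = set()
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            a, b = keep[i], keep[j]
            if a.unit_id in dropped or b.unit_id in dropped:
                continue
            f = coincidence_fraction(a.spike_times, b.spike_times, coincidence_window)
            if f > duplicate_threshold:
                dropped.add(b.unit_id if a.n_spikes >= b.n_spikes else a.unit_id)
    return [t for t in keep if t.unit_id not in dropped]
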