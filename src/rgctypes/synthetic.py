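"""Synthetic retinal ganglion cell populations.

Spike trains are generated by a linear-nonlinear-Poisson style cascade:
the full-field luminance drive is high-pass filtered with a kinetic time
constant (small tau -> transient, large tau -> sustained), half-wave
rectified according to the cell's polarity, scaled by separable Gaussian
tuning on log2 spatial/temporal axes and by Naka-Rushton contrast
saturation, and converted to spikes by inhomogeneous-Poisson thinning with
a 1.5 ms dead time.

The archetypes mirror the qualitative functional families the typing
pipeline is built to separate: transient and sustained ON/OFF cells
(putative parasol/midget-like), a transient ON-OFF cell, low-temporal-
frequency full-field responders, and grating-only cells with narrow
spatio-temporal tuning that ignore full-field stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import stimuli as st
from .metrics import Epoch, SpikeTrain

__all__ = [
    "SyntheticCellSpec",
    "GroundTruthLabel",
    "ClusterTemplate",
    "PopulationConfig",
    "DOMINANT_FIVE",
    "make_archetypes",
    "simulate_rate",
    "generate_spikes",
    "generate_population",
    "make_templates",
]

#: default receptive-field span (um) used to pad moving-bar passage times
DEFAULT_RF_SPAN_UM = 300.0

#: dead time enforced between spikes (s); matches the sorting QC bound
DEFAULT_REFRACTORY_S = 0.0015


@dataclass
class SyntheticCellSpec:
    """Parameters of one archetype; tuning centers live on log2 axes."""

    label: str
    polarity: str  # "ON" | "OFF" | "ON-OFF" | "none"
    kinetic_tau: float  # s; decay of the step response
    tf_center: float  # log2 Hz
    tf_sigma: float  # log2 Hz
    sf_center: float  # log2 um (spatial period)
    sf_sigma: float  # log2 um
    contrast_c50: float  # half-saturation contrast in (0, 1]
    baseline_rate: float  # Hz
    max_rate: float  # Hz
    speed_center: Optional[float] = None  # log2 mm/s
    speed_sigma: Optional[float] = None
    responds_to_fullfield: bool = True
    true_cluster: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.max_rate <= self.baseline_rate:
            raise ValueError("max_rate must exceed baseline_rate")
        if self.tf_sigma <= 0 or self.sf_sigma <= 0:
            raise ValueError("tuning sigmas must be positive")
        if not (0 < self.contrast_c50 <= 1):
            raise ValueError("contrast_c50 must be in (0, 1]")
        if self.polarity not in ("ON", "OFF", "ON-OFF", "none"):
            raise ValueError(f"unknown polarity: {self.polarity!r}")


@dataclass(frozen=True)
class GroundTruthLabel:
    unit_id: str
    archetype: str
    true_cluster: int


@dataclass
class ClusterTemplate:
    """Normalized flash+chirp response trace on a fixed 10 ms time base."""

    name: str
    values: np.ndarray  # normalized to max 1
    dt: float  # s per sample
    flash_samples: int  # boundary between the flash and chirp segments

    @property
    def chirp_values(self) -> np.ndarray:
        return self.values[self.flash_samples:]

    @property
    def flash_values(self) -> np.ndarray:
        return self.values[: self.flash_samples]


# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------

def _log2(x: float) -> float:
    return math.log2(x)


DOMINANT_FIVE = (
    "transient_on",
    "transient_off",
    "sustained_on",
    "sustained_off",
    "on_off_transient",
)


def make_archetypes() -> list[SyntheticCellSpec]:
    """Ten archetypes: the five dominant full-field types, two low-TF
    full-field responders, and three grating-only cells with narrow tuning."""
    a = [
        SyntheticCellSpec(
            label="transient_on", polarity="ON", kinetic_tau=0.08,
            tf_center=_log2(6.0), tf_sigma=1.2, sf_center=_log2(2000.0), sf_sigma=1.6,
            contrast_c50=0.15, baseline_rate=3.0, max_rate=80.0,
            speed_center=_log2(8.0), speed_sigma=1.0, true_cluster=1,
        ),
        SyntheticCellSpec(
            label="transient_off", polarity="OFF", kinetic_tau=0.08,
            tf_center=_log2(6.0), tf_sigma=1.2, sf_center=_log2(2000.0), sf_sigma=1.6,
            contrast_c50=0.15, baseline_rate=3.0, max_rate=80.0,
            speed_center=_log2(8.0), speed_sigma=1.0, true_cluster=2,
        ),
        SyntheticCellSpec(
            label="sustained_on", polarity="ON", kinetic_tau=4.0,
            tf_center=_log2(2.0), tf_sigma=3.0, sf_center=_log2(1000.0), sf_sigma=1.6,
            contrast_c50=0.5, baseline_rate=3.0, max_rate=50.0,
            speed_center=_log2(2.0), speed_sigma=1.0, true_cluster=3,
        ),
        SyntheticCellSpec(
            label="sustained_off", polarity="OFF", kinetic_tau=4.0,
            tf_center=_log2(2.0), tf_sigma=3.0, sf_center=_log2(1000.0), sf_sigma=1.6,
            contrast_c50=0.5, baseline_rate=3.0, max_rate=50.0,
            speed_center=_log2(2.0), speed_sigma=1.0, true_cluster=4,
        ),
        SyntheticCellSpec(
            label="on_off_transient", polarity="ON-OFF", kinetic_tau=0.1,
            tf_center=_log2(6.0), tf_sigma=1.2, sf_center=_log2(1000.0), sf_sigma=1.6,
            contrast_c50=0.3, baseline_rate=3.0, max_rate=70.0,
            speed_center=_log2(4.0), speed_sigma=1.0, true_cluster=5,
        ),
        SyntheticCellSpec(
            label="lowtf_on", polarity="ON", kinetic_tau=0.3,
            tf_center=_log2(1.5), tf_sigma=0.8, sf_center=_log2(2000.0), sf_sigma=1.2,
            contrast_c50=0.4, baseline_rate=4.0, max_rate=55.0,
            speed_center=_log2(2.0), speed_sigma=1.0, true_cluster=6,
        ),
        SyntheticCellSpec(
            label="lowtf_off", polarity="OFF", kinetic_tau=0.3,
            tf_center=_log2(1.5), tf_sigma=0.8, sf_center=_log2(2000.0), sf_sigma=1.2,
            contrast_c50=0.4, baseline_rate=4.0, max_rate=55.0,
            speed_center=_log2(2.0), speed_sigma=1.0, true_cluster=7,
        ),
        SyntheticCellSpec(
            label="grating_only_fast_fine", polarity="none", kinetic_tau=0.1,
            tf_center=_log2(8.0), tf_sigma=0.5, sf_center=_log2(500.0), sf_sigma=0.5,
            contrast_c50=0.3, baseline_rate=1.5, max_rate=60.0,
            responds_to_fullfield=False, true_cluster=9,
        ),
        SyntheticCellSpec(
            label="grating_only_slow_coarse", polarity="none", kinetic_tau=0.1,
            tf_center=_log2(1.0), tf_sigma=0.5, sf_center=_log2(2000.0), sf_sigma=0.5,
            contrast_c50=0.3, baseline_rate=1.5, max_rate=60.0,
            responds_to_fullfield=False, true_cluster=10,
        ),
        SyntheticCellSpec(
            label="grating_only_mid_wide", polarity="none", kinetic_tau=0.1,
            tf_center=_log2(4.0), tf_sigma=0.5, sf_center=_log2(4000.0), sf_sigma=0.5,
            contrast_c50=0.3, baseline_rate=1.5, max_rate=60.0,
            responds_to_fullfield=False, true_cluster=11,
        ),
    ]
    return a


# ---------------------------------------------------------------------------
# rate model
# ---------------------------------------------------------------------------

def _gauss_gain(x_log2: float, center: float, sigma: float) -> float:
    return math.exp(-0.5 * ((x_log2 - center) / sigma) ** 2)


def _naka_rushton(contrast: float, c50: float) -> float:
    return contrast / (contrast + c50)


def _rectify(y: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "ON":
        return np.maximum(y, 0.0)
    if polarity == "OFF":
        return np.maximum(-y, 0.0)
    if polarity == "ON-OFF":
        return np.abs(y)
    # "none": grating-only cells; local (grating/bar) drive is half-rectified
    return np.maximum(y, 0.0)


def _highpass(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """x minus a first-order low-pass of x: a step becomes exp(-t/tau).

    The filter is seeded at the initial level so a pre-stimulus grey screen
    produces zero drive.
    """
    from scipy.signal import lfilter

    alpha = dt / (tau + dt)
    low, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=[(1.0 - alpha) * x[0]])
    return x - low


def simulate_rate(cell: SyntheticCellSpec, stimulus, dt: float = 0.001,
                  rf_span_um: float = DEFAULT_RF_SPAN_UM) -> np.ndarray:
    """Firing-rate trace (Hz) of ``cell`` for one stimulus presentation."""
    if dt > 0.002:
        raise ValueError("dt must be <= 2 ms")
    base, peak = cell.baseline_rate, cell.max_rate
    amp = peak - base

    if isinstance(stimulus, st.GratingStimulus):
        g = (
            _gauss_gain(_log2(stimulus.spatial_period), cell.sf_center, cell.sf_sigma)
            * _gauss_gain(_log2(stimulus.temporal_frequency), cell.tf_center, cell.tf_sigma)
            * _naka_rushton(stimulus.contrast, cell.contrast_c50)
        )
        t = np.arange(0.0, stimulus.duration, dt)
        carrier = np.sin(2 * np.pi * stimulus.temporal_frequency * t)
        # gratings drive all polarities through a half-rectified F1 carrier:
        # the analysis reads only the F1 amplitude, and a full-wave |sin|
        # would put an ON-OFF cell's energy entirely into the F2 harmonic
        rate = base + amp * g * np.maximum(carrier, 0.0)

    elif isinstance(stimulus, st.ChirpStimulus):
        t = np.arange(0.0, stimulus.total_duration, dt)
        if not cell.responds_to_fullfield:
            return np.full(t.shape, base)
        x = (stimulus.intensity(t) - st.GREY) / (st.WHITE - st.GREY)
        if stimulus.kind == "frequency_ramp":
            f_inst = st.chirp_instantaneous_frequency(np.clip(t - stimulus.pre_grey, 0, None))
            gain = np.exp(-0.5 * ((np.log2(f_inst) - cell.tf_center) / cell.tf_sigma) ** 2)
            gain *= _naka_rushton(1.0, cell.contrast_c50)
        else:
            c = np.clip((t - stimulus.pre_grey) / stimulus.duration, 0.0, 1.0)
            gain = c / (c + cell.contrast_c50)
            gain *= _gauss_gain(_log2(stimulus.carrier_hz), cell.tf_center, cell.tf_sigma)
        rate = base + amp * gain * _rectify(x, cell.polarity)

    elif isinstance(stimulus, st.FlashStimulus):
        trace = stimulus.trace(sample_rate=1.0 / dt)
        if not cell.responds_to_fullfield:
            return np.full(trace.shape, base)
        x = (trace - st.GREY) / (st.WHITE - st.GREY)
        y = _highpass(x, cell.kinetic_tau, dt)
        rate = base + amp * _naka_rushton(1.0, cell.contrast_c50) * _rectify(y, cell.polarity)

    elif isinstance(stimulus, st.BarStimulus):
        segs = stimulus.segments(rf_span_um)
        duration = segs[-1][2] + stimulus.inter_speed_gap
        t = np.arange(0.0, duration, dt)
        rate = np.full(t.shape, base)
        if cell.speed_center is not None:
            for speed, on, off in segs:
                g = _gauss_gain(_log2(speed), cell.speed_center, cell.speed_sigma)
                rate[(t >= on) & (t < off)] = base + amp * g * _naka_rushton(1.0, cell.contrast_c50)
    else:
        raise TypeError(f"unknown stimulus class: {type(stimulus).__name__}")

    return np.clip(rate, 0.0, peak)


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

def _dead_time(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedy keep-first enforcement of an absolute dead time."""
    if times.size < 2:
        return times
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last > refractory:
            kept.append(t)
            last = t
    return np.asarray(kept)


def generate_spikes(rate: np.ndarray, dt: float, n_trials: int,
                    refractory: float = DEFAULT_REFRACTORY_S,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spikes by thinning, one array per trial.

    Candidate spikes are drawn homogeneously at the peak rate, accepted with
    probability rate(t)/peak, then pruned to enforce the dead time.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    duration = rate.size * dt
    rmax = float(rate.max(initial=0.0))
    trials: list[np.ndarray] = []
    for _ in range(n_trials):
        if rmax <= 0:
            trials.append(np.empty(0))
            continue
        n_cand = rng.poisson(rmax * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        idx = np.minimum((cand / dt).astype(int), rate.size - 1)
        accept = rng.uniform(size=n_cand) < rate[idx] / rmax
        trials.append(_dead_time(cand[accept], refractory))
    return trials


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Study conditions for a synthetic population.

    Repeat counts are the package defaults (the source protocol does not
    print them): 3 repeats per grating, 5 chirp repeats of each kind,
    5 flash sequences, 1 bar sweep per speed and polarity. ``noise`` scales
    per-cell parameter jitter: tuning centers receive additive Gaussian
    jitter of ``0.5 * noise`` octaves, gains and time constants multiplicative
    log-normal jitter of sigma ``0.3 * noise``.
    """

    cells_per_archetype: int = 10
    noise: float = 0.3
    grating_repeats: int = 3
    chirp_repeats: int = 5
    flash_repeats: int = 10
    include_gratings: bool = True
    include_chirp: bool = True
    include_contrast_ramp: bool = True
    include_flash: bool = True
    include_bars: bool = True
    grating_duration: float = 12.0
    inter_epoch_gap: float = 0.5
    dt: float = 0.001


def _jitter_cell(cell: SyntheticCellSpec, noise: float,
                 rng: np.random.Generator) -> SyntheticCellSpec:
    if noise <= 0:
        return replace(cell)
    add = lambda v: v + rng.normal(0.0, 0.5 * noise)
    mul = lambda v: v * math.exp(rng.normal(0.0, 0.3 * noise))
    out = replace(
        cell,
        tf_center=add(cell.tf_center),
        sf_center=add(cell.sf_center),
        kinetic_tau=mul(cell.kinetic_tau),
        baseline_rate=mul(cell.baseline_rate),
        max_rate=max(mul(cell.max_rate), mul(cell.baseline_rate) + 1.0),
        contrast_c50=min(1.0, mul(cell.contrast_c50)),
    )
    if out.speed_center is not None:
        out.speed_center = add(out.speed_center)
    return out


def _protocol_stimuli(config: PopulationConfig):
    """Yield (stimulus, stimulus_id getter, n_repeats) in protocol order."""
    items: list[tuple[object, int]] = []
    if config.include_gratings:
        for g in st.grating_set(duration=config.grating_duration):
            items.append((g, config.grating_repeats))
    if config.include_chirp:
        items.append((st.ChirpStimulus(kind="frequency_ramp"), config.chirp_repeats))
    if config.include_contrast_ramp:
        items.append((st.ChirpStimulus(kind="contrast_ramp", pre_grey=2.0), config.chirp_repeats))
    if config.include_flash:
        items.append((st.FlashStimulus(), config.flash_repeats))
    if config.include_bars:
        items.append((st.BarStimulus(polarity="black"), 1))
        items.append((st.BarStimulus(polarity="white"), 1))
    return items


def generate_population(
    config: PopulationConfig | None = None,
    archetypes: Sequence[SyntheticCellSpec] | None = None,
    seed: int = 0,
) -> tuple[list[SpikeTrain], list[GroundTruthLabel]]:
    """Simulate a full population through the five-stimulus protocol."""
    config = config or PopulationConfig()
    archetypes = list(archetypes) if archetypes is not None else make_archetypes()
    if config.cells_per_archetype < 1:
        raise ValueError("need at least one cell per archetype")

    ss = np.random.SeedSequence(seed)
    trains: list[SpikeTrain] = []
    labels: list[GroundTruthLabel] = []
    items = _protocol_stimuli(config)
    unit_idx = 0
    for arch in archetypes:
        for child in ss.spawn(config.cells_per_archetype):
            rng = np.random.default_rng(child)
            cell = _jitter_cell(arch, config.noise, rng)
            unit_id = f"u{unit_idx:04d}"
            unit_idx += 1

            spike_blocks: list[np.ndarray] = []
            epochs: list[Epoch] = []
            t0 = 0.0
            for stimulus, n_rep in items:
                rate = simulate_rate(cell, stimulus, dt=config.dt)
                duration = rate.size * config.dt
                trials = generate_spikes(rate, config.dt, n_rep, rng=rng)
                for rep, spikes in enumerate(trials):
                    spike_blocks.append(spikes + t0)
                    if isinstance(stimulus, st.BarStimulus):
                        for speed, on, off in stimulus.segments(DEFAULT_RF_SPAN_UM):
                            epochs.append(Epoch(stimulus.stimulus_id(speed),
                                                t0 + on, t0 + min(off + 1.0, duration), rep))
                    else:
                        epochs.append(Epoch(stimulus.stimulus_id, t0, t0 + duration, rep))
                    t0 += duration + config.inter_epoch_gap

            times = np.concatenate(spike_blocks) if spike_blocks else np.empty(0)
            trains.append(SpikeTrain(unit_id=unit_id, spike_times=times,
                                     recording_duration=t0, epochs=epochs))
            labels.append(GroundTruthLabel(unit_id, cell.label, arch.true_cluster))
    return trains, labels


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def make_templates(archetypes: Sequence[SyntheticCellSpec] | None = None,
                   dt: float = 0.01) -> list[ClusterTemplate]:
    """Noiseless flash+chirp rate templates of the five dominant archetypes.

    These are synthetic stand-ins for cluster templates obtained from
    external recordings; user-supplied templates can replace them through
    :func:`rgctypes.io.read_templates`.
    """
    archetypes = list(archetypes) if archetypes is not None else make_archetypes()
    by_label = {a.label: a for a in archetypes}
    missing = [n for n in DOMINANT_FIVE if n not in by_label]
    if missing:
        raise ValueError(f"missing dominant archetypes: {missing}")

    sim_dt = 0.001
    stride = int(round(dt / sim_dt))
    templates = []
    for name in DOMINANT_FIVE:
        cell = by_label[name]
        flash = simulate_rate(cell, st.FlashStimulus(), dt=sim_dt)
        chirp = simulate_rate(cell, st.ChirpStimulus(kind="frequency_ramp"), dt=sim_dt)
        flash_ds = flash[: flash.size // stride * stride].reshape(-1, stride).mean(axis=1)
        chirp_ds = chirp[: chirp.size // stride * stride].reshape(-1, stride).mean(axis=1)
        values = np.concatenate([flash_ds, chirp_ds])
        peak = values.max()
        if peak > 0:
            values = values / peak
        templates.append(ClusterTemplate(name=name, values=values, dt=dt,
                                         flash_samples=flash_ds.size))
    return templates
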