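"""Light-stimulus definitions and retina/visual-angle unit conversions.

Five stimulus classes are used throughout the pipeline:

* drifting sinusoidal gratings on a 6 spatial-period x 4 temporal-frequency
  grid (24 stimuli, full contrast, 12 s each),
* a full-field "chirp" frequency ramp with intensity
  ``128 + 128*sin(pi*(t**2 + t/10))``,
* a full-field contrast ramp (2 Hz carrier, amplitude growing 0 -> 128 over
  8 s),
* single bars moving at 1, 2, 4, 8, 16 mm/s,
* full-field contrast steps grey -> black -> grey -> white -> grey (2 s per
  step).

Display units are linear in luminance (the projector was linearized), so
contrast arithmetic is done directly in display units: grey = 128,
black = 0, white = 255. Retinal distances convert to visual angle with
266 um per degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GRATING_PERIODS_UM",
    "GRATING_FREQS_HZ",
    "UM_PER_DEGREE",
    "GREY",
    "BLACK",
    "WHITE",
    "GratingStimulus",
    "ChirpStimulus",
    "BarStimulus",
    "FlashStimulus",
    "StimulusProgram",
    "grating_set",
    "grating_id",
    "chirp_phase",
    "chirp_intensity",
    "chirp_instantaneous_frequency",
    "chirp_ramp_end_time",
    "um_to_cyc_per_deg",
    "retinal_speed_to_deg_per_s",
    "weber_contrast",
]

GRATING_PERIODS_UM: tuple[float, ...] = (100.0, 200.0, 500.0, 1000.0, 2000.0, 4000.0)
GRATING_FREQS_HZ: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)

#: conversion factor between retinal distance and visual angle
UM_PER_DEGREE: float = 266.0

GREY: float = 128.0
BLACK: float = 0.0
WHITE: float = 255.0

#: default stimulus/response sampling rate (Hz); matches the 1 ms response bins
DEFAULT_SAMPLE_RATE: float = 1000.0


# ---------------------------------------------------------------------------
# stimulus dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GratingStimulus:
    """One drifting sinusoidal grating (single fixed direction)."""

    spatial_period: float  # um on the retina
    temporal_frequency: float  # Hz
    duration: float = 12.0  # s
    contrast: float = 1.0  # fraction of the full display range

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("grating duration must be positive")
        if self.spatial_period <= 0 or self.temporal_frequency <= 0:
            raise ValueError("grating period and frequency must be positive")

    @property
    def stimulus_id(self) -> str:
        return grating_id(self.spatial_period, self.temporal_frequency)


def grating_id(period_um: float, freq_hz: float) -> str:
    return f"grating_p{period_um:g}_f{freq_hz:g}"


@dataclass(frozen=True)
class ChirpStimulus:
    """Full-field chirp: frequency ramp or contrast ramp.

    The contrast ramp carries a ``pre_grey`` lead-in (grey screen) used by the
    analysis as the local background window for the contrast preference index.
    """

    kind: str = "frequency_ramp"  # or "contrast_ramp"
    duration: float = 8.0  # s of ramp
    mean_level: float = GREY
    amplitude: float = 128.0
    carrier_hz: float = 2.0  # contrast ramp only
    pre_grey: float = 0.0  # s of grey before the ramp
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.kind not in ("frequency_ramp", "contrast_ramp"):
            raise ValueError(f"unknown chirp kind: {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("chirp duration must be positive")

    @property
    def total_duration(self) -> float:
        return self.pre_grey + self.duration

    @property
    def stimulus_id(self) -> str:
        return "chirp_freq" if self.kind == "frequency_ramp" else "chirp_contrast"

    def intensity(self, t: np.ndarray | float) -> np.ndarray:
        """Display intensity at time ``t`` (s, measured from epoch onset)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        ramp_t = np.clip(t - self.pre_grey, 0.0, self.duration)
        if self.kind == "frequency_ramp":
            out = self.mean_level + self.amplitude * np.sin(chirp_phase(ramp_t))
        else:
            amp = self.amplitude * ramp_t / self.duration
            out = self.mean_level + amp * np.sin(2 * np.pi * self.carrier_hz * ramp_t)
        out = np.where(t - self.pre_grey < 0, self.mean_level, out)
        out = np.where(t - self.pre_grey > self.duration, self.mean_level, out)
        return out

    def trace(self) -> np.ndarray:
        dt = 1.0 / self.sample_rate
        t = np.arange(0.0, self.total_duration, dt)
        return self.intensity(t)


@dataclass(frozen=True)
class BarStimulus:
    """Single bar sweeping at several speeds with grey gaps in between."""

    bar_extent: float = 1000.0  # um along the motion direction
    polarity: str = "black"  # "black" or "white"
    speeds: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)  # mm/s
    inter_speed_gap: float = 3.0  # s
    background: float = GREY

    def __post_init__(self) -> None:
        if self.bar_extent <= 0:
            raise ValueError("bar extent must be positive")
        if any(b >= a for a, b in zip(self.speeds[1:], self.speeds)):
            raise ValueError("bar speeds must be strictly increasing")
        if self.polarity not in ("black", "white"):
            raise ValueError(f"unknown bar polarity: {self.polarity!r}")

    def sweep_duration(self, speed_mm_s: float, rf_span_um: float = 0.0) -> float:
        """Time (s) the bar takes to cross a point, optionally padded by a
        receptive-field span (a simulator parameter, not a stimulus one)."""
        return (self.bar_extent + rf_span_um) / (1000.0 * speed_mm_s)

    def segments(self, rf_span_um: float = 0.0) -> list[tuple[float, float, float]]:
        """Return (speed, onset, offset) per sweep, gaps included."""
        out = []
        t = 0.0
        for speed in self.speeds:
            d = self.sweep_duration(speed, rf_span_um)
            out.append((speed, t, t + d))
            t += d + self.inter_speed_gap
        return out

    def stimulus_id(self, speed_mm_s: float) -> str:
        return f"bar_{self.polarity}_s{speed_mm_s:g}"


@dataclass(frozen=True)
class FlashStimulus:
    """Full-field contrast steps grey -> black -> grey -> white -> grey."""

    sequence: tuple[float, ...] = (GREY, BLACK, GREY, WHITE, GREY)
    step_duration: float = 2.0  # s

    def __post_init__(self) -> None:
        if self.sequence[0] != self.sequence[-1]:
            raise ValueError("flash sequence must start and end at the same grey level")
        signs = [np.sign(b - a) for a, b in zip(self.sequence, self.sequence[1:])]
        if signs.count(1) != 2 or signs.count(-1) != 2:
            raise ValueError("flash sequence must have two positive and two negative transitions")

    @property
    def stimulus_id(self) -> str:
        return "flash"

    @property
    def duration(self) -> float:
        return self.step_duration * len(self.sequence)

    def transitions(self) -> list[tuple[float, float, float, int]]:
        """Return (time, from_level, to_level, sign) for each step transition."""
        out = []
        for i, (a, b) in enumerate(zip(self.sequence, self.sequence[1:])):
            out.append(((i + 1) * self.step_duration, a, b, int(np.sign(b - a))))
        return out

    def trace(self, sample_rate: float = DEFAULT_SAMPLE_RATE) -> np.ndarray:
        n_step = int(round(self.step_duration * sample_rate))
        return np.repeat(np.asarray(self.sequence, dtype=float), n_step)


@dataclass
class StimulusProgram:
    """Ordered, non-overlapping presentation schedule of stimuli."""

    entries: list[dict] = field(default_factory=list)  # {stimulus, onset_s, repeats}
    conversion_factor: float = UM_PER_DEGREE

    def add(self, stimulus, onset_s: float, repeats: int = 1) -> None:
        self.entries.append({"stimulus": stimulus, "onset_s": float(onset_s), "repeats": int(repeats)})

    def to_dict(self) -> dict:
        ser = []
        for e in self.entries:
            stim = e["stimulus"]
            ser.append(
                {
                    "type": type(stim).__name__,
                    "parameters": asdict(stim),
                    "onset_s": e["onset_s"],
                    "repeats": e["repeats"],
                }
            )
        return {"conversion_factor": self.conversion_factor, "entries": ser}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProgram":
        types = {c.__name__: c for c in (GratingStimulus, ChirpStimulus, BarStimulus, FlashStimulus)}
        prog = cls(conversion_factor=d.get("conversion_factor", UM_PER_DEGREE))
        for e in d["entries"]:
            params = dict(e["parameters"])
            for key in ("sequence", "speeds"):
                if key in params and isinstance(params[key], list):
                    params[key] = tuple(params[key])
            stim = types[e["type"]](**params)
            prog.add(stim, e["onset_s"], e["repeats"])
        return prog


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def grating_set(
    periods: Sequence[float] = GRATING_PERIODS_UM,
    freqs: Sequence[float] = GRATING_FREQS_HZ,
    duration: float = 12.0,
) -> list[GratingStimulus]:
    """The 24-stimulus grid: Cartesian product of periods and frequencies."""
    return [
        GratingStimulus(spatial_period=p, temporal_frequency=f, duration=duration)
        for p in periods
        for f in freqs
    ]


def chirp_phase(t: np.ndarray | float) -> np.ndarray:
    """Phase pi*(t**2 + t/10) of the frequency-ramp chirp, t in seconds."""
    t = np.asarray(t, dtype=float)
    return np.pi * (t**2 + t / 10.0)


def chirp_intensity(t: np.ndarray | float, kind: str = "frequency_ramp") -> np.ndarray:
    """Chirp display intensity at time ``t`` (s); rejects negative times."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    return ChirpStimulus(kind=kind).intensity(t_arr)


def chirp_instantaneous_frequency(t: np.ndarray | float) -> np.ndarray:
    """Instantaneous frequency of the chirp: d/dt[phase]/(2 pi) = t + 0.05 Hz.

    Note this is 0.05 Hz at onset; the nominal ramp is described as starting
    at 0.5 Hz, a discrepancy the package keeps as specified by the formula.
    """
    t = np.asarray(t, dtype=float)
    return t + 0.05


def chirp_ramp_end_time(f_end_hz: float = 8.0) -> float:
    """Time at which the instantaneous chirp frequency reaches ``f_end_hz``."""
    if f_end_hz <= chirp_instantaneous_frequency(0.0):
        raise ValueError("end frequency below the onset frequency")
    return float(
        brentq(lambda t: float(chirp_instantaneous_frequency(t)) - f_end_hz, 0.0, 100.0)
    )


def um_to_cyc_per_deg(period_um: float, factor: float = UM_PER_DEGREE) -> float:
    """Spatial period on the retina (um) -> spatial frequency in cyc/deg."""
    if period_um <= 0 or factor <= 0:
        raise ValueError("period and conversion factor must be positive")
    return factor / period_um


def retinal_speed_to_deg_per_s(speed_mm_s: float, factor: float = UM_PER_DEGREE) -> float:
    """Retinal speed (mm/s) -> visual-field speed (deg/s)."""
    if speed_mm_s <= 0 or factor <= 0:
        raise ValueError("speed and conversion factor must be positive")
    return 1000.0 * speed_mm_s / factor


def weber_contrast(level: float, background: float = GREY) -> float:
    """Weber contrast (L - L_bg)/L_bg of a luminance step in display units."""
    if background == 0:
        raise ValueError("background must be non-zero")
    return (level - background) / background
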