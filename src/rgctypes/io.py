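"""File formats and run configuration.

Formats (all plain text):

* spikes CSV: ``unit_id, spike_time_s`` (seconds, microsecond precision),
* epochs CSV: ``unit_id, stimulus_id, onset_s, offset_s, repeat`` with
  0-based repeats and half-open windows [onset, offset),
* combined JSON: one object per unit with times, duration and epochs,
* labels CSV: ``unit_id, archetype, true_cluster``,
* profile CSV: one row per unit, one column per derived metric,
* grating-map tidy CSV: ``unit_id, period_um, frequency_hz, strength, valid``,
* assignments CSV: ``unit_id, cluster, step, similarity, note``,
* template CSVs (``time_s, value``) plus a JSON manifest,
* run configuration as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterAssignment
from .indices import CellProfile
from .metrics import Epoch, SpikeTrain
from .synthetic import ClusterTemplate, GroundTruthLabel

__all__ = [
    "SchemaError",
    "UnsortedSpikesError",
    "OverlappingEpochsError",
    "RunConfig",
    "write_spike_trains",
    "read_spike_trains",
    "write_spike_trains_json",
    "read_spike_trains_json",
    "write_labels",
    "read_labels",
    "write_templates",
    "read_templates",
    "profiles_to_frame",
    "maps_to_frame",
    "assignments_to_frame",
]

TIME_FORMAT = "%.6f"  # microsecond precision


class SchemaError(ValueError):
    pass


class UnsortedSpikesError(SchemaError):
    pass


class OverlappingEpochsError(SchemaError):
    pass


@dataclass
class RunConfig:
    """Serializable knobs of a full pipeline run."""

    seed: int = 0
    kernel_sigma_s: float = 0.040
    spont_window_s: float = 2.0
    chirp_band_hz: tuple[float, float] = (0.5, 8.0)
    step1_transiency_ms: float = 400.0
    step1_sustained_margin: float = 0.2
    k_range: tuple[int, int] = (2, 12)
    kmeans_repetitions: int = 1000
    duplicate_threshold: float = 0.3
    chirp_bin_hz: float = 1.0
    template_path: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("kernel_sigma_s", "spont_window_s", "step1_transiency_ms",
                     "step1_sustained_margin", "duplicate_threshold", "chirp_bin_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["chirp_band_hz"] = list(self.chirp_band_hz)
        d["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["chirp_band_hz"] = tuple(d["chirp_band_hz"])
        d["k_range"] = tuple(d["k_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def write_spike_trains(trains: Sequence[SpikeTrain], spikes_path: str | Path,
                       epochs_path: str | Path) -> None:
    with open(spikes_path, "w") as fh:
        fh.write("unit_id,spike_time_s\n")
        for t in trains:
            for s in t.spike_times:
                fh.write(f"{t.unit_id},{TIME_FORMAT % s}\n")
    with open(epochs_path, "w") as fh:
        fh.write("unit_id,stimulus_id,onset_s,offset_s,repeat\n")
        for t in trains:
            for e in t.epochs:
                fh.write(f"{t.unit_id},{e.stimulus_id},{TIME_FORMAT % e.onset},"
                         f"{TIME_FORMAT % e.offset},{e.repeat}\n")


def _validate_train(train: SpikeTrain) -> None:
    if np.any(np.diff(train.spike_times) < 0):
        raise UnsortedSpikesError(f"unit {train.unit_id}: spike times not sorted")
    if np.any(train.spike_times < 0) or (
            train.spike_times.size and train.spike_times[-1] > train.recording_duration):
        raise SchemaError(f"unit {train.unit_id}: spike times outside recording")
    eps = sorted(train.epochs, key=lambda e: e.onset)
    for a, b in zip(eps, eps[1:]):
        if b.onset < a.offset - 1e-9:
            raise OverlappingEpochsError(
                f"unit {train.unit_id}: epochs {a.stimulus_id} and {b.stimulus_id} overlap")


def read_spike_trains(spikes_path: str | Path,
                      epochs_path: str | Path) -> list[SpikeTrain]:
    spikes = pd.read_csv(spikes_path)
    epochs = pd.read_csv(epochs_path)
    for df, cols in ((spikes, {"unit_id", "spike_time_s"}),
                     (epochs, {"unit_id", "stimulus_id", "onset_s", "offset_s", "repeat"})):
        if not cols.issubset(df.columns):
            raise SchemaError(f"missing columns: {cols - set(df.columns)}")
    trains = []
    unit_ids = list(dict.fromkeys(epochs["unit_id"])) or list(dict.fromkeys(spikes["unit_id"]))
    spike_groups = dict(list(spikes.groupby("unit_id", sort=False)))
    epoch_groups = dict(list(epochs.groupby("unit_id", sort=False)))
    for uid in unit_ids:
        times = (spike_groups[uid]["spike_time_s"].to_numpy(dtype=float)
                 if uid in spike_groups else np.empty(0))
        eps = [
            Epoch(r.stimulus_id, float(r.onset_s), float(r.offset_s), int(r.repeat))
            for r in epoch_groups[uid].itertuples()
        ] if uid in epoch_groups else []
        duration = max([e.offset for e in eps] + ([times[-1]] if times.size else [0.0]))
        train = SpikeTrain(unit_id=str(uid), spike_times=times,
                           recording_duration=duration, epochs=eps)
        _validate_train(train)
        trains.append(train)
    return trains


def write_spike_trains_json(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    payload = [
        {
            "unit_id": t.unit_id,
            "recording_duration": t.recording_duration,
            "spike_times_s": [float(TIME_FORMAT % s) for s in t.spike_times],
            "epochs": [
                {"stimulus_id": e.stimulus_id, "onset_s": e.onset,
                 "offset_s": e.offset, "repeat": e.repeat}
                for e in t.epochs
            ],
        }
        for t in trains
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_spike_trains_json(path: str | Path) -> list[SpikeTrain]:
    payload = json.loads(Path(path).read_text())
    trains = []
    for d in payload:
        train = SpikeTrain(
            unit_id=d["unit_id"],
            spike_times=np.asarray(d["spike_times_s"], dtype=float),
            recording_duration=float(d["recording_duration"]),
            epochs=[Epoch(e["stimulus_id"], float(e["onset_s"]),
                          float(e["offset_s"]), int(e["repeat"]))
                    for e in d["epochs"]],
        )
        _validate_train(train)
        trains.append(train)
    return trains


# ---------------------------------------------------------------------------
# labels, templates, result tables
# ---------------------------------------------------------------------------

def write_labels(labels: Sequence[GroundTruthLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id,archetype,true_cluster\n")
        for l in labels:
            fh.write(f"{l.unit_id},{l.archetype},{l.true_cluster}\n")


def read_labels(path: str | Path) -> list[GroundTruthLabel]:
    df = pd.read_csv(path)
    return [GroundTruthLabel(str(r.unit_id), str(r.archetype), int(r.true_cluster))
            for r in df.itertuples()]


def write_templates(templates: Sequence[ClusterTemplate], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for tpl in templates:
        fname = f"template_{tpl.name}.csv"
        t = np.arange(tpl.values.size) * tpl.dt
        with open(directory / fname, "w") as fh:
            fh.write("time_s,value\n")
            for ti, v in zip(t, tpl.values):
                fh.write(f"{ti:.4f},{v:.6f}\n")
        manifest.append({"name": tpl.name, "file": fname, "dt_s": tpl.dt,
                         "flash_samples": tpl.flash_samples})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_templates(directory: str | Path) -> list[ClusterTemplate]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = []
    for entry in manifest:
        df = pd.read_csv(directory / entry["file"])
        out.append(ClusterTemplate(name=entry["name"],
                                   values=df["value"].to_numpy(dtype=float),
                                   dt=float(entry["dt_s"]),
                                   flash_samples=int(entry["flash_samples"])))
    return out


def profiles_to_frame(profiles: Sequence[CellProfile]) -> pd.DataFrame:
    rows = [asdict(p) for p in profiles]
    return pd.DataFrame(rows).set_index("unit_id")


def maps_to_frame(maps_by_unit: dict[str, "np.ndarray"],
                  periods: Sequence[float], freqs: Sequence[float]) -> pd.DataFrame:
    rows = []
    for uid, m in maps_by_unit.items():
        for i, p in enumerate(periods):
            for j, f in enumerate(freqs):
                rows.append({"unit_id": uid, "period_um": p, "frequency_hz": f,
                             "strength": m[i, j]})
    return pd.DataFrame(rows)


def assignments_to_frame(assignments: Sequence[ClusterAssignment]) -> pd.DataFrame:
    return pd.DataFrame([
        {"unit_id": a.unit_id,
         "cluster": "" if a.cluster is None else a.cluster,
         "step": "" if a.step is None else a.step,
         "similarity": "" if a.similarity is None else round(a.similarity, 6),
         "note": a.note}
        for a in assignments
    ])
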