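"""Domain types and file I/O for trials, events, configuration and profiles.

Angle convention (fixed for the whole package, see README): sagittal-plane
segment angles in degrees, anticlockwise-positive as viewed from the
athlete's right with motion left-to-right; clockwise rotation decreases the
angle.  Time is seconds from the start of the recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ValidationError

SEGMENTS = ("trunk", "thigh_L", "thigh_R", "shank_L", "shank_R", "foot_L", "foot_R")
SIDES = ("left", "right")
EVENT_KINDS = ("toe_off", "touchdown")

#: suffix used in segment ids for each physical side
SIDE_SUFFIX = {"left": "L", "right": "R"}


def other_side(side: str) -> str:
    return "right" if side == "left" else "left"


def segment_id(base: str, side: str) -> str:
    """Segment id of a sided segment, e.g. ``("thigh", "left") -> "thigh_L"``."""
    return f"{base}_{SIDE_SUFFIX[side]}"


@dataclass(frozen=True)
class AngleSeries:
    """Uniformly sampled angle signal for one body segment.

    Parameters
    ----------
    segment_id:
        One of :data:`SEGMENTS`.
    sample_rate:
        Sampling frequency in Hz (positive).
    values:
        Angles in degrees; at least two finite samples.
    start_time:
        Time of the first sample, in seconds.
    """

    segment_id: str
    sample_rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.segment_id not in SEGMENTS:
            raise ValidationError(f"unknown segment id {self.segment_id!r}")
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("values must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"non-finite angles in segment {self.segment_id}")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.values.size - 1) / self.sample_rate


@dataclass(frozen=True)
class GaitEvent:
    """One gait event: toe-off or touchdown of a given limb."""

    kind: str
    time: float
    side: str
    label: str = ""

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")


@dataclass
class Trial:
    """One sprint trial: seven segment angle series plus ordered gait events."""

    participant_id: str
    series: dict[str, AngleSeries]
    events: list[GaitEvent]
    front_block_side: str = "right"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [s for s in SEGMENTS if s not in self.series]
        if missing:
            raise ValidationError(f"trial missing segment series: {missing}")
        if self.front_block_side not in SIDES:
            raise ValidationError(f"bad front_block_side {self.front_block_side!r}")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("events must be strictly increasing in time")
        for ev in self.events:
            for s in self.series.values():
                if not (s.start_time <= ev.time <= s.end_time):
                    raise ValidationError(
                        f"event {ev.label or ev.kind}@{ev.time:g}s outside span of "
                        f"segment {s.segment_id} [{s.start_time:g}, {s.end_time:g}]"
                    )

    @property
    def sample_rate(self) -> float:
        return next(iter(self.series.values())).sample_rate


_SD_FORMULAS = ("angular_deviation", "ln_r")
_BOUNDARY_RULES = ("distal", "proximal")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    ``lowpass_cutoff=None`` disables filtering (useful for noise-free
    synthetic data).
    """

    n_norm_points: int = 101
    lowpass_cutoff: float | None = 15.0
    filter_order: int = 4
    circular_sd_formula: str = "angular_deviation"
    bin_boundary_rule: str = "distal"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_norm_points < 3:
            raise ConfigError("n_norm_points must be >= 3")
        if self.lowpass_cutoff is not None and self.lowpass_cutoff <= 0:
            raise ConfigError("lowpass_cutoff must be positive or None")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.circular_sd_formula not in _SD_FORMULAS:
            raise ConfigError(
                f"circular_sd_formula must be one of {_SD_FORMULAS}"
            )
        if self.bin_boundary_rule not in _BOUNDARY_RULES:
            raise ConfigError(f"bin_boundary_rule must be one of {_BOUNDARY_RULES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trial I/O
# ---------------------------------------------------------------------------

_ANGLE_COLUMNS = ("time_s",) + SEGMENTS


def read_trial(
    angles_path: str | Path,
    events_path: str | Path,
    participant_id: str | None = None,
) -> Trial:
    """Read a trial from an angles CSV plus an events CSV/JSON file.

    The angles file must have columns ``time_s`` plus one per segment; the
    events file rows carry ``kind, time_s, side, label``.  The front-block
    side is inferred from the side of the first toe-off.
    """
    angles_path = Path(angles_path)
    df = pd.read_csv(angles_path)
    for col in _ANGLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"angles file {angles_path} missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("angles file must have at least two rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("time_s must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-9):
        raise ValidationError("time_s must be uniformly sampled")
    fs = 1.0 / float(np.median(dt))
    series = {
        seg: AngleSeries(seg, fs, df[seg].to_numpy(dtype=float), start_time=float(t[0]))
        for seg in SEGMENTS
    }
    events = read_events(events_path)
    toe_offs = [e for e in events if e.kind == "toe_off"]
    if not toe_offs:
        raise ValidationError("events contain no toe_off")
    front = toe_offs[0].side
    if participant_id is None:
        participant_id = angles_path.stem.replace("_angles", "")
    return Trial(participant_id, series, events, front_block_side=front)


def read_events(path: str | Path) -> list[GaitEvent]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            rows = json.load(fh)
    else:
        edf = pd.read_csv(path)
        for col in ("kind", "time_s", "side", "label"):
            if col not in edf.columns:
                raise FormatError(f"events file {path} missing column {col!r}")
        rows = edf.to_dict("records")
    events = [
        GaitEvent(str(r["kind"]), float(r["time_s"]), str(r["side"]), str(r.get("label", "")))
        for r in rows
    ]
    return events


def write_trial(trial: Trial, angles_path: str | Path, events_path: str | Path) -> None:
    """Write a trial back to the CSV formats accepted by :func:`read_trial`."""
    ref = trial.series[SEGMENTS[0]]
    data = {"time_s": ref.times}
    for seg in SEGMENTS:
        s = trial.series[seg]
        if s.values.size != ref.values.size:
            raise ValidationError("all segment series must share one time base")
        data[seg] = s.values
    pd.DataFrame(data).to_csv(angles_path, index=False, float_format="%.9g")
    edf = pd.DataFrame(
        [{"kind": e.kind, "time_s": e.time, "side": e.side, "label": e.label} for e in trial.events]
    )
    edf.to_csv(events_path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = (
    "participant",
    "step",
    "coupling",
    "interval_index",
    "coupling_angle_deg",
    "bin_index",
    "bin_label",
    "dominant_segment",
    "dominancy_pct",
    "defined",
    "imputed",
    "touchdown_pct",
)


def profiles_to_frame(profiles: Iterable) -> pd.DataFrame:
    """Flatten CoordinationProfile objects into a tidy frame (one row per interval)."""
    profiles = list(profiles)
    rows = []
    if profiles:
        n0 = profiles[0].n_intervals
        coupling0 = profiles[0].coupling.name
        for p in profiles:
            if p.n_intervals != n0:
                raise ValidationError("profiles have heterogeneous interval counts")
            if p.coupling.name != coupling0:
                raise ValidationError("profiles mix couplings; write one coupling per file")
            labels = p.bin_labels()
            for i in range(p.n_intervals):
                rows.append(
                    {
                        "participant": p.participant_id,
                        "step": p.step_index,
                        "coupling": p.coupling.name,
                        "interval_index": i,
                        "coupling_angle_deg": p.gamma[i],
                        "bin_index": int(p.bin_index[i]),
                        "bin_label": labels[i],
                        "dominant_segment": p.dominant[i] if p.dominant[i] else "",
                        "dominancy_pct": p.dominancy_pct[i],
                        "defined": bool(p.defined[i]),
                        "imputed": bool(p.imputed[i]),
                        "touchdown_pct": p.touchdown_pct,
                    }
                )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profiles(profiles: Iterable, path: str | Path) -> None:
    """Write coordination profiles to CSV (one row per interval).

    All profiles must share one coupling and one normalization length.
    An empty collection yields a header-only file.
    """
    profiles_to_frame(profiles).to_csv(path, index=False, float_format="%.9g")


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"profiles file {path} missing columns {missing}")
    return df
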