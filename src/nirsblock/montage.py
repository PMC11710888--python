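"""Channel montage and randomized block protocol.

A continuous-wave fNIRS montage is a set of source-detector channels, each
with a cortical region label, plus the pair of laser/LED wavelengths and the
sampling rate of the instrument.  The default montage covers the bilateral
premotor cortex (PMC), supplementary motor area (SMA) and primary motor
cortex (M1) with 16 channels formed from 8 sources and 8 detectors at
~3.0 cm separation.

The block protocol interleaves four motor-acquisition conditions -- motor
execution (ME), motor imagery (MI), action observation (AO) and mirror
visual feedback (MVF) -- in randomized order: each 60-s task block is
preceded by a 10-s instruction cue and followed by a 40-s rest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Channel",
    "Montage",
    "TaskEvent",
    "Schedule",
    "TASK_CONDITIONS",
    "default_montage",
    "build_schedule",
    "read_events",
    "write_events",
    "read_montage",
    "write_montage",
]

#: The four motor-acquisition task conditions.
TASK_CONDITIONS = ("ME", "MI", "AO", "MVF")

#: Non-task event labels.
AUX_CONDITIONS = ("REST", "CUE")

HEMISPHERES = ("left", "right")
REGIONS = ("PMC", "SMA", "M1")

# Region/hemisphere partition of the 16 default channels.
_DEFAULT_PARTITION = {
    ("left", "PMC"): (1, 2, 3, 4),
    ("left", "SMA"): (5, 6),
    ("right", "SMA"): (7, 8),
    ("right", "PMC"): (9, 10, 11, 12),
    ("left", "M1"): (13, 14),
    ("right", "M1"): (15, 16),
}


@dataclass(frozen=True)
class Channel:
    """A single source-detector channel."""

    channel_id: int
    source_id: int
    detector_id: int
    hemisphere: str
    region: str
    separation_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not self.separation_cm > 0:
            raise ValueError("separation_cm must be positive")

    @property
    def label(self) -> str:
        """Human-readable label in the style ``L't PMC (Ch1)``."""
        side = "L't" if self.hemisphere == "left" else "R't"
        return f"{side} {self.region} (Ch{self.channel_id})"


@dataclass(frozen=True)
class Montage:
    """An ordered set of channels plus acquisition parameters."""

    channels: tuple[Channel, ...]
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    sampling_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if len(self.wavelengths_nm) != 2:
            raise ValueError("exactly 2 wavelengths supported")
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("channel_ids must be unique")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(c.channel_id for c in self.channels)

    @property
    def separations_cm(self) -> np.ndarray:
        return np.array([c.separation_cm for c in self.channels])

    def channel(self, channel_id: int) -> Channel:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c
        raise KeyError(f"no channel {channel_id} in montage")

    def with_sampling_rate(self, fs: float) -> "Montage":
        return replace(self, sampling_rate_hz=fs)


def default_montage(sampling_rate_hz: float = 10.0) -> Montage:
    """The 16-channel bilateral PMC/SMA/M1 motor montage.

    Sources and detectors (8 each) are assigned so that every source feeds
    two channels; only the region/hemisphere partition is meaningful for
    analysis, the optode indices are bookkeeping.
    """
    channels = []
    for (hemisphere, region), ids in _DEFAULT_PARTITION.items():
        for ch in ids:
            src = (ch - 1) // 2 + 1
            det = (src - 1 + (ch - 1) % 2) % 8 + 1
            channels.append(
                Channel(
                    channel_id=ch,
                    source_id=src,
                    detector_id=det,
                    hemisphere=hemisphere,
                    region=region,
                    separation_cm=3.0,
                )
            )
    channels.sort(key=lambda c: c.channel_id)
    return Montage(channels=tuple(channels), sampling_rate_hz=sampling_rate_hz)


@dataclass(frozen=True)
class TaskEvent:
    """One scheduled event (task block, rest, or instruction cue)."""

    condition: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.condition not in TASK_CONDITIONS + AUX_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.onset_s < 0:
            raise ValueError("onset_s must be nonnegative")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Schedule:
    """An ordered, non-overlapping event list for one recording."""

    events: tuple[TaskEvent, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_onset = -np.inf
        for i, ev in enumerate(self.events):
            if ev.onset_s <= prev_onset:
                raise ValueError(f"event {i}: onsets must be strictly increasing")
            if ev.onset_s < prev_end - 1e-9:
                raise ValueError(f"event {i}: overlaps previous event")
            prev_onset = ev.onset_s
            prev_end = ev.offset_s

    @property
    def task_blocks(self) -> tuple[TaskEvent, ...]:
        return tuple(e for e in self.events if e.condition in TASK_CONDITIONS)

    @property
    def duration_s(self) -> float:
        return max(e.offset_s for e in self.events) if self.events else 0.0

    def blocks_for(self, condition: str) -> tuple[TaskEvent, ...]:
        return tuple(e for e in self.task_blocks if e.condition == condition)


def build_schedule(
    seed: int,
    conditions: tuple[str, ...] = TASK_CONDITIONS,
    blocks_per_condition: int = 3,
    task_s: float = 60.0,
    rest_s: float = 40.0,
    cue_s: float = 10.0,
) -> Schedule:
    """Randomized block schedule: per block, cue -> task -> rest.

    The block-condition sequence is a uniform shuffle of
    ``conditions x blocks_per_condition``, reproducible from ``seed``.
    Total duration is ``n_blocks * (cue_s + task_s + rest_s)``.
    """
    if not conditions:
        raise ValueError("conditions must be nonempty")
    if blocks_per_condition < 1:
        raise ValueError("blocks_per_condition must be >= 1")
    if min(task_s, rest_s, cue_s) <= 0:
        raise ValueError("durations must be positive")
    order = [c for c in conditions for _ in range(blocks_per_condition)]
    rng = np.random.default_rng(seed)
    rng.shuffle(order)

    events: list[TaskEvent] = []
    t = 0.0
    for cond in order:
        events.append(TaskEvent("CUE", t, cue_s))
        events.append(TaskEvent(cond, t + cue_s, task_s))
        events.append(TaskEvent("REST", t + cue_s + task_s, rest_s))
        t += cue_s + task_s + rest_s
    return Schedule(events=tuple(events), seed=seed)


# ---------------------------------------------------------------------------
# events file IO (3-column delimited text: onset_s, duration_s, condition)
# ---------------------------------------------------------------------------

def write_events(schedule: Schedule, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["onset_s", "duration_s", "condition"])
        for ev in schedule.events:
            w.writerow([f"{ev.onset_s:.6f}", f"{ev.duration_s:.6f}", ev.condition])


def read_events(path) -> Schedule:
    events: list[TaskEvent] = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if rows and rows[0][:2] == ["onset_s", "duration_s"]:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"no events in {path}")
    for i, row in enumerate(rows):
        if len(row) != 3:
            raise ValueError(f"row {i}: expected 3 columns, got {len(row)}")
        try:
            onset, dur = float(row[0]), float(row[1])
        except ValueError as exc:
            raise ValueError(f"row {i}: non-numeric onset/duration") from exc
        try:
            events.append(TaskEvent(row[2].strip(), onset, dur))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    try:
        return Schedule(events=tuple(events))
    except ValueError as exc:
        raise ValueError(f"invalid event list in {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# montage config IO (YAML)
# ---------------------------------------------------------------------------

def write_montage(montage: Montage, path) -> None:
    doc = {
        "wavelengths_nm": list(montage.wavelengths_nm),
        "sampling_rate_hz": montage.sampling_rate_hz,
        "channels": [
            {
                "channel_id": c.channel_id,
                "source_id": c.source_id,
                "detector_id": c.detector_id,
                "hemisphere": c.hemisphere,
                "region": c.region,
                "separation_cm": c.separation_cm,
            }
            for c in montage.channels
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_montage(path) -> Montage:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "channels" not in doc:
        raise ValueError(f"{path}: not a montage config")
    channels = tuple(Channel(**ch) for ch in doc["channels"])
    return Montage(
        channels=channels,
        wavelengths_nm=tuple(doc.get("wavelengths_nm", (760.0, 850.0))),
        sampling_rate_hz=float(doc.get("sampling_rate_hz", 10.0)),
    )
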