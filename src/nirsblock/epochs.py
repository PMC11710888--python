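"""Block segmentation, baseline correction, and phase summaries.

Each 60-s task block is extracted together with the 10 s immediately
preceding its onset (the instruction-cue period), which serves as the
baseline: the baseline-window mean is subtracted per channel.  Block
responses are averaged within condition and summarized as the mean
concentration change over the early phase (0-30 s after onset, the
immediate hemodynamic response) and the late phase (30-60 s, sustained
activation).  The per-(subject, condition, channel, phase) means are the
unit of group inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Schedule, TASK_CONDITIONS
from .preprocess import HbSeries
from .qc import QCReport

__all__ = [
    "EpochConfig",
    "EpochSet",
    "segment_blocks",
    "block_average",
    "phase_mean",
    "phase_summary",
]

PHASES = ("early", "late")


@dataclass(frozen=True)
class EpochConfig:
    baseline_s: float = 10.0
    early_window_s: tuple[float, float] = (0.0, 30.0)
    late_window_s: tuple[float, float] = (30.0, 60.0)
    analyte: str = "hbo"

    def __post_init__(self) -> None:
        if self.baseline_s <= 0:
            raise ValueError("baseline_s must be positive")
        for lo, hi in (self.early_window_s, self.late_window_s):
            if not lo < hi:
                raise ValueError("phase windows must be nonempty")
        if self.analyte not in ("hbo", "hbr", "hbdiff"):
            raise ValueError("analyte must be hbo, hbr or hbdiff")

    def window(self, phase: str) -> tuple[float, float]:
        if phase == "early":
            return self.early_window_s
        if phase == "late":
            return self.late_window_s
        raise ValueError(f"unknown phase {phase!r}")


@dataclass(frozen=True)
class EpochSet:
    """Baseline-corrected analyte segments, (block, time, channel).

    ``time_s`` is onset-relative and starts at ``-baseline_s``; samples are
    assigned to windows by the half-open convention t in [a, b).
    """

    data: np.ndarray
    time_s: np.ndarray
    conditions: tuple[str, ...]
    channel_ids: tuple[int, ...]
    sampling_rate_hz: float
    analyte: str
    rejected: frozenset[int] = frozenset()

    @property
    def n_blocks(self) -> int:
        return self.data.shape[0]

    def kept_mask(self) -> np.ndarray:
        return np.array([cid not in self.rejected for cid in self.channel_ids])


def _win_idx(time_s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (time_s >= lo - 1e-9) & (time_s < hi - 1e-9)


def segment_blocks(
    hb: HbSeries,
    schedule: Schedule,
    config: EpochConfig = EpochConfig(),
    qc: QCReport | None = None,
) -> EpochSet:
    """Extract [-baseline_s, +task_s) around each task-block onset.

    The mean of the pre-onset baseline window [-baseline_s, 0) is
    subtracted per channel and block.
    """
    fs = hb.sampling_rate_hz
    blocks = schedule.task_blocks
    if not blocks:
        raise ValueError("schedule contains no task blocks")
    task_s = blocks[0].duration_s
    n_pre = int(round(config.baseline_s * fs))
    n_total = n_pre + int(round(task_s * fs))
    x = hb.analyte(config.analyte)

    segs, conds = [], []
    for k, ev in enumerate(blocks):
        onset_i = int(round(ev.onset_s * fs))
        if onset_i - n_pre < 0:
            raise ValueError(
                f"block {k} at {ev.onset_s} s starts less than "
                f"{config.baseline_s} s into the recording"
            )
        if onset_i + n_total - n_pre > hb.n_samples:
            raise ValueError(f"block {k} extends past the recording end")
        seg = x[onset_i - n_pre : onset_i - n_pre + n_total].astype(float).copy()
        seg -= seg[:n_pre].mean(axis=0)
        segs.append(seg)
        conds.append(ev.condition)

    time_s = (np.arange(n_total) - n_pre) / fs
    montage_ids = tuple(range(1, hb.n_channels + 1))
    return EpochSet(
        data=np.stack(segs, axis=0),
        time_s=time_s,
        conditions=tuple(conds),
        channel_ids=montage_ids,
        sampling_rate_hz=fs,
        analyte=config.analyte,
        rejected=qc.rejected if qc is not None else frozenset(),
    )


def block_average(epochs: EpochSet) -> dict[str, tuple[np.ndarray, int]]:
    """Pointwise mean time course per condition: {condition: (curve, n)}.

    ``curve`` is (time, channel); ``n`` the number of blocks averaged.
    """
    out: dict[str, tuple[np.ndarray, int]] = {}
    conds = np.asarray(epochs.conditions)
    for cond in dict.fromkeys(epochs.conditions):
        sel = conds == cond
        out[cond] = (epochs.data[sel].mean(axis=0), int(sel.sum()))
    return out


def phase_mean(
    avg_curve: np.ndarray,
    time_s: np.ndarray,
    config: EpochConfig = EpochConfig(),
) -> dict[str, np.ndarray]:
    """Mean of an averaged time course over each phase window, per channel."""
    out = {}
    for phase in PHASES:
        lo, hi = config.window(phase)
        idx = _win_idx(time_s, lo, hi)
        if not idx.any():
            raise ValueError(f"{phase} window [{lo}, {hi}) contains no samples")
        out[phase] = avg_curve[idx].mean(axis=0)
    return out


def phase_summary(
    epochs: EpochSet,
    subject: str,
    config: EpochConfig = EpochConfig(),
) -> pd.DataFrame:
    """Long-format per-subject summary: condition x channel x phase means.

    Cells from QC-rejected channels are NaN (missing, not zero).
    """
    rows = []
    kept = epochs.kept_mask()
    averaged = block_average(epochs)
    for cond, (curve, n_blocks) in averaged.items():
        phases = phase_mean(curve, epochs.time_s, config)
        for phase, vals in phases.items():
            for c, cid in enumerate(epochs.channel_ids):
                rows.append(
                    {
                        "subject": subject,
                        "condition": cond,
                        "channel_id": cid,
                        "phase": phase,
                        "value": float(vals[c]) if kept[c] else np.nan,
                        "n_blocks": n_blocks if kept[c] else 0,
                    }
                )
    return pd.DataFrame(rows)
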