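"""Coefficient-of-variation channel quality control.

Signal quality of a continuous-wave channel is screened on the raw
intensities at both wavelengths with the relative coefficient of variation
CV = sigma/mu x 100% (population SD), at two granularities: CV_chan over
the entire recording, and CV_trial within each 60-s task block.  A channel
is rejected if CV_chan exceeds 15% or any CV_trial exceeds 10% at either
wavelength (strict inequality); the thresholds target motion-induced
coupling instability and blood-pressure transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Schedule
from .recording import RawRecording

__all__ = [
    "QCConfig",
    "QCReport",
    "coefficient_of_variation",
    "cv_chan",
    "cv_trial",
    "apply_rejection",
    "run_qc",
]


@dataclass(frozen=True)
class QCConfig:
    cv_chan_threshold_pct: float = 15.0
    cv_trial_threshold_pct: float = 10.0
    sd_convention: str = "population"

    def __post_init__(self) -> None:
        if self.cv_chan_threshold_pct <= 0 or self.cv_trial_threshold_pct <= 0:
            raise ValueError("CV thresholds must be positive")
        if self.sd_convention != "population":
            raise ValueError("only the population-SD convention is supported")


@dataclass(frozen=True)
class QCReport:
    """CV values, the rejected-channel set, and per-channel reasons.

    ``reasons[channel_id]`` is a list of (rule, wavelength_nm, trial_index,
    value_pct) tuples; trial_index is None for the whole-recording rule.
    """

    cv_chan: np.ndarray  # (channel, wavelength), percent
    cv_trial: np.ndarray  # (channel, trial, wavelength), percent
    rejected: frozenset[int]
    reasons: dict[int, list[tuple]] = field(default_factory=dict)
    channel_ids: tuple[int, ...] = ()
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)

    @property
    def kept(self) -> frozenset[int]:
        return frozenset(self.channel_ids) - self.rejected


def coefficient_of_variation(x: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Population-SD coefficient of variation, in percent."""
    x = np.asarray(x, dtype=float)
    n = x.shape[axis] if axis is not None else x.size
    if n < 2:
        raise ValueError("CV requires at least 2 samples")
    mu = x.mean(axis=axis)
    if np.any(mu == 0):
        raise ValueError("CV undefined: zero mean")
    return np.abs(x.std(axis=axis, ddof=0) / mu) * 100.0


def cv_chan(raw: RawRecording) -> np.ndarray:
    """CV of raw intensity over the full recording, (channel, wavelength) %."""
    if raw.n_samples < 2:
        raise ValueError("CV requires at least 2 samples")
    return coefficient_of_variation(raw.intensity, axis=0)


def cv_trial(raw: RawRecording, schedule: Schedule | None = None) -> np.ndarray:
    """CV within each task block, (channel, trial, wavelength) percent."""
    if schedule is None:
        schedule = raw.schedule
    fs = raw.sampling_rate_hz
    out = []
    for k, ev in enumerate(schedule.task_blocks):
        i0 = int(np.ceil(ev.onset_s * fs - 1e-9))
        i1 = int(np.ceil(ev.offset_s * fs - 1e-9))
        if i1 > raw.n_samples:
            raise ValueError(f"task block {k} ({ev.condition}) extends past recording end")
        out.append(coefficient_of_variation(raw.intensity[i0:i1], axis=0))
    return np.stack(out, axis=1)


def apply_rejection(
    cv_chan_pct: np.ndarray,
    cv_trial_pct: np.ndarray,
    config: QCConfig = QCConfig(),
    channel_ids: tuple[int, ...] | None = None,
    wavelengths_nm: tuple[float, float] = (760.0, 850.0),
) -> QCReport:
    """Reject channels violating either CV rule at either wavelength.

    A channel is rejected iff cv_chan > cv_chan_threshold at any wavelength
    OR any cv_trial > cv_trial_threshold at any wavelength (strict
    inequality at the thresholds).
    """
    cv_chan_pct = np.asarray(cv_chan_pct, dtype=float)
    cv_trial_pct = np.asarray(cv_trial_pct, dtype=float)
    n_chan = cv_chan_pct.shape[0]
    if channel_ids is None:
        channel_ids = tuple(range(1, n_chan + 1))

    reasons: dict[int, list[tuple]] = {}
    rejected: set[int] = set()
    for c in range(n_chan):
        cid = channel_ids[c]
        for w in range(cv_chan_pct.shape[1]):
            if cv_chan_pct[c, w] > config.cv_chan_threshold_pct:
                reasons.setdefault(cid, []).append(
                    ("cv_chan", wavelengths_nm[w], None, float(cv_chan_pct[c, w]))
                )
                rejected.add(cid)
        for trial in range(cv_trial_pct.shape[1]):
            for w in range(cv_trial_pct.shape[2]):
                if cv_trial_pct[c, trial, w] > config.cv_trial_threshold_pct:
                    reasons.setdefault(cid, []).append(
                        ("cv_trial", wavelengths_nm[w], trial, float(cv_trial_pct[c, trial, w]))
                    )
                    rejected.add(cid)
    return QCReport(
        cv_chan=cv_chan_pct,
        cv_trial=cv_trial_pct,
        rejected=frozenset(rejected),
        reasons=reasons,
        channel_ids=tuple(channel_ids),
        wavelengths_nm=wavelengths_nm,
    )


def run_qc(raw: RawRecording, config: QCConfig = QCConfig()) -> QCReport:
    """Compute both CV screens on a recording and apply the rejection rule."""
    return apply_rejection(
        cv_chan(raw),
        cv_trial(raw),
        config,
        channel_ids=raw.montage.channel_ids,
        wavelengths_nm=tuple(raw.montage.wavelengths_nm),
    )
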