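"""In-memory container for a raw dual-wavelength intensity recording."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage, Schedule

__all__ = ["RawRecording"]


@dataclass(frozen=True)
class RawRecording:
    """Sampled light intensities, time x channel x wavelength.

    Intensities are in arbitrary detector units and must be strictly
    positive (optical density is a log of intensity ratios).
    """

    intensity: np.ndarray
    sampling_rate_hz: float
    schedule: Schedule
    montage: Montage

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("intensity must be (time, channel, 2 wavelengths)")
        if arr.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if not np.all(arr > 0):
            raise ValueError("intensity must be strictly positive")
        object.__setattr__(self, "intensity", arr)
        span = self.schedule.duration_s
        n_expected = int(round(span * self.sampling_rate_hz))
        if arr.shape[0] < n_expected:
            raise ValueError(
                f"recording has {arr.shape[0]} samples but schedule spans "
                f"{span} s at {self.sampling_rate_hz} Hz ({n_expected} samples)"
            )

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz
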