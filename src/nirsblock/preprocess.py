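"""Raw intensity to hemoglobin concentration changes.

The conversion chain is: optical density (OD) relative to the
full-recording mean intensity, zero-phase Butterworth band-pass on OD
(0.01-0.2 Hz by default, removing cardiac ~1 Hz, respiratory ~0.25 Hz and
slow drift), inversion of the modified Beer-Lambert law (MBLL) to
oxy-/deoxy-hemoglobin concentration changes, and optionally
correlation-based signal improvement (CBSI), which projects out the
common-mode (motion-related) component by enforcing perfect HbO/HbR
anticorrelation.

Concentration changes are expressed in micromolar (uM), relative to the
recording mean (the OD reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "ODSeries",
    "HbSeries",
    "MbllParams",
    "EXTINCTION_1_PER_MM_CM",
    "default_mbll_params",
    "intensity_to_od",
    "bandpass",
    "bandpass_od",
    "mbll",
    "cbsi",
    "baseline_shift",
]

#: Molar extinction coefficients [1/(mM cm)] at the instrument wavelengths,
#: rows (HbO2, Hb), from the standard Gratzer/Prahl compilation.
EXTINCTION_1_PER_MM_CM = {
    760.0: (0.5866, 1.5485),
    850.0: (1.0580, 0.6913),
}


@dataclass(frozen=True)
class ODSeries:
    """Optical-density changes, time x channel x wavelength (dimensionless)."""

    delta_od: np.ndarray
    sampling_rate_hz: float
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    i0_convention: str = "full-recording-mean"

    def __post_init__(self) -> None:
        if self.delta_od.ndim != 3 or self.delta_od.shape[2] != 2:
            raise ValueError("delta_od must be (time, channel, 2 wavelengths)")
        if not np.all(np.isfinite(self.delta_od)):
            raise ValueError("delta_od must be finite")

    @property
    def n_samples(self) -> int:
        return self.delta_od.shape[0]

    @property
    def n_channels(self) -> int:
        return self.delta_od.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class HbSeries:
    """Hemoglobin concentration changes, time x channel, in uM.

    ``hbdiff = hbo - hbr`` always; after CBSI, ``hbr = -hbo / alpha`` and
    corr(hbo, hbr) = -1 per channel.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate_hz: float
    cbsi_applied: bool = False
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 2:
            raise ValueError("hbo/hbr must be equal-shape (time, channel) arrays")

    @property
    def hbdiff(self) -> np.ndarray:
        return self.hbo - self.hbr

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def analyte(self, name: str) -> np.ndarray:
        if name == "hbo":
            return self.hbo
        if name == "hbr":
            return self.hbr
        if name == "hbdiff":
            return self.hbdiff
        raise ValueError(f"unknown analyte {name!r}")


@dataclass(frozen=True)
class MbllParams:
    """Modified Beer-Lambert parameters.

    extinction: 2x2 matrix, rows = wavelengths, columns = (HbO, HbR),
    in 1/(mM cm).  dpf: differential pathlength factor per wavelength.
    separation_cm: source-detector distance per channel.
    """

    extinction: np.ndarray
    dpf: tuple[float, float] = (6.0, 6.0)
    separation_cm: np.ndarray = field(default_factory=lambda: np.full(16, 3.0))

    def __post_init__(self) -> None:
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2):
            raise ValueError("extinction must be 2x2 (wavelength x species)")
        if np.linalg.cond(ext) > 1e8:
            raise ValueError("extinction matrix is singular or ill-conditioned")
        if not all(d > 0 for d in self.dpf):
            raise ValueError("dpf must be positive")
        object.__setattr__(self, "extinction", ext)
        object.__setattr__(self, "separation_cm", np.asarray(self.separation_cm, float))

    def pathlength_cm(self) -> np.ndarray:
        """Effective pathlength d*DPF, shape (channel, wavelength)."""
        return self.separation_cm[:, None] * np.asarray(self.dpf)[None, :]


def default_mbll_params(montage=None, dpf: tuple[float, float] = (6.0, 6.0)) -> MbllParams:
    """MBLL parameters for a montage (default 16 channels at 3.0 cm)."""
    if montage is None:
        sep = np.full(16, 3.0)
        wls = (760.0, 850.0)
    else:
        sep = montage.separations_cm
        wls = tuple(montage.wavelengths_nm)
    ext = np.array([EXTINCTION_1_PER_MM_CM[w] for w in wls])
    return MbllParams(extinction=ext, dpf=dpf, separation_cm=sep)


def intensity_to_od(raw) -> ODSeries:
    """OD change relative to the full-recording mean intensity.

    dOD(t, lambda) = -log10(I(t, lambda) / I0(lambda)) with I0 the mean
    intensity of that channel/wavelength over the whole recording.
    """
    intensity = raw.intensity
    if np.any(intensity <= 0):
        ch_idx, = np.where((intensity <= 0).any(axis=(0, 2)))
        ids = [raw.montage.channel_ids[i] for i in ch_idx]
        raise ValueError(f"nonpositive intensity (OD undefined) on channels {ids}")
    i0 = intensity.mean(axis=0, keepdims=True)
    od = -np.log10(intensity / i0)
    return ODSeries(
        delta_od=od,
        sampling_rate_hz=raw.sampling_rate_hz,
        wavelengths_nm=tuple(raw.montage.wavelengths_nm),
    )


def bandpass(
    x: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.2,
    fs: float = 10.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0.

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is |H|^2 and phase is zero; DC and out-of-band physiological
    rhythms (cardiac, respiration) are removed.
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for fs={fs} Hz: "
            "need 0 < low < high < fs/2"
        )
    x = np.asarray(x, dtype=float)
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, x, axis=0)


def bandpass_od(od: ODSeries, low_hz: float = 0.01, high_hz: float = 0.2, order: int = 4) -> ODSeries:
    shape = od.delta_od.shape
    flat = od.delta_od.reshape(shape[0], -1)
    filt = bandpass(flat, low_hz, high_hz, od.sampling_rate_hz, order=order)
    return replace(od, delta_od=filt.reshape(shape))


def mbll(od: ODSeries, params: MbllParams) -> HbSeries:
    """Invert the modified Beer-Lambert law per sample and channel.

    Solves dOD(lambda) = sum_s eps[lambda, s] * dc[s] * d * DPF(lambda)
    for dc = (dHbO, dHbR); eps in 1/(mM cm), d*DPF in cm, so dc is in mM and
    is returned in uM.
    """
    if od.n_channels != len(params.separation_cm):
        raise ValueError("channel count mismatch between OD and MBLL params")
    path = params.pathlength_cm()  # (C, W)
    # per-channel system matrix A[c, w, s] = eps[w, s] * path[c, w]
    a = params.extinction[None, :, :] * path[:, None, :]
    a_inv = np.linalg.inv(a)  # (C, 2, 2)
    # dc[t, c, s] = A^{-1}[c, s, w] @ dOD[t, c, w]
    conc_mm = np.einsum("csw,tcw->tcs", a_inv, od.delta_od)
    conc_um = conc_mm * 1e3
    return HbSeries(
        hbo=np.ascontiguousarray(conc_um[:, :, 0]),
        hbr=np.ascontiguousarray(conc_um[:, :, 1]),
        sampling_rate_hz=od.sampling_rate_hz,
    )


def cbsi(hb: HbSeries, zero_variance: str = "error") -> HbSeries:
    """Correlation-based signal improvement.

    Per channel, with alpha = SD(HbO)/SD(HbR):

        HbO' = (HbO - alpha * HbR) / 2
        HbR' = -HbO' / alpha

    which removes the common-mode (positively correlated, motion-like)
    component and leaves HbO'/HbR' perfectly anticorrelated.

    zero_variance: ``"error"`` raises on a constant channel; ``"skip"``
    leaves such channels unchanged with alpha = NaN.
    """
    if zero_variance not in ("error", "skip"):
        raise ValueError("zero_variance must be 'error' or 'skip'")
    sd_o = hb.hbo.std(axis=0)
    sd_r = hb.hbr.std(axis=0)
    bad = (sd_o == 0) | (sd_r == 0)
    if bad.any() and zero_variance == "error":
        raise ValueError(f"zero-variance channel(s) at index {np.where(bad)[0].tolist()}: CBSI undefined")
    alpha = np.full(hb.n_channels, np.nan)
    ok = ~bad
    alpha[ok] = sd_o[ok] / sd_r[ok]
    hbo_new = hb.hbo.copy()
    hbr_new = hb.hbr.copy()
    hbo_new[:, ok] = (hb.hbo[:, ok] - alpha[ok] * hb.hbr[:, ok]) / 2.0
    hbr_new[:, ok] = -hbo_new[:, ok] / alpha[ok]
    return HbSeries(
        hbo=hbo_new,
        hbr=hbr_new,
        sampling_rate_hz=hb.sampling_rate_hz,
        cbsi_applied=True,
        alpha=alpha,
    )


def baseline_shift(hb: HbSeries, window: tuple[float, float]) -> HbSeries:
    """Subtract the per-channel mean over ``window`` (seconds, half-open)."""
    start_s, end_s = window
    fs = hb.sampling_rate_hz
    i0 = int(np.ceil(start_s * fs - 1e-9))
    i1 = int(np.ceil(end_s * fs - 1e-9))
    i0 = max(i0, 0)
    if i1 <= i0 or i0 >= hb.n_samples:
        raise ValueError(f"empty baseline window {window}")
    i1 = min(i1, hb.n_samples)
    mu_o = hb.hbo[i0:i1].mean(axis=0)
    mu_r = hb.hbr[i0:i1].mean(axis=0)
    return replace(hb, hbo=hb.hbo - mu_o, hbr=hb.hbr - mu_r)
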