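"""Forward simulation of raw dual-wavelength fNIRS recordings.

The simulator generates hemoglobin concentration changes with a known
activation map (which channels respond under which condition, at what peak
amplitude), adds physiological noise (cardiac, respiratory, Mayer waves,
slow drift, white noise), maps concentrations to optical density through
the forward modified Beer-Lambert law, exponentiates to detector
intensities, and optionally injects motion artifacts (spikes and step
shifts in optode coupling).  Every step is reproducible from a seed, and
ground truth is retained so the analysis pipeline can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .montage import Montage, Schedule, TASK_CONDITIONS, build_schedule, default_montage
from .preprocess import HbSeries, MbllParams, ODSeries, default_mbll_params
from .recording import RawRecording

__all__ = [
    "HRFParams",
    "SimTruth",
    "NoiseModel",
    "canonical_hrf",
    "block_regressor",
    "simulate_hb",
    "forward_mbll",
    "od_to_intensity",
    "add_motion",
    "simulate_recording",
    "simulate_cohort",
    "default_active_map",
]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    dispersion_s: float = 1.0


def canonical_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Unit-peak double-gamma HRF evaluated on time grid ``t`` (s).

    Gamma shapes are parameterized so the positive lobe's mode sits at
    ``peak_delay_s`` and the undershoot's at ``undershoot_delay_s``; the
    curve is 0 at t = 0 and normalized so its maximum is 1.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t < 0):
        raise ValueError("time grid must be nonnegative")

    def _raw(tt: np.ndarray) -> np.ndarray:
        d = params.dispersion_s
        peak = sp_stats.gamma.pdf(tt, a=1.0 + params.peak_delay_s / d, scale=d)
        under = sp_stats.gamma.pdf(tt, a=1.0 + params.undershoot_delay_s / d, scale=d)
        return peak - params.undershoot_ratio * under

    ref = _raw(np.arange(0, params.undershoot_delay_s + 32.0, 0.01))
    return _raw(t) / ref.max()


def block_regressor(
    schedule: Schedule,
    condition: str,
    fs: float,
    n_samples: int,
    hrf: HRFParams = HRFParams(),
) -> np.ndarray:
    """Task regressor for one condition: boxcar * HRF, unit peak.

    The convolution is normalized so the response to a single task block
    peaks at exactly 1; a channel active at amplitude A then has a peak
    concentration change of A uM.
    """
    blocks = schedule.blocks_for(condition)
    t = np.arange(n_samples) / fs
    box = np.zeros(n_samples)
    for ev in blocks:
        box[(t >= ev.onset_s) & (t < ev.offset_s)] = 1.0
    if not blocks:
        return box
    kernel_t = np.arange(0, hrf.undershoot_delay_s + 32.0, 1.0 / fs)
    kernel = canonical_hrf(kernel_t, hrf)
    reg = np.convolve(box, kernel)[:n_samples] / fs

    one_block = np.zeros(int(round(blocks[0].duration_s * fs)) + kernel.size)
    one_block[: int(round(blocks[0].duration_s * fs))] = 1.0
    peak = (np.convolve(one_block, kernel) / fs).max()
    return reg / peak


def default_active_map() -> dict[str, frozenset[int]]:
    """A motor-task-like activation map over the 16-channel montage.

    Motor execution and mirror feedback engage broad bilateral premotor/
    SMA/M1 sets, imagery favors premotor and SMA, and action observation
    drives no channel above noise -- the qualitative pattern expected for
    these four acquisition modes.
    """
    return {
        "ME": frozenset({1, 7, 8, 10, 12, 14, 15, 16}),
        "MI": frozenset({1, 5, 7, 9, 10, 12, 15, 16}),
        "AO": frozenset(),
        "MVF": frozenset({1, 3, 4, 5, 6, 7, 8, 12, 13, 14, 15, 16}),
    }


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth activation structure for one simulated cohort/subject."""

    active_map: dict[str, frozenset[int]] = field(default_factory=default_active_map)
    hbo_amplitude_um: float = 0.5
    hbr_ratio: float = 1.0 / 3.0
    hrf: HRFParams = HRFParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hbo_amplitude_um >= 0:
            raise ValueError("hbo_amplitude_um must be nonnegative")
        if not 0 < self.hbr_ratio <= 1:
            raise ValueError("hbr_ratio must be in (0, 1]")
        object.__setattr__(
            self,
            "active_map",
            {k: frozenset(v) for k, v in self.active_map.items()},
        )

    def validate_against(self, montage: Montage) -> None:
        ids = set(montage.channel_ids)
        for cond, chans in self.active_map.items():
            missing = set(chans) - ids
            if missing:
                raise ValueError(f"active_map[{cond}] references unknown channels {sorted(missing)}")


@dataclass(frozen=True)
class MotionParams:
    spike_rate_per_min: float = 0.5
    spike_amp: float = 0.15
    shift_prob: float = 0.02


@dataclass(frozen=True)
class NoiseModel:
    """Additive physiological noise on concentrations (uM) plus motion.

    Oscillatory components are (frequency Hz, amplitude uM) pairs with
    random phase per channel and species; drift is (slope uM/min, slow
    oscillation amplitude uM).  Motion artifacts act multiplicatively on
    intensity (see :func:`add_motion`).
    """

    cardiac: tuple[float, float] = (1.0, 0.30)
    respiration: tuple[float, float] = (0.25, 0.15)
    mayer: tuple[float, float] = (0.10, 0.10)
    drift: tuple[float, float] = (0.05, 0.15)
    white_sd: float = 0.05
    motion: MotionParams = MotionParams()

    def __post_init__(self) -> None:
        for freq, amp in (self.cardiac, self.respiration, self.mayer):
            if freq <= 0 or amp < 0:
                raise ValueError("oscillation frequencies must be > 0 and amplitudes >= 0")
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        """No noise at all (for exact recovery tests)."""
        return cls(
            cardiac=(1.0, 0.0),
            respiration=(0.25, 0.0),
            mayer=(0.10, 0.0),
            drift=(0.0, 0.0),
            white_sd=0.0,
            motion=MotionParams(0.0, 0.0, 0.0),
        )


def _physio_noise(
    noise: NoiseModel, t: np.ndarray, n_channels: int, rng: np.random.Generator
) -> np.ndarray:
    """One (time, channel) noise realization in uM."""
    out = np.zeros((t.size, n_channels))
    for freq, amp in (noise.cardiac, noise.respiration, noise.mayer):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi, n_channels)
            out += amp * np.sin(2 * np.pi * freq * t[:, None] + phase[None, :])
    slope, slow_amp = noise.drift
    if slope != 0:
        out += slope * rng.uniform(-1, 1, n_channels)[None, :] * (t[:, None] / 60.0)
    if slow_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, n_channels)
        out += slow_amp * np.sin(2 * np.pi * t[:, None] / 600.0 + phase[None, :])
    if noise.white_sd > 0:
        out += rng.normal(0.0, noise.white_sd, (t.size, n_channels))
    return out


def simulate_hb(
    truth: SimTruth,
    noise: NoiseModel,
    schedule: Schedule,
    montage: Montage,
    rng: np.random.Generator | None = None,
) -> HbSeries:
    """Ground-truth concentration changes plus physiological noise.

    For each active (condition, channel): HbO = amplitude x unit-peak
    regressor of that condition's blocks, HbR = -hbr_ratio x HbO.  Noise is
    drawn independently per channel and per species.
    """
    truth.validate_against(montage)
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    fs = montage.sampling_rate_hz
    n = int(round(schedule.duration_s * fs))
    t = np.arange(n) / fs
    nchan = montage.n_channels
    ch_index = {cid: i for i, cid in enumerate(montage.channel_ids)}

    hbo = np.zeros((n, nchan))
    for cond in TASK_CONDITIONS:
        chans = truth.active_map.get(cond, frozenset())
        if not chans or not schedule.blocks_for(cond):
            continue
        reg = block_regressor(schedule, cond, fs, n, truth.hrf)
        for cid in chans:
            hbo[:, ch_index[cid]] += truth.hbo_amplitude_um * reg
    hbr = -truth.hbr_ratio * hbo

    hbo = hbo + _physio_noise(noise, t, nchan, rng)
    hbr = hbr + _physio_noise(noise, t, nchan, rng)
    return HbSeries(hbo=hbo, hbr=hbr, sampling_rate_hz=fs)


def forward_mbll(hb: HbSeries, params: MbllParams) -> ODSeries:
    """Forward Beer-Lambert: concentrations (uM) -> OD changes."""
    conc_mm = np.stack([hb.hbo, hb.hbr], axis=2) * 1e-3  # (T, C, species), mM
    path = params.pathlength_cm()  # (C, W)
    a = params.extinction[None, :, :] * path[:, None, :]  # (C, W, S)
    od = np.einsum("cws,tcs->tcw", a, conc_mm)
    return ODSeries(delta_od=od, sampling_rate_hz=hb.sampling_rate_hz)


def od_to_intensity(
    od: ODSeries,
    schedule: Schedule,
    montage: Montage,
    baseline_intensity: float | np.ndarray = 1.0,
) -> RawRecording:
    """Exponentiate OD changes to raw intensities: I = I0 * 10^(-dOD)."""
    i0 = np.asarray(baseline_intensity, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("baseline_intensity must be positive")
    intensity = i0 * np.power(10.0, -od.delta_od)
    return RawRecording(
        intensity=intensity,
        sampling_rate_hz=od.sampling_rate_hz,
        schedule=schedule,
        montage=montage,
    )


def add_motion(
    raw: RawRecording,
    noise: NoiseModel,
    seed: int,
) -> tuple[RawRecording, list[dict]]:
    """Inject motion artifacts; returns the recording and an artifact log.

    Spikes are brief multiplicative excursions of optode coupling
    (exponential decay, ~0.4 s) affecting both wavelengths of one channel;
    shifts are sustained multiplicative steps.  The multiplicative factor
    is exp(amplitude profile), which keeps intensity strictly positive and
    equals 1 + amp to first order.  Counts, times and channels are drawn
    from ``seed`` only, so the log is reproducible.
    """
    m = noise.motion
    rng = np.random.default_rng(seed)
    intensity = raw.intensity.copy()
    t = raw.time_s
    fs = raw.sampling_rate_hz
    duration_min = raw.n_samples / fs / 60.0
    log: list[dict] = []

    n_spikes = rng.poisson(m.spike_rate_per_min * duration_min) if m.spike_rate_per_min > 0 else 0
    for _ in range(n_spikes):
        ch = rng.integers(0, raw.n_channels)
        t0 = rng.uniform(0, t[-1])
        amp = m.spike_amp * (1.0 + abs(rng.normal(0, 0.5))) * rng.choice([-1.0, 1.0])
        profile = amp * np.exp(-np.abs(t - t0) / 0.4)
        intensity[:, ch, :] *= np.exp(profile)[:, None]
        log.append({"kind": "spike", "channel_id": raw.montage.channel_ids[ch], "time_s": float(t0), "amp": float(amp)})

    if m.shift_prob > 0:
        for ch in range(raw.n_channels):
            if rng.uniform() < m.shift_prob:
                t0 = rng.uniform(0, t[-1])
                step = 0.5 * m.spike_amp * rng.choice([-1.0, 1.0])
                intensity[t >= t0, ch, :] *= np.exp(step)
                log.append({"kind": "shift", "channel_id": raw.montage.channel_ids[ch], "time_s": float(t0), "amp": float(step)})

    out = RawRecording(
        intensity=intensity,
        sampling_rate_hz=raw.sampling_rate_hz,
        schedule=raw.schedule,
        montage=raw.montage,
    )
    return out, log


def simulate_recording(
    truth: SimTruth,
    noise: NoiseModel,
    schedule: Schedule,
    montage: Montage,
    mbll_params: MbllParams | None = None,
    seed: int | None = None,
    baseline_intensity: float = 1.0,
) -> tuple[RawRecording, HbSeries, list[dict]]:
    """Full forward chain: concentrations -> OD -> intensity -> motion.

    Returns (raw recording, noise-bearing ground-truth concentrations,
    motion artifact log).
    """
    if seed is None:
        seed = truth.seed
    ss = np.random.SeedSequence(seed)
    hb_seed, motion_seed = ss.spawn(2)
    hb = simulate_hb(truth, noise, schedule, montage, rng=np.random.default_rng(hb_seed))
    params = mbll_params if mbll_params is not None else default_mbll_params(montage)
    od = forward_mbll(hb, params)
    raw = od_to_intensity(od, schedule, montage, baseline_intensity)
    m = noise.motion
    if m.spike_rate_per_min > 0 or m.shift_prob > 0:
        raw, log = add_motion(raw, noise, seed=int(motion_seed.generate_state(1)[0] % (2**31)))
    else:
        log = []
    return raw, hb, log


def simulate_cohort(
    n_subjects: int,
    truth: SimTruth,
    noise: NoiseModel,
    montage: Montage | None = None,
    seed: int = 0,
    blocks_per_condition: int = 3,
    task_s: float = 60.0,
    rest_s: float = 40.0,
    cue_s: float = 10.0,
) -> list[tuple[RawRecording, SimTruth]]:
    """Simulate ``n_subjects`` independent recordings sharing one truth.

    Each subject gets an independent randomized block order and noise
    realization (sub-seeded from ``seed``); the activation map and effect
    sizes are shared, as in a group study.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if montage is None:
        montage = default_montage()
    cohort = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_subjects):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        schedule = build_schedule(
            sub_seed,
            conditions=TASK_CONDITIONS,
            blocks_per_condition=blocks_per_condition,
            task_s=task_s,
            rest_s=rest_s,
            cue_s=cue_s,
        )
        sub_truth = SimTruth(
            active_map=truth.active_map,
            hbo_amplitude_um=truth.hbo_amplitude_um,
            hbr_ratio=truth.hbr_ratio,
            hrf=truth.hrf,
            seed=sub_seed,
        )
        raw, _, _ = simulate_recording(sub_truth, noise, schedule, montage, seed=sub_seed)
        cohort.append((raw, sub_truth))
    return cohort
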