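"""Forward simulator: HRF, concentration model, Beer-Lambert forward map,
motion artifacts, and cohort generation."""

import numpy as np
import pytest

from nirsblock import (
    HRFParams,
    NoiseModel,
    SimTruth,
    bandpass,
    build_schedule,
    canonical_hrf,
    default_mbll_params,
    default_montage,
    forward_mbll,
    intensity_to_od,
    mbll,
    od_to_intensity,
    simulate_cohort,
    simulate_hb,
    simulate_recording,
)
from nirsblock.qc import cv_chan
from nirsblock.simulate import MotionParams, add_motion, block_regressor


class TestCanonicalHrf:
    def test_zero_at_onset(self):
        assert canonical_hrf(np.array([0.0]))[0] == 0.0

    def test_unit_peak_on_dense_grid(self):
        t = np.arange(0, 40, 0.01)
        assert canonical_hrf(t).max() == pytest.approx(1.0, abs=1e-6)

    def test_peak_location_matches_parameter(self):
        t = np.arange(0, 40, 0.01)
        for delay in (4.0, 6.0, 8.0):
            h = canonical_hrf(t, HRFParams(peak_delay_s=delay))
            assert t[np.argmax(h)] == pytest.approx(delay, abs=1.0)

    def test_undershoot_present(self):
        t = np.arange(0, 40, 0.01)
        assert canonical_hrf(t).min() < 0

    def test_empty_grid_error(self):
        with pytest.raises(ValueError):
            canonical_hrf(np.array([]))


class TestSimulateHb:
    def test_noiseless_active_channel_is_scaled_regressor(self, montage_5hz, schedule):
        truth = SimTruth(active_map={"ME": frozenset({3})}, hbo_amplitude_um=0.7, seed=0)
        hb = simulate_hb(truth, NoiseModel.silent(), schedule, montage_5hz)
        n = hb.n_samples
        reg = block_regressor(schedule, "ME", 5.0, n)
        np.testing.assert_allclose(hb.hbo[:, 2], 0.7 * reg, atol=1e-12)
        np.testing.assert_allclose(hb.hbr[:, 2], -truth.hbr_ratio * 0.7 * reg, atol=1e-12)
        assert np.all(hb.hbo[:, 0] == 0)  # inactive channel silent

    def test_unit_peak_amplitude_convention(self, montage_5hz, schedule):
        truth = SimTruth(active_map={"MI": frozenset({5})}, hbo_amplitude_um=0.5, seed=0)
        hb = simulate_hb(truth, NoiseModel.silent(), schedule, montage_5hz)
        assert hb.hbo[:, 4].max() == pytest.approx(0.5, rel=1e-6)

    def test_hbo_hbr_anticorrelated_noiseless(self, montage_5hz, schedule):
        truth = SimTruth(active_map={"ME": frozenset({1})}, seed=0)
        hb = simulate_hb(truth, NoiseModel.silent(), schedule, montage_5hz)
        r = np.corrcoef(hb.hbo[:, 0], hb.hbr[:, 0])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_amplitude_null_simulation(self, montage_5hz, schedule):
        truth = SimTruth(active_map={}, hbo_amplitude_um=0.0, seed=4)
        hb = simulate_hb(truth, NoiseModel(), schedule, montage_5hz)
        # pure noise: no task-locked structure; overall means are near zero
        # relative to the oscillation amplitudes
        assert abs(hb.hbo.mean()) < 0.2

    def test_reproducible_from_seed(self, montage_5hz, schedule):
        truth = SimTruth(seed=9)
        a = simulate_hb(truth, NoiseModel(), schedule, montage_5hz)
        b = simulate_hb(truth, NoiseModel(), schedule, montage_5hz)
        np.testing.assert_array_equal(a.hbo, b.hbo)

    def test_unknown_channel_in_active_map(self, montage_5hz, schedule):
        truth = SimTruth(active_map={"ME": frozenset({99})})
        with pytest.raises(ValueError, match="99"):
            simulate_hb(truth, NoiseModel.silent(), schedule, montage_5hz)


class TestForwardMbll:
    def test_zero_concentration_zero_od(self, noiseless_recording, mbll_params):
        _, hb, _ = noiseless_recording
        zero = type(hb)(hbo=np.zeros_like(hb.hbo), hbr=np.zeros_like(hb.hbr),
                        sampling_rate_hz=hb.sampling_rate_hz)
        od = forward_mbll(zero, mbll_params)
        assert np.all(od.delta_od == 0)

    def test_linearity(self, noiseless_recording, mbll_params):
        _, hb, _ = noiseless_recording
        od1 = forward_mbll(hb, mbll_params)
        doubled = type(hb)(hbo=2 * hb.hbo, hbr=2 * hb.hbr, sampling_rate_hz=hb.sampling_rate_hz)
        od2 = forward_mbll(doubled, mbll_params)
        np.testing.assert_allclose(od2.delta_od, 2 * od1.delta_od, rtol=1e-12)

    def test_inversion_round_trip(self, mbll_params):
        """forward MBLL then the 2x2 linear-solve inversion is the identity."""
        rng = np.random.default_rng(0)
        from nirsblock.preprocess import HbSeries

        hb = HbSeries(hbo=rng.normal(0, 1, (200, 16)), hbr=rng.normal(0, 1, (200, 16)),
                      sampling_rate_hz=5.0)
        rec = mbll(forward_mbll(hb, mbll_params), mbll_params)
        np.testing.assert_allclose(rec.hbo, hb.hbo, rtol=1e-9)
        np.testing.assert_allclose(rec.hbr, hb.hbr, rtol=1e-9)


class TestOdIntensity:
    def test_zero_od_gives_baseline(self, montage_5hz, schedule, noiseless_recording):
        from nirsblock.preprocess import ODSeries

        n = int(schedule.duration_s * 5)
        od = ODSeries(delta_od=np.zeros((n, 16, 2)), sampling_rate_hz=5.0)
        raw = od_to_intensity(od, schedule, montage_5hz, baseline_intensity=2.5)
        assert np.all(raw.intensity == 2.5)

    def test_od_one_divides_by_ten(self, montage_5hz, schedule):
        from nirsblock.preprocess import ODSeries

        n = int(schedule.duration_s * 5)
        arr = np.zeros((n, 16, 2))
        arr[100, 0, 0] = 1.0
        od = ODSeries(delta_od=arr, sampling_rate_hz=5.0)
        raw = od_to_intensity(od, schedule, montage_5hz)
        assert raw.intensity[100, 0, 0] == pytest.approx(0.1)

    def test_round_trip_mean_referenced(self, noiseless_recording, mbll_params):
        """od -> intensity -> od recovers the OD up to its mean (the I0
        reference), to 1e-12."""
        raw, hb, _ = noiseless_recording
        od_true = forward_mbll(hb, mbll_params)
        recovered = intensity_to_od(raw)
        a = od_true.delta_od - od_true.delta_od.mean(axis=0)
        b = recovered.delta_od - recovered.delta_od.mean(axis=0)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestAddMotion:
    def test_noop_when_disabled(self, noisy_recording):
        raw, _, _ = noisy_recording
        quiet = NoiseModel(motion=MotionParams(0.0, 0.0, 0.0))
        out, log = add_motion(raw, quiet, seed=3)
        np.testing.assert_array_equal(out.intensity, raw.intensity)
        assert log == []

    def test_spike_increases_cv(self, noiseless_recording):
        raw, _, _ = noiseless_recording
        heavy = NoiseModel(motion=MotionParams(spike_rate_per_min=20.0, spike_amp=0.8, shift_prob=0.0))
        out, log = add_motion(raw, heavy, seed=3)
        assert len(log) > 0
        assert cv_chan(out).max() > cv_chan(raw).max()

    def test_deterministic_artifact_log(self, noisy_recording):
        raw, _, _ = noisy_recording
        nm = NoiseModel()
        _, log1 = add_motion(raw, nm, seed=7)
        _, log2 = add_motion(raw, nm, seed=7)
        assert log1 == log2


class TestFullRoundTrip:
    def test_noiseless_pipeline_recovers_truth(self, noiseless_recording, mbll_params):
        """simulate -> forward MBLL -> intensity -> OD -> inverse MBLL
        reproduces ground-truth concentrations (recording-mean reference)
        to 1e-6 uM, without filtering or CBSI."""
        raw, hb_true, _ = noiseless_recording
        hb_rec = mbll(intensity_to_od(raw), mbll_params)
        for true, rec in ((hb_true.hbo, hb_rec.hbo), (hb_true.hbr, hb_rec.hbr)):
            a = true - true.mean(axis=0)
            b = rec - rec.mean(axis=0)
            np.testing.assert_allclose(a, b, atol=1e-6)


class TestSimulateCohort:
    def test_deterministic(self, montage_5hz):
        a = simulate_cohort(2, SimTruth(), NoiseModel(), montage_5hz, seed=5)
        b = simulate_cohort(2, SimTruth(), NoiseModel(), montage_5hz, seed=5)
        for (ra, _), (rb, _) in zip(a, b):
            np.testing.assert_array_equal(ra.intensity, rb.intensity)

    def test_subjects_have_distinct_block_orders(self, montage_5hz):
        cohort = simulate_cohort(4, SimTruth(), NoiseModel.silent(), montage_5hz, seed=5)
        orders = {tuple(e.condition for e in raw.schedule.task_blocks) for raw, _ in cohort}
        assert len(orders) > 1

    def test_cohort_size_configurable_to_study_n(self):
        # a 29-subject cohort (the full study size) at coarse sampling
        cohort = simulate_cohort(29, SimTruth(), NoiseModel(), default_montage(2.0), seed=1)
        assert len(cohort) == 29
        assert len({t.seed for _, t in cohort}) == 29

    def test_empty_cohort_rejected(self, montage_5hz):
        with pytest.raises(ValueError):
            simulate_cohort(0, SimTruth(), NoiseModel(), montage_5hz)


def test_active_channels_exceed_inactive_in_expectation():
    """With physiological noise and the 0.01-0.2 Hz band-pass, task-locked
    early means on active channels exceed inactive ones on average over
    50 seeded replicates."""
    from nirsblock.pipeline import PipelineConfig, process_recording

    montage = default_montage(4.0)
    cfg = PipelineConfig(sampling_rate_hz=4.0)
    active = frozenset({2, 4})
    truth0 = SimTruth(active_map={"ME": active}, hbo_amplitude_um=0.5)
    noise = NoiseModel(motion=MotionParams(0.0, 0.0, 0.0))
    diffs = []
    for seed in range(50):
        schedule = build_schedule(seed)
        raw, _, _ = simulate_recording(
            SimTruth(active_map=truth0.active_map, seed=seed), noise, schedule, montage, seed=seed
        )
        summary, _ = process_recording(raw, "s", cfg)
        sub = summary[(summary.condition == "ME") & (summary.phase == "early")]
        act = sub[sub.channel_id.isin(active)]["value"].mean()
        inact = sub[~sub.channel_id.isin(active)]["value"].mean()
        diffs.append(act - inact)
    assert np.mean(diffs) > 0
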