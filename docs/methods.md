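# Methods

This note documents the models, conventions and numerical choices behind
`nirsblock`, and what the simulation-based validation does and does not
establish.

## Protocol model

The montage is 16 source-detector channels (8 sources, 8 detectors,
3.0 cm separation) partitioned as left PMC {1–4}, left SMA {5, 6}, right
SMA {7, 8}, right PMC {9–12}, left M1 {13, 14}, right M1 {15, 16}. Only
this region/hemisphere partition carries analytical meaning; the
source/detector indices are bookkeeping, and no scalp-coordinate geometry
is modelled.

A session is 12 task blocks — 3 per condition (ME, MI, AO, MVF) in a
uniformly shuffled order — each consisting of a 10-s instruction cue, 60 s
of task, and 40 s of rest, giving a fixed 1320-s session. The cue is
recorded as its own event but treated as rest analytically; it doubles as
the pre-onset baseline window. The shuffle imposes no constraint against
repeated conditions back-to-back. The sampling rate is not a property of
the protocol; it defaults to 10 Hz (typical for continuous-wave
instruments) and is reduced to 4 Hz in the repeated-simulation studies,
which only needs to resolve the 0.01–0.2 Hz analysis band and the ~1 Hz
cardiac line it must reject.

## Forward simulator

The simulator is the package's validation instrument: it generates raw
recordings from known ground truth so the analysis chain can be scored by
parameter recovery.

* **Response model.** Each condition's regressor is the convolution of
  its block boxcar with a canonical double-gamma HRF (positive-lobe mode
  6 s, undershoot mode 16 s, undershoot ratio 1/6, dispersion 1 s; zero at
  onset). The convolution is normalized so a single block's response peaks
  at exactly 1, making the amplitude parameter the peak ΔHbO in µM
  (default 0.5 µM, a comfortable but non-trivial group effect at n = 12).
  ΔHbR = −⅓ × ΔHbO, reflecting the smaller deoxygenation response.
* **Noise.** Additive, per channel and per species, each sinusoid with a
  random phase: cardiac (1.0 Hz, 0.30 µM), respiration (0.25 Hz, 0.15 µM),
  Mayer waves (0.10 Hz, 0.10 µM — deliberately inside the analysis band),
  linear drift (±0.05 µM/min) plus a slow 10-min oscillation (0.15 µM),
  and white noise (SD 0.05 µM). These magnitudes are calibration choices,
  not measurements; they sit in config, and the Mayer and white components
  are what make detection statistical rather than deterministic.
* **Optics.** Concentrations map to optical density through the forward
  Beer–Lambert relation and to intensity via I = I₀·10^(−ΔOD) with
  I₀ = 1 detector unit (only ratios matter). Motion artifacts multiply
  intensity by exp(a·profile) — brief exponential-decay spikes (~0.4 s,
  default 0.5/min at 15% amplitude) and sustained steps (2% of channels
  per recording) — which keeps intensity positive while matching how
  movement perturbs optode coupling.
* **Reproducibility.** Every draw descends from a `numpy` `SeedSequence`;
  cohorts spawn per-subject child seeds, so subjects get independent
  block orders and noise while remaining bit-reproducible.

What the simulator does **not** emulate: scalp/superficial hemodynamic
compartments and short-separation channels, photon-transport physics,
serially correlated (1/f) noise, subject-specific HRF variability, and
amplitude heterogeneity across subjects. Passing recovery tests therefore
demonstrates the correctness and calibration of the analysis chain under
the stated noise model, not performance on any particular real dataset.

## Preprocessing conventions

* **I₀ reference.** OD is referenced to the full-recording mean intensity
  (robust to initial transients). Concentrations are therefore relative
  to the recording mean; the per-block baseline subtraction later removes
  any constant offset, so the reference choice cannot affect results.
* **Filter.** 4th-order Butterworth band-pass (0.01–0.2 Hz), applied
  forward-backward (`sosfiltfilt`) on OD before inversion. Zero phase
  matters because the early/late phase split is onset-relative; a causal
  filter would delay the response into the wrong window. Filtering OD vs
  concentrations commutes through the linear Beer–Lambert inversion.
* **Extinction coefficients.** Gratzer/Prahl values at 760 nm
  (ε_HbO = 0.5866, ε_HbR = 1.5485 mM⁻¹cm⁻¹) and 850 nm (1.0580, 0.6913);
  DPF = 6.0 at both wavelengths. These only rescale concentrations — every
  inferential decision is invariant to them.
* **CBSI.** Applied to the continuous filtered series per channel (not
  per epoch), with α = SD(HbO)/SD(HbR) over the whole recording. A
  zero-variance channel makes α undefined; the default is a hard error,
  with a `skip` mode (channel passed through, α = NaN) for deliberately
  noise-free simulations where null channels are exactly constant.
* **QC.** CV uses population SD (the conventional signal-quality
  descriptor); thresholds are strict inequalities (15%/10%), so a channel
  at exactly the threshold is kept. A trial-level violation rejects the
  whole channel for that subject. Under the default noise model the CV
  values sit at 1–3% and the null rejection rate is ~0; the screens
  engage on motion-corrupted recordings, which the artifact tests
  construct explicitly.

## Epoching and phases

Blocks are extracted over [−10 s, 60 s) around onset; the mean of
[−10, 0) (the cue) is the baseline. Windows are half-open at sample
resolution — a sample belongs to [a, b) iff its onset-relative time t
satisfies a ≤ t < b — so the 30-s boundary sample is counted exactly once
and early/late partition the block. Early = [0, 30), late = [30, 60);
both are config-exposed (an alternative 40–60 s late window is one
argument away). Cells from QC-rejected channels are missing (NaN), never
zero.

## Statistics

* **Activation.** One-sample, one-sided t (alternative mean > 0) of the
  subject phase means per channel; BH step-up across the 16-channel
  family, separately per (condition, phase) — families are not pooled
  across conditions. Missing subject cells are dropped pairwise with n
  recorded; an all-constant channel is error-flagged rather than given an
  infinite t (relevant only in noise-free simulations).
* **BH tie-break.** Adjusted p-values use p̃_(i) = min_{j≥i} m·p_(j)/j;
  rejection uses the algebraically equivalent step-up comparison
  p_(k) ≤ k·q/m directly, because the division-based form can differ by
  one ulp at exact threshold ties.
* **Condition comparisons.** Per channel: one-way repeated-measures
  ANOVA across the four conditions (subjects with complete data,
  listwise within channel; degenerate all-equal input is reported as
  F = 0), then paired t-tests for the six pairs, Bonferroni-corrected by
  6 within the channel (the correction attaches to the pairs, not the
  16 channels; both family choices are config-exposed). A full
  multivariate test across 16 channels at cohort sizes of 12–29 would be
  near-degenerate, so the omnibus is deliberately univariate per channel.
* **Summary table.** Across-subject mean ± sample SD (n − 1) per
  channel × condition of the early-phase ΔHbO, with FDR significance
  flags; CV is the only place population SD is used.

## Validation studies and problem sizes

The repeated-simulation studies run the entire forward-model → pipeline
path (nothing is shortcut at the concentration level) at 4 Hz with motion
disabled, since they measure the statistical chain and the QC screen is
exercised separately:

* **Error control:** 500 cohorts × 12 subjects, 8 channels active under
  ME at 0.5 µM and 8 null; mean false-discovery proportion of the
  early-phase activation test is compared against q = 0.05. With half the
  family null, BH's expected FDR is ≤ q/2 under independence; the
  measured value (~0.01) is comfortably below q.
* **Power:** detection sensitivity at 0.1, 0.25 and 0.5 µM, 200
  replicates each, same seed root per level so only amplitude varies;
  sensitivity must be nondecreasing.
* **Exact recovery:** a noise-free cohort must yield sensitivity 1.0 and
  FDP 0.0 end-to-end, and the noiseless simulate → forward → invert round
  trip must agree to 10⁻⁶ µM (10⁻⁹ relative for the linear algebra alone).

## Known limitations

* The noise model is stationary and sinusoidal-plus-white; real fNIRS
  noise has 1/f structure, superficial-layer contamination and
  subject-level variance components that would lower power relative to
  these simulations.
* Channel positions are symbolic; no spatial statistics (e.g. cluster
  inference, MNI mapping) are possible or attempted.
* The SNIRF reader covers only single-block continuous-wave amplitude
  files with two wavelengths.
* Motion handling is screen-and-reject plus CBSI; no spline/wavelet/TDDR
  artifact repair is provided.
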