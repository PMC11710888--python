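# nirsblock

Block-design functional near-infrared spectroscopy (fNIRS) analysis for
motor-task studies, with a forward simulator for end-to-end validation.

fNIRS measures cortical hemodynamics through light attenuation at two
wavelengths (here 760 and 850 nm) across source-detector channels on the
scalp. `nirsblock` implements the complete analysis chain for a randomized
block protocol in which subjects perform a reaching-and-grasping task under
four motor-acquisition modes — motor execution (ME), motor imagery (MI),
action observation (AO) and mirror visual feedback (MVF) — over 16 channels
covering bilateral premotor cortex (PMC), supplementary motor area (SMA)
and primary motor cortex (M1):

1. **Quality control** — relative coefficient of variation
   (CV = σ/μ × 100%, population SD) of the raw intensities, per channel
   over the whole recording (CV_chan) and within each 60-s task block
   (CV_trial); channels with CV_chan > 15% or any CV_trial > 10% at either
   wavelength are rejected.
2. **Optical density** — ΔOD(t, λ) = −log₁₀(I(t, λ)/I₀(λ)) against the
   recording-mean intensity.
3. **Band-pass filtering** — zero-phase 4th-order Butterworth, 0.01–0.2 Hz,
   removing cardiac (~1 Hz), respiratory (~0.25 Hz) and slow drift.
4. **Modified Beer–Lambert inversion** — per sample and channel, solve

   ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF(λ)

   for the oxy-/deoxy-hemoglobin concentration changes (µM), with
   extinction coefficients ε from the standard Gratzer/Prahl compilation,
   source-detector separation d = 3.0 cm and differential pathlength
   factor DPF = 6.0.
5. **CBSI** — correlation-based signal improvement: with
   α = SD(HbO)/SD(HbR), HbO′ = (HbO − α·HbR)/2 and HbR′ = −HbO′/α, which
   removes the common-mode (motion-like) component and enforces the
   physiological HbO/HbR anticorrelation. Hbdiff = HbO − HbR is carried
   alongside.
6. **Epoching** — each 60-s block is extracted with the 10 s of
   pre-onset cue as baseline (its mean subtracted), block-averaged per
   condition, and summarized as mean ΔHbO over the **early phase**
   (0–30 s after onset) and **late phase** (30–60 s).
7. **Group statistics** — per (condition, phase): channel-wise one-sided
   one-sample t-tests of the subject phase means against zero
   (activation = HbO increase), Benjamini–Hochberg FDR at q = 0.05 across
   the 16-channel family; plus per-channel repeated-measures ANOVA across
   the four conditions with Bonferroni-corrected paired contrasts for the
   six condition pairs.

No public recordings exist for this protocol, so the package bundles a
forward simulator (`nirsblock.simulate`): condition regressors are 60-s
boxcars convolved with a canonical double-gamma hemodynamic response
(unit peak, so the amplitude parameter is the peak ΔHbO in µM),
HbR = −⅓·HbO, physiological noise (cardiac, respiration, Mayer waves,
drift, white noise) is added per species and channel, concentrations are
pushed through the forward Beer–Lambert map to detector intensities, and
motion spikes/steps perturb the optode coupling multiplicatively. Ground
truth is retained, so the whole pipeline is validated by parameter
recovery rather than against withheld data.

## Worked example

Simulate a 12-subject cohort, analyze it, and compare the significant
channels against the simulation ground truth:

```python
from nirsblock.pipeline import PipelineConfig, run_simulate, run_analyze, run_recover
from nirsblock.montage import default_montage
from nirsblock import io as nio

cfg = PipelineConfig(n_subjects=12, seed=1, sampling_rate_hz=4.0)
paths = run_simulate("demo/sim", cfg)
res = run_analyze(paths["raw"], paths["events"], default_montage(4.0),
                  "demo/results", cfg)
truth = nio.read_truth("demo/sim/truth.json")
print(run_recover(truth, res["activation"])["pooled"])
```

`demo/results/group_summary.tsv` begins:

```
channel	AO	ME	MI	MVF
L't PMC (Ch1)	-0.0149463 +/- 0.0145266	0.143799 +/- 0.0242519 *	0.127296 +/- 0.0257994 *	0.122184 +/- 0.0401211 *
L't PMC (Ch2)	0.00151582 +/- 0.00836168	0.0103788 +/- 0.0343208	0.00365595 +/- 0.0221268	0.00346805 +/- 0.0215307
L't PMC (Ch3)	-0.00688025 +/- 0.00831974	-0.00721541 +/- 0.0289153	0.00620483 +/- 0.0133317	0.115881 +/- 0.016292 *
```

Each cell is the across-subject mean ± SD of the early-phase ΔHbO (µM,
after filtering and CBSI — an attenuated version of the simulated 0.5 µM
peak); `*` marks channels significant after FDR correction. Channel 1 was
simulated active under ME, MI and MVF but not AO, and is flagged exactly
there. The recovery report pools all four conditions:

```python
{'true_positives': 28, 'false_positives': 0, 'false_negatives': 0,
 'true_negatives': 36, 'sensitivity': 1.0, 'fdp': 0.0}
```

i.e. all 28 truly active (condition, channel) pairs were detected with no
false positives.

The same workflow is available from a shell:

```bash
nirsblock simulate --out demo/sim --n-subjects 12 --seed 1
nirsblock analyze --raw 'demo/sim/sub-01_raw.tsv' --events 'demo/sim/sub-01_events.tsv' \
    --montage demo/sim/montage.yaml --out demo/results   # repeat --raw/--events per subject
nirsblock recover --truth demo/sim/truth.json --results demo/results
```

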