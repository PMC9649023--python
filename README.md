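# coldface

Analysis pipeline for **Cold Face Test (CFT) / MIST psychophysiology
studies**: from raw single-lead ECG and salivary cortisol samples to the
condition-comparison statistics, together with a synthetic-cohort generator
that provides ground truth for every stage.

The scientific setting: applying a cold stimulus to the face triggers the
trigeminal–vagal reflex arc and a transient bradycardia (heart-rate drop of
roughly 22.5 % ± 9.0 %, onset ≈ 5.6 s, peak ≈ 35.8 s after stimulus onset).
Used as an *intervention* right before each arithmetic-stress block of the
Montreal Imaging Stress Task (MIST, 3 phases × {BL, RP/CFI, AT, FB}
subphases), this parasympathetic stimulation may blunt the acute stress
response — visible in heart rate, time-domain HRV and the salivary cortisol
curve. The package implements the complete computational chain such a study
needs, for researchers in psychophysiology and affective science.

## What it computes

**ECG → RR.** 3–45 Hz zero-lag FIR bandpass; Hamilton-rule QRS detection
(adaptive peak/noise thresholds, 200 ms refractory, search-back);
Lipponen–Tarvainen beat correction (ectopic / missed / extra / misaligned);
RR artifact rules — remove intervals at HR ≤ 45 or ≥ 200 bpm, RR outliers
≥ 2.576 σ and successive-difference outliers ≥ 1.96 σ, imputing removals by
linear interpolation.

**HRV features per subphase.** HR = 60000 / mean(RR), RMSSD =
√(mean ΔRRᵢ²), pRR50 = % of |ΔRRᵢ| > 50 ms; each normalised per participant
to the 15-min Global Baseline (BL_Glo) as percent change (ΔHR etc.); and
the temporal statistic

> t̂_Glo = duration-weighted % of subphase time during which the measure,
> computed over N = 10-beat sliding windows, exceeds its BL_Glo value.

**Cortisol metrics** over samples S1..S6 at 0, 30, 40, 50, 60, 70 min from
MIST start:

> AUC_G = Σᵢ (cᵢ + cᵢ₊₁)/2 · (tᵢ₊₁ − tᵢ)  (trapezoid, 5 intervals),
> AUC_I = AUC_G − c₁·(t₆ − t₁),
> Δc_max = 100·(max c₂..₆ − c₁)/c₁,  a_S1S4 = (c₄ − c₁)/(t₄ − t₁)

plus the cohort-level S0 screen (flag > mean + 3 SD).

**Gated statistics.** Shapiro–Wilk gates t-tests vs Mann–Whitney-U /
Wilcoxon; Levene gates pooled vs Welch t; repeated-measures and mixed
(split-plot) ANOVA with Mauchly-gated Greenhouse–Geisser correction;
Bonferroni post-hocs within each measure; Hedges' g and partial η² with
95 % noncentral CIs.

**Synthetic cohorts.** Programmed stress tachycardia, CFT bradycardia
kinetics, Control baseline drift, RMSSD-calibrated beat jitter, cortisol
response curves peaking 10–20 min post-stressor — with a truth manifest,
per-participant reproducible substreams, and optional planted exclusion
archetypes (CFT non-responder, S0 outlier, HR hyper-responder).

## Worked example

`python examples/05_full_study.py` simulates the study's 28-participant
cohort (13 Control, 12 CFT, plus the three planted exclusion archetypes),
applies the exclusion rules and runs the statistics battery:

```
28 participants simulated, 25 retained after exclusions:
  excluded P26: cft_nonresponse
  excluded P27: s0_outlier
  excluded P28: hr_outlier

Condition x MIST-phase interaction on BL heart rate: F(1.23, 28.22) = 122.50, p = 0.0000, partial eta^2 = 0.842
dc_max CFT vs Control: t-test, p = 0.0021, Hedges' g = -1.34
```

Exactly the three planted archetypes are excluded (25 retained). The
Control condition's baseline heart rate drifts upward across MIST phases
while the CFT condition recovers to its resting level, producing the
Condition × MIST-phase interaction (GG-corrected dfs because sphericity was
rejected); the CFT cortisol response is blunted, giving a large negative
Hedges' g for the maximum cortisol increase. The synthetic world is cleaner
than real physiology, so effect sizes run larger than in field data.

Other examples: `01_simulate_cohort.py` (bundle layout + ground truth),
`02_ecg_pipeline.py` (ECG → clean RR), `03_hrv_and_tglo.py` (normalised
measures and t̂_Glo), `04_cortisol_metrics.py` (AUCs and response metrics).

A thin CLI wraps the same pipeline:

```bash
coldface simulate --out cohort/ --seed 1 --with-ecg
coldface process  --input cohort/ --out results/
coldface report   --results results/
```

## Layout

- `src/coldface/` — `protocol` (study timeline), `ecg` (I/O, filter, RR
  rules), `qrs` (Hamilton detector), `rr_correction`
  (Lipponen–Tarvainen), `hrv`, `cortisol`, `stats`, `synth`, `pipeline`,
  `cli`
- `docs/methods.md` — model assumptions, parameter choices, numerical
  decisions, limitations
- `examples/`, `tests/`, `scripts/acceptance.py`
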