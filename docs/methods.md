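# Methods

This note documents the models, the defaults and the numerical decisions
behind `coldface`, and what the synthetic-data tests do and do not show
about real recordings.

## Study timeline model

The session clock starts at the beginning of the 15-min Global Baseline;
all event times are seconds on that clock. The MIST runs as three
contiguous phases of BL (1 min) → RP/CFI (2 min) → AT (4 min) → FB
(default 2.5 min, the middle of the 2–3 min range; configurable). All
intervals are half-open `[start, end)` so a beat on a boundary belongs to
exactly one subphase and concatenated subphase slices partition the phase.
Gaps between FB end and the next BL are not modelled (segments are
contiguous); the MIST start defaults to the Global Baseline end but can be
placed later. Saliva samples S0..S6 sit at −20, 0, 30, 40, 50, 60, 70 min
relative to MIST start (S0's exact pre-protocol offset is arbitrary; it
never enters a curve metric).

## ECG processing

**Filter.** A wearable-firmware-style "second-order FIR bandpass" cannot
realise a useful 3–45 Hz band, so the filter is a linear-phase FIR
(Hamming-window design) whose order is configurable; the default — two
seconds of taps, forced odd — gives ≥ 20 dB attenuation at DC and at
50/60 Hz while keeping the passband within ±1 dB. Symmetric taps are
applied centred (`mode="same"` convolution), which cancels the group delay
exactly, so R-peak times are not shifted and output length equals input
length.

**QRS detection** follows the Hamilton open-source rules: detection
function = 80 ms moving average of the absolute first difference;
candidate peaks ≥ 200 ms apart classified against a threshold placed at
0.3125 of the way from the running noise-peak mean to the running QRS-peak
mean (last 8 each); a close follower (< 360 ms) under half the previous
QRS height is treated as a T wave; when an RR gap exceeds 1.5× the running
mean RR, the largest rejected candidate above half threshold is rescued
(search-back). Detections are snapped to the local |ECG| extremum
(±100 ms). All thresholds are relative, so detection is invariant to
amplitude scaling. A flat signal yields an empty series.

**Beat correction** implements the Lipponen–Tarvainen decision rules:
successive RR differences normalised by a time-varying threshold (5.2 ×
quartile deviation over a 91-beat window), deviations from an 11-beat
running median, ectopic short-long/long-short patterns in the
(dRR, neighbour-dRR) subspace (constants c₁ = 0.13, c₂ = 0.17), missed
beats (interval ≈ 2× local median → split), extra beats (adjacent pair ≈
local median → merge), and misaligned detections (re-centred). Corrections
are applied one at a time, re-evaluating the series after each, and
logged. Because beat jitter has Gaussian tails, an isolated re-centring at
the decision threshold can occur even on artifact-free data (order 1 in
10³–10⁴ beats); the tests assert near-identity rather than strict no-op on
clean series.

**RR artifact rules.** Applied once each, in order: (1) HR ≤ 45 or
≥ 200 bpm; (2) RR ≥ 2.576 σ from the mean RR; (3) successive difference
≥ 1.96 σ of the differences (the later interval flagged). σ is the plain
SD (mean-based; the rule description names σ, not a robust scale) over the
per-participant recording, re-estimated over the surviving intervals after
each stage so that gross artifacts caught early cannot inflate later
estimates. σ = 0 (constant series) disables the statistical rules. Removed
intervals are imputed by linear interpolation between surviving neighbours
(nearest-value extension at the edges); flags record which rule fired and
the beat count never changes. Intervals flagged on input stay flagged, are
excluded from the σ estimates and are never re-flagged — but exact
idempotence of the *statistical* rules is impossible for one-shot
fixed-quantile removal (removing a tail shrinks σ, so a second pass can
always find new near-threshold values; iterating to a fixed point instead
cascades to ≈ 20 % removal on ordinary beat jitter, since the 1.96 σ rule
removes 5 % of normal data per pass by construction). The implementation
therefore guarantees the weaker, practically relevant invariants above.

Note the 1.96 σ difference rule removes ≈ 5 % of *clean* intervals by
construction; this mildly biases RMSSD/pRR50 downward everywhere, which is
inherent to the procedure and affects both conditions equally.

## HRV measures and t̂_Glo

HR, RMSSD and pRR50 are computed per subphase (pRR50 strictly "> 50 ms";
pRR50 and pNN50 name the same statistic). Normalisation is percent change
against the participant's untrimmed 15-min Global Baseline; a zero
baseline (possible for pRR50) makes the normalised value undefined rather
than infinite.

t̂_Glo uses windows of N = 10 *RR intervals* advancing one beat at a time
(10 raw ECG samples would span 39 ms and cannot carry HRV). "Percentage of
time" is taken literally: each interval's above-baseline indicator is the
mean over the up-to-N windows covering it, and the subphase fraction is
the RR-duration-weighted average of those per-interval fractions. Ties
count as not-above. The baseline reference is the subphase-level measure
over the whole Global Baseline, not a windowed distribution.

**Peak bradycardia** is the minimum 10-beat windowed HR during a CFI
subphase, as percent decrease from the preceding BL subphase's mean HR.
It is measured on the beat-corrected series *before* the statistical
artifact rules: those rules exist to excise ectopic artifacts, and for
genuinely deep dips (dip HR near or below the 45 bpm bound) they would
censor the very extremum being measured and replace it with interpolated
values. On cleaned series the same estimator is exact whenever the dip
stays above the artifact bound.

## Cortisol metrics

AUC_G is the trapezoid over the six analysis samples (five intervals —
the standard area-under-the-curve-with-respect-to-ground); AUC_I
subtracts the baseline rectangle c₁·(t₆ − t₁) and may be negative.
Δc_max is expressed as percent of c₁ (the absolute difference is carried
alongside); a_S1S4 is the two-point slope. S0 is used only for the cohort
screen (flag > mean + 3 SD, computed once over everyone; an SD of zero
flags nobody, and a cohort below n = 3 is refused — note an included
outlier can reach z > 3 only when n ≥ 11, since max z = (n−1)/√n).

## Statistics engine

Two-sample comparisons: Shapiro–Wilk per group at α = 0.05 (the gate α is
configurable separately from the test α); a violation routes to the
two-sided Mann–Whitney U, otherwise Levene routes to the pooled or Welch
t-test (Welch dfs are fractional). Paired comparisons gate on the
differences and route to Wilcoxon signed-rank (Pratt zero-handling). An
exactly constant non-zero difference vector is reported as a deterministic
shift (infinite t, p = 0) rather than crashing the gate.

RM ANOVA (one within factor) and mixed ANOVA (one between × one within —
the designs used in every analysis here) are computed from the classical
sums-of-squares decompositions. Greenhouse–Geisser ε comes from the sample
covariance of the subject × level table; the Mauchly statistic from the
eigenvalues of the double-centred covariance with the standard f- and
second-order corrections to the χ² approximation. When Mauchly rejects at
the gate level, both dfs of the within-effect and interaction F-tests are
multiplied by ε. With two within levels sphericity holds trivially
(ε = 1). Both ANOVAs agree with pingouin to ~10⁻¹⁴ on random tables (test
suite cross-check).

Effect sizes: Hedges' g with the exact gamma-function bias correction
(two-sample on the pooled SD; paired on the difference scale, d_z — the
pooled-SD paired variant is deliberately not the default), CIs by
noncentral-t inversion; partial η² = SS_eff/(SS_eff + SS_err) with 95 %
CIs by noncentral-F inversion (95 % rather than the 90 % sometimes used
for η², matching the reporting convention adopted here). Rank-test
results still report Hedges' g so effect sizes are comparable across gate
branches. Bonferroni post-hocs multiply by the number of comparisons in
the family produced by one call (all level pairs of one measure);
families are not pooled across measures or subphases.

Under null simulations the full gated two-sample procedure's rejection
rate at α = 0.05 stays within the binomial 95 % band at 2,000 replicates
(acceptance suite).

## Synthetic cohort generator

The generator's defaults are the study conditions; per-participant
substreams (`default_rng([seed, index])`) make each participant
individually reproducible under one global seed.

| parameter | default | rationale |
|---|---|---|
| baseline HR | 70 ± 8 bpm | resting HR of young, healthy adults |
| AT peak tachycardia | 26/33/39 % (± 5 between subjects) | escalating stress response across MIST phases |
| AT ramp / sustain | 60 s to peak, then → 85 % of peak | peak tachycardia within the first AT minute, elevated thereafter |
| FB recovery τ | 40 s | cardiac recovery toward the phase baseline during feedback |
| CFT dip | onset 5.6 s, peak 35.8 s, depth 22.5 ± 9 %, recovery τ 10 s | cold-face bradycardia kinetics in healthy adults; fast recovery after stimulus end |
| Control BL drift | 0/8/15 % (± 3) per phase | incomplete between-phase recovery in the Control condition; free parameters (only depicted graphically in the source data), configurable to 0 |
| RMSSD target | 45 ms | typical short-term HRV for this age group |
| cortisol | c₁ 5 ± 1.5 nmol/L; amplitude 70 % (Control) / 5 % (CFT) ± 25; onset +10 min, peak 15 min post-stressor; noise 0.5 nmol/L | afternoon salivary baseline; stress response peaking in the S3–S4 window; blunted CFT response |

The CFT dip is linear from onset to peak, held at depth until stimulus
end, then decays exponentially — only the onset/peak/depth anchor points
are literature-constrained; the shape between them is a modelling choice.
Beat-to-beat variability is white Gaussian RR jitter with
σ = RMSSD_target/√2, the simplest model with a controllable expected
RMSSD (E[ΔRR²] = 2σ²); it has no respiratory structure, so
frequency-domain HRV of synthetic data is meaningless. The ECG is a
Gaussian-bump P-QRS-T template placed at beat times — morphologically
crude but exact in R-peak ground truth, which is what detector scoring
needs. The cortisol pulse is a log-normal bump on an individual baseline;
mildly negative responders are allowed (amplitude floor −20 %).

Planted exclusion archetypes: a CFT non-responder (slight programmed
tachycardia during CFI), an S0 outlier (21 nmol/L) and an HR
hyper-responder (AT gains × 2.5). Exclusion rules, evaluated in that
order with one recorded reason per participant: (a) CFT-condition mean
ΔHR ≥ 0 during CFI in both MIST1 and MIST2; (b) S0 > cohort mean + 3 SD;
(c) participant mean ΔHR over the AT subphases > 3 SD from the cohort
mean. Rule (c)'s aggregate (mean over ATs) is a design choice;
thresholds are configurable.

**What passing synthetic tests shows — and does not.** Recovery of
programmed HR, depth and cortisol parameters shows the chain is
internally consistent and unbiased under the generator's assumptions
(template morphology, white jitter, smooth programmed trends). It does
not certify performance against real-world challenges absent from the
generator: electrode noise and motion artifacts, true ectopy, respiratory
sinus arrhythmia, wandering baselines beyond the modelled 0.25 Hz, or
assay-specific cortisol error structure.

## Numerical details and degenerate inputs

- Detector refuses recordings < 2 s; empty and flat signals return empty
  peak series rather than errors.
- An RR segment with < 2 intervals yields NaN measures with a warning
  (< 3 for RMSSD/pRR50); t̂_Glo needs ≥ N intervals.
- If every RR interval is removed by the artifact rules the recording is
  rejected as unprocessable.
- Noncentral CI inversions use Brent root-finding at 10⁻¹⁰ tolerance with
  adaptive bracketing; a noncentrality bracket failure returns NaN bounds
  rather than raising.
- All F statistics are computed with explicit zero-MS guards (0/0 → F = 0
  for all-equal responses; η² boundaries 0 and 1 are exact).
- Pipeline runs are deterministic: identical inputs, configuration and
  seed produce byte-identical outputs; the manifest records one status
  per participant and one reason per exclusion.

## Problem sizes used by the test and acceptance suites

Detector fidelity uses 5-min single-records at 45–180 bpm; parameter
recovery uses cohorts of 12 CFT participants with full-session ECG at
256 Hz; oracle equivalence uses 1,000 random RR series and 10,000 random
cortisol profiles; ANOVA cross-checks use 100 random tables; type-I
calibration uses 2,000 null replicates at n = 15 per group. These sizes
make the checks statistically meaningful while keeping the default suite
comfortably fast.

## Known limitations

- The ECG template is not a biophysical model; detector performance on
  real multi-morphology ECG will be lower than the synthetic scores.
- The statistical artifact rules remove a fixed quantile of clean data by
  construction (see above); RMSSD/pRR50 are correspondingly conservative.
- Mixed designs beyond one between × one within factor (e.g. three-way
  within interactions) are out of scope.
- Cortisol simulation ignores diurnal slope and menstrual-cycle or
  contraceptive effects on reactivity; condition contrasts are driven
  solely by the amplitude parameter.
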