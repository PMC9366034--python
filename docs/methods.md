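# Methods

This note documents the models, parameter choices and numerical conventions
behind `hrvtbi`, and the limits of what its synthetic experiments establish.

## The experimental design being emulated

The pipeline targets a two-arm, twelve-subject swine protocol: six animals
receive controlled hemorrhage alone, six receive a blunt TBI followed by the
same hemorrhage. Each animal contributes three recorded phases — a 22-minute
anesthetized baseline (Hb/Tb), a 5-minute hemorrhage (Hh/Th), and a 5-minute
post-hemorrhage period (Hp/Tp). The scientific claim under test is that TBI
superimposed on hemorrhage collapses beat-to-beat variability in a way
hemorrhage alone does not, and that this collapse is detectable by a linear
classifier within the first hour.

No recordings ship with the package, so every stage runs against the
synthetic cohort described next.

## Synthetic RR generator

Each subject-phase tachogram is drawn from

    rr_i = max(200 ms, mean + g_i + j_i)

where `g` is a stationary AR(1) Gaussian process with lag-1 correlation
`ar_coefficient` and `j` is an independent Bernoulli(`jump_prob`) excursion
of fixed magnitude `jump_scale` with random sign. Beats are emitted until
their cumulative time first reaches the phase duration. The Gaussian
variance is set to `target_sdnn² − jump_prob·s²` (with `s` the jump
magnitude), so the series' marginal SD matches the SDNN target; if the jump
term alone would exceed the target, the jump magnitude is capped so its
variance share never passes one half — a small-variability series therefore
shrinks its excursions rather than degenerating into a constant trace
punctuated by rare 60 ms spikes.

This mixture is the simplest process that produces the two signatures the
analysis depends on: a **bimodal successive-difference distribution** at
baseline (a diffuse Gaussian mode over 0–19 ms plus a discrete ≥ 50 ms mode
from the jumps) and a clean **variability collapse** when scaled down.

Defaults (one subject-phase):

| parameter | default | rationale |
|---|---|---|
| `target_mean_rr` | 600 ms | HR ≈ 100 bpm, typical for isoflurane-anesthetized young swine |
| `target_sdnn` | 40 ms | large enough to populate the ≥ 50 ms difference bin at baseline |
| `jump_prob` | 0.1 | sporadic large excursions (sinus-arrhythmia-like events) |
| `jump_scale` | 60 ms | puts the jump mode firmly in the ≥ 50 ms bin |
| `ar_coefficient` | 0.4 | see below |
| RR floor | 200 ms | physiological ceiling of 300 bpm; keeps ECG pulses separable |

The AR coefficient trades realism of the difference histogram against
estimator stability: the sampling SD of the sample-SD of an AR(1) series
grows like √((1+φ²)/(1−φ²)), so strongly autocorrelated tachograms
(φ ≥ 0.8) make a 300-beat SDNN estimate scatter by 7–13% around its target.
At φ = 0.4 a 300-beat estimate concentrates within ~5% while the difference
histogram keeps its two modes. This is a deliberate compromise; real swine
tachograms are more autocorrelated than this.

### The TBI effect

The Th/Tp phases of the TBI arm multiply `target_sdnn` **and** `jump_scale`
by 0.35 and 0.25 respectively, leaving `jump_prob` alone — a uniform
shrinkage of excursion amplitudes. This choice makes short- and long-term
variability fall in proportion, so the SD1/SD2 ratio is preserved across
groups while SDNN, pNN50, SD1 and SD2 all collapse and the majority of
|ΔRR| lands below 10 ms; shrinking the jump *probability* instead would
change the shape of the process and give the ratio its own artificial arm
signal, contradicting the physiology being modelled (a proportional loss of
autonomic modulation).

### Between-subject heterogeneity

Each subject-phase draws lognormal multipliers on mean RR (σ = 0.25), SDNN
(σ = 0.5) and jump probability (σ = 0.5). Two consequences are intended:

- The arms **overlap**. Group contrasts at n = 6 per arm are clearly
  significant, yet a classifier still errs on the occasional low-variability
  control or high-variability TBI animal — the regime in which subset
  selection is meaningful at all (with narrow heterogeneity every subset
  scores 100% and the comparison degenerates).
- Mean RR becomes a **large-scale nuisance feature** (SD ≈ 150 ms around
  600 ms), reflecting how differently animals respond to hemorrhage
  (compensatory tachycardia vs relative bradycardia).

Heterogeneity is redrawn independently for every subject-phase rather than
held fixed per subject. This makes all control-arm phases literal iid draws
from one distribution — so cross-phase null contrasts reject at exactly the
nominal rate — at the cost of discarding within-animal correlation across
phases. Since every downstream analysis is unpaired and uses one phase at a
time, nothing in the pipeline exploits that correlation anyway.

## Peak detection

The detector is deliberately minimal: a zero-phase 2nd-order Butterworth
band-pass over 5–30 Hz (the QRS energy band; applied forward-backward so
peak times are not displaced), half-wave cutting at 0 mV, then local-maximum
selection at ≥ 0.4 × signal maximum with a 200 ms refractory period
(greedy, descending amplitude). Polarity is auto-detected by comparing
|max| to |min| after filtering. On the synthetic pulse-train ECG at SNR 10
it recovers ≥ 99% of peaks within ±5 ms with ≥ 99% precision; it is not a
substitute for a clinical QRS detector on pathological rhythms (no T-wave
discrimination, no adaptive thresholding).

## HRV parameters

All statistics use the sample (n−1) denominator. Trimming removes the
⌊0.025·n⌋ largest and smallest RR *values* (ties broken by position) before
any feature is computed, and every difference-based quantity (pNN bins, SD1,
Poincaré points) skips beat pairs whose adjacency was broken by trimming —
otherwise each removed beat would fabricate two large spurious differences.

pNN binning uses exhaustive half-open bins [0,10), [10,20) … [40,50),
[50,∞) so percentages sum to 100; `pNN50` is the top bin and therefore uses
≥ 50 ms (not the strict > 50 ms of some HRV libraries). SD1/SD2 are defined
through the successive-difference variance, which ties them to SDNN by the
identity SD1² + SD2² = 2·SDNN²; when trimming decouples the two variance
estimates the SD2 radicand can go (slightly) negative and is clamped to zero
with a warning, the ratio reported as NaN.

## Statistics

Two-group comparisons use Student's pooled-variance t-test (Welch by flag),
more than two groups one-way ANOVA, all two-sided at α = 0.05 with no
multiple-testing correction. Degenerate zero-variance inputs follow fixed
conventions (equal constants → p = 1; unequal constants → significant,
flagged). Six contrasts are screened per parameter; a parameter qualifies as
significant through the three injury-related contrasts (Hp vs Tp, Tb vs Th,
Tb vs Tp) only.

The stochastic validation quantifies the multiplicity risk the missing
correction leaves behind: for each flagged (parameter, contrast) instance,
the 12 pooled values are randomly split into two groups of six (uniformly,
with replacement across draws — the 462 distinct splits are sampled, not
enumerated), t-tested, and the significant fraction recorded over 100 tests
× 10 trials. Calibration note: with a *fixed* dataset that fraction is a
property of the data and varies far more than Binomial(1000, α) across
datasets; the package's null-calibration tests therefore redraw a fresh
exchangeable dataset per test, which makes every test an exact α-level draw.

## Classifier

Subsets follow the reference enumeration: all contiguous index ranges
starting at 1, 2 or 3 (18), plus incremental prefixes of the significant set
(4 when five parameters are significant), 22 in total. Each subset trains a
libsvm C-SVC with linear kernel, C = 1, on the post-phase feature rows of
the 12 subjects, and is scored by holding out one randomly chosen subject
per arm per repeat (default 100 repeats); per-repeat weights, biases and
scalings are averaged into the mean model. Boundary ties predict "control"
(the conservative error for a TBI screen).

Features enter the SVM in **raw units** by default. With parameters spanning
four orders of magnitude (mean RR ~600 against SD1 of a few ms), an unscaled
linear kernel penalises subsets that include uninformative large-scale
parameters — which is precisely what gives subset selection its teeth, and
what produces the characteristic ordering in which accuracy rises with the
fraction of significant parameters. Per-fold standardisation is available
(`standardize=True`); under it accuracy is invariant to rescaling any
feature column, and the gap between the significant-only and all-parameter
subsets largely disappears.

The accuracy grid groups subsets into four bands (ranges from 1, from 2,
from 3, and the significant prefixes) and reports each band's mean percent
significant and mean accuracy.

## Problem sizes and runtime

Default analyses are sized for a laptop CPU: cohorts of 12 subjects with a
22-minute baseline simulate in under a second; a full pipeline run (features,
screening, 100×10 stochastic validation, 22 subsets × 100 hold-out repeats)
completes in well under a minute; the repeated-cohort experiments in the test
suite use 20 seeds.

## What the synthetic experiments do and do not show

They establish that the implementation is correct and internally coherent:
features match independent formula evaluations, the detector recovers known
peak times, null configurations behave at their nominal rates, and the
qualitative orderings (significant-parameter screening, subset-selection
advantage, baseline uninformativeness) emerge for the stated generative
mechanism. They do **not** establish that real swine or human recordings
satisfy that mechanism: the generator has no respiratory sinus arrhythmia,
no baroreflex coupling to blood pressure, no ectopy or artifact, phases are
independent draws rather than one evolving physiology, and effect sizes are
assumptions, not measurements. Absolute accuracies on real data will differ;
only the structure of the analysis transfers.

## Known limitations

- Frequency-domain HRV (VLF/LF/HF) is out of scope.
- The peak detector assumes a dominant R deflection of consistent polarity.
- The stochastic validation reports raw empirical probabilities; it is a
  diagnostic, not a formal multiple-testing correction.
- `sd_ratio` is NaN for (near-)constant series; the classifier refuses
  feature matrices containing non-finite values rather than imputing.
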