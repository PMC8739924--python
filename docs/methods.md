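# Methods

`pulsewave` implements a complete radial pulse-wave analysis chain:
synthetic signal and cohort generation, recording preconditioning and
cardiac-cycle segmentation, fiducial time-domain feature extraction,
multiscale sample entropy, nonparametric case-control statistics, and a
three-class coronary-lesion-extent classifier comparison. This note
records the models, conventions, and numerical choices behind each stage,
and what the synthetic data can and cannot establish.

## Synthetic cycle model

One cardiac cycle is modelled as the sum of three Gaussian components —
percussion (main systolic) wave, tidal (reflection) wave, and dicrotic
(early-diastolic rebound) wave — sharing a spread `component_width`; the
dicrotic notch arises as the valley between the tidal and dicrotic
components. A fast edge-decay correction (time constant half a component
width) pins the cycle to baseline 0 at both ends without sagging the
diastolic tail below the foot level, so the inter-cycle junction remains
the true local minimum; the residual end-point offset (~1e-18 of the
amplitude) is removed by a negligible linear term.

This construction was chosen because its landmark locations have
well-defined continuous-time truth: each extremum of the mixture is found
by bounded scalar optimisation (tolerance 1e-10 s) between the relevant
component centres, and the main-wave widths by bracketed root finding on
the level crossings. Component overlap is therefore accounted for exactly;
with the default morphology the percussion peak height stays within 1% of
`amp_percussion`.

Default morphology (arbitrary mm-scaled units; the source device reports
amplitude in mm without an absolute calibration): period 0.85 s, component
amplitudes 10 / 6.5 / 3.5 mm, centres at 0.13 / 0.27 / 0.46 s, spread
0.045 s (notch seed 0.37 s). These give height ratios and widths on the
scale of published radial-pulse tables, with a clearly articulated notch.
When `amp_tidal` (or `amp_dicrotic`) is zero the corresponding landmark is
flagged absent in the truth rather than interpolated.

Recordings concatenate per-cycle waveforms with independent multiplicative
period jitter (lognormal, CV 3% by default — typical short-term heart
period variability at rest), stretching the whole cycle so morphology is
preserved. Baseline drift is a slow sinusoid (default 0.2 Hz, a
respiratory-scale wander) and measurement noise is white Gaussian. The
study dialect is 60 s at 720 Hz (43,200 samples per subject).

## Synthetic cohorts

Two tiers serve different purposes:

* **Waveform tier** (`generate_cohort`): per-subject cycle parameters are
  drawn around the base morphology (lognormal inter-subject variability,
  CV 5%) and shifted per group. Default shifts follow the directions the
  case-control comparison reports: the few-lesion group gains a more
  prominent tidal wave and wider main wave (raising H2/H1, H3/H1, W2); the
  multi-lesion group has a 6% shorter period with unchanged systolic
  timing (lowering T and W1, raising T1/T) and a smaller noise amplitude
  (lowering entropy at every scale). Demographics and comorbidity
  prevalences are drawn per group from the published cohort table. This
  tier closes the loop with segmentation and landmark detection.

* **Feature tier** (`sample_feature_cohort`): per-subject feature vectors
  are drawn directly from per-group split-lognormal distributions
  quantile-matched to the published median (Q1, Q3) of each feature. A
  split-lognormal (separate log-spreads below and above the median) is
  used because the printed quartiles are skewed even on the log scale, so
  a single lognormal cannot match all three printed numbers. The three
  time-domain features the comparison tables do not print (H4/H1, H5/H1,
  T1/T4) use one group-invariant plausible row. This tier is the fast
  path for calibration studies needing hundreds of cohorts.

Features in the feature tier are drawn independently within a subject.
Real pulse features are strongly cross-correlated (entropy scales of one
signal; ratios sharing H1), so passing tests on this tier demonstrates
the statistical machinery and the direction/magnitude structure of group
effects — not the multivariate dependence structure of real cohorts, nor
device- or operator-specific artifacts. Absolute classifier precisions on
synthetic cohorts are therefore not comparable to the published ones;
only qualitative orderings are asserted.

## Preconditioning and segmentation

Denoising is a zero-phase (forward–backward) 4th-order Butterworth
low-pass at 20 Hz — pulse harmonics above ~15 Hz are negligible — and
drift removal a zero-phase high-pass at 0.5 Hz, below the slowest
plausible cardiac fundamental (40 bpm ≈ 0.67 Hz). Both preserve landmark
timing by construction. The residual baseline is then re-anchored by
interpolating through the detected beat feet, so cycle-onset levels sit
near 0 mm. A recording shorter than the filter warm-up is an error, and
an (almost) constant recording is returned unchanged. Preprocessing is
idempotent to within a few percent away from the recording edges; the
first/last beats sit in the filters' edge-transient region and are the
usual cycles lost to the quality filter.

Cycle onsets are placed at the foot of each beat: candidate beats are
maxima of the first derivative (prominent upstrokes), kept apart by a
refractory distance of 0.7× the dominant beat period estimated from the
signal's autocorrelation — so a prominent tidal or dicrotic upstroke
cannot split a cycle even when the tidal wave rivals the percussion wave
— with a weaker-peak prune for any residual pair closer than 0.55× the
median inter-beat gap. The onset is then the local minimum
closest to — and preceding — the upstroke, restricted to minima near the
floor of the search window so an earlier shallow diastolic dip is not
mistaken for the foot. Indices are 0-based; cycle *i* spans the half-open
interval `[onset_i, onset_{i+1})`. Cycles with implied periods outside
0.4–1.5 s (40–150 bpm) or peak-to-peak amplitude below a configurable
floor (default 0.5 mm) are rejected; fewer than `min_cycles` (default 10)
surviving cycles is a quality error. With measurement noise the detected
foot can wander a few tens of milliseconds along the flat diastolic tail;
this is a property of foot detection on noisy signals, shared by real
recordings, and is absorbed by per-recording median aggregation.

## Fiducial landmarks and time-domain features

Within a baseline-corrected cycle: H1/T1 is the global maximum (an error
if it falls in the first or last 5% of the cycle); subsequent landmarks
are taken from the interleaved local extrema after T1 — gorge (first
minimum), tidal wave (maximum between the two minima), dicrotic notch
(second minimum), dicrotic wave (first maximum after the notch) — with
prominence at least 1.5% of H1. When the tidal wave is fused into the
falling limb (one trough only), the notch is that trough and the
tidal/gorge position falls back to the inflection of minimal absolute
curvature on the falling limb, with `tidal_present` cleared; landmarks
that cannot be located are NaN, never fabricated. Heights are measured
above the cycle-onset level, matching the figure convention of a baseline
at the onset.

Widths W1 and W2 are the durations for which the main wave exceeds 1/3
and 2/3 of H1 respectively, by linear interpolation at the level
crossings enclosing T1. The source figure's caption defines both widths
at "1/3 height" and both T4 and T5 as the notch phase — evident
duplications; the 1/3–2/3 convention is adopted because W2 < W1 in every
printed comparison row (a higher measurement level gives a narrower
width), and T5 is read as the dicrotic-wave peak phase. Both fractions
are configuration-exposed.

The nine per-cycle features (H2/H1, H3/H1, H4/H1, H5/H1, T1/T, T1/T4, T,
W1, W2) are aggregated per recording by the feature-wise **median** over
accepted cycles (missing values excluded per feature) — the robust choice
given occasional mis-detected cycles; whether the original analysis used
mean or median is unstated.

## Multiscale entropy

Coarse-graining at scale *s* replaces the series by non-overlapping block
means of length *s* (`floor(N/s)` points; scale 1 is the identity).
Sample entropy is −ln(A/B) with B the number of template pairs of length
*m* within Chebyshev distance *r* (self-matches excluded, N−m templates
for both lengths, the standard convention) and A the same at length m+1;
A = 0 or B = 0 yields a missing value rather than ±∞. Pair counting uses
a k-d tree two-tree count, algebraically identical to brute-force
enumeration (verified to 1e-12 against an O(n²) oracle).

Defaults: m = 2, r = 0.15 × SD of the **original** series (sample SD,
ddof = 1), r held fixed across scales, maximum scale 5 — the parameters
conventional for the original multiscale-entropy method, which the source
analysis cites without stating its own; both are configuration-exposed
and echoed in every output. Entropy is computed on the full preprocessed
recording, not per cycle, since coarse-graining is defined on the signal
to be tested as a whole.

## Cohort statistics

Continuous features are summarised as median (Q1, Q3) with quartiles by
linear interpolation (type 7, recorded in the output, since the
convention is not stated in the source). Pairwise contrasts use the
Wilcoxon–Mann–Whitney test in its normal approximation with tie-corrected
variance — the Z equals the exact permutation moments of U even under
heavy ties — and two-sided P values; the three-group omnibus test is
tie-corrected Kruskal–Wallis against chi-squared with k−1 df (the
published tables label their omnibus column "Z"; it is treated as a
labelling artifact). Categorical factors use Pearson's chi-squared
without continuity correction, which reproduces every published
categorical statistic from its printed counts to 3 decimals. One-way
ANOVA can be reconstructed from per-group mean/SD/n summaries; the
published age row is not consistent with the classic one-way F (it is
closer to a Welch-type statistic) and is therefore not asserted anywhere.
Pairwise P values are reported unadjusted at α = 0.05 by default,
mirroring the per-test significance marks of the source tables; a
Bonferroni option exists but is off by default.

## Classification

Datasets: baseline (age, sex male=1/female=0, BMI) plus the nine
time-domain features (dataset1, 12 columns), the five entropy features
(dataset2, 8 columns), or both (dataset3, 17 columns). Evaluation is
stratified 10-fold cross-validation with pooled out-of-fold predictions;
per-class precision is TP/(TP+FP) per lesion group on the pooled
predictions and "average precision" is their unweighted (macro) mean —
consistent with the published per-class/average relationship. Missing
features are median-imputed within training folds. KNN (k = 5)
standardises features within training folds; the random forest uses 500
trees; the decision tree uses Gini splits and cost-complexity pruning
with the pruning strength chosen by an inner stratified 5-fold CV scored
on macro precision — the source describes its tree method as including
pruning, and an unpruned tree overfits cohorts with weak effects. The
validation scheme behind the published precisions is unstated; stratified
10-fold CV is this package's declared choice. Rows are ordered by subject
id before fold assignment, so evaluation is invariant to cohort row
order. All randomness derives from the caller's seed.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` recomputes: the published categorical chi-squared
statistics and two ANOVA F values from their printed summary inputs
(n = 529); coarse-graining against a loop oracle (s ≤ 10, n = 257);
sample entropy against the brute-force oracle (50 series, n between 100
and 2000); landmark recovery on 100 zero-noise 10-s recordings (~1100
cycles); group-comparison null calibration on 500 exchangeable
study-sized cohorts (7000 omnibus tests); and the classifier-ordering
properties on 25 study-sized effect-bearing cohorts. These sizes are the
package's standard verification workload; each stage logs its wall time
to stderr.

## Known limitations

* The synthetic cycle is a phenomenological mixture, not a hemodynamic
  (e.g. Windkessel) model; it provides landmark truth, not physiology.
* Feature-tier cohorts ignore within-subject feature correlations, and
  waveform-tier group shifts are minimal mechanisms chosen to produce the
  published effect directions, not fitted to the unavailable raw data.
* Published absolute classifier precisions are not reproducible without
  the original cohort; only qualitative orderings are asserted, as
  stochastic properties over seeded replicates.
* The published age-row F statistic is not reproducible by classic
  one-way ANOVA from its printed summaries and is excluded from checks.
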