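# pulsewave

Radial pulse-wave analysis for coronary-lesion-extent studies: from raw
single-channel pressure recordings to per-subject features, case-control
statistics, and lesion-group classification.

The radial pressure pulse carries information about cardiac ejection and
arterial wave reflection. Within one cardiac cycle the classical landmarks
are the percussion wave (height H1, phase T1), the main-wave gorge (H2,
T2), the tidal wave (H3, T3), the dicrotic notch (H4, T4) and the dicrotic
wave (H5, T5), plus the cycle period T and the widths W1, W2 for which the
main wave exceeds 1/3 and 2/3 of H1. The nine time-domain features

    H2/H1, H3/H1, H4/H1, H5/H1, T1/T, T1/T4, T, W1, W2

index vascular compliance, peripheral resistance, ejection function and
sustained arterial pressure. Nonlinear structure is summarised by
multiscale sample entropy: the signal `u` is coarse-grained at scale `s`,

    y_j = (1/s) * sum_{i=(j-1)s+1}^{js} u_i ,   1 <= j <= floor(N/s),

and SampEn(m, r) = −ln(A/B) is computed per scale (s = 1..5), where B
counts template pairs of length m within Chebyshev distance r and A the
same at length m+1 (r = 0.15 × SD of the original signal, m = 2).

Subjects grouped by coronary angiography (group 1: < 50% stenosis;
group 2: 1–2 lesions; group 3: ≥ 3 lesions) are compared feature-wise with
Wilcoxon–Mann–Whitney and Kruskal–Wallis rank tests (chi-squared for
categorical factors), and lesion extent is predicted from feature panels
(demographics + time-domain, + entropy, or both) with KNN, a pruned
decision tree, and a random forest under stratified 10-fold
cross-validation, reporting per-class and macro ("average") precision.

Because raw clinical recordings of this kind are typically not shareable,
the package includes a first-class synthetic-data module: an analytic
pulse-cycle generator with exact landmark ground truth, a waveform-tier
cohort generator, and a feature-tier cohort sampler matched to published
group summaries. Every downstream stage is tested against these.

## Worked example

```python
import numpy as np
from pulsewave import (CycleParams, generate_recording, preprocess,
                       segment_cycles, quality_filter, detect_fiducials,
                       compute_features, aggregate_recording,
                       multiscale_entropy)

rec, truth = generate_recording(CycleParams(), duration_s=60.0, fs=720.0,
                                seed=1, noise_sd=0.15, drift_amplitude=1.0)
pp = preprocess(rec)
seg = quality_filter(segment_cycles(pp), pp)
per_cycle = []
for i in range(seg.n_cycles):
    if seg.accepted_flags[i]:
        a, b = seg.cycle_bounds(i)
        per_cycle.append(compute_features(detect_fiducials(pp.samples[a:b], pp.fs)))
agg = aggregate_recording(per_cycle)
print(f"cycles: {agg.n_cycles}")
print({k: round(v, 3) for k, v in agg.as_dict().items()})
print([round(v, 3) for v in multiscale_entropy(pp.samples).values])
```

prints

```
cycles: 70
{'h2_h1': 0.397, 'h3_h1': 0.653, 'h4_h1': 0.074, 'h5_h1': 0.351, 't1_t': 0.17,
 't1_t4': 0.374, 't_s': 0.849, 'w1_s': 0.251, 'w2_s': 0.078}
[0.03, 0.057, 0.073, 0.079, 0.084]
```

— 70 accepted cycles from a 60-s recording at ~71 bpm; the median height
ratios and widths recover the generator morphology (the tidal-wave ratio
H3/H1 ≈ 0.65 for a 6.5/10 component amplitude ratio; the period 0.849 s
against a nominal 0.85 s), and the MSE1–MSE5 profile rises with scale, as
expected for a nearly periodic signal with a small noise floor.

The same pipeline runs from the shell on whole cohorts:

```bash
pulsewave all --seed 7 --outdir run     # simulate -> extract -> mse -> stats -> classify
```

which writes `cohort.csv`, `features.csv`, `stats_report.csv/.json` and
`classification_report.csv/.json`, each stamped with a provenance block
(config hash, seed, package version).

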