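# Methods

## Index model

The unit of analysis is the utterance: a breath-delimited stretch of
continuous voice. An emotion engine assigns each utterance five integer
components in 0–10 (anger, joy, sorrow, calmness, excitement). Two convex
ratios summarize mood-relevant contrasts:

- vivacity = joy / (joy + sorrow) — joyful vs. sorrowful affect;
- relaxation = calmness / (calmness + excitement) — calm vs. tense affect.

Both live in [0, 1]. If a denominator is zero the ratio is undefined; the
package marks it *missing* and excludes the utterance from the affected
mean rather than imputing 0.5, which would bias recording vitality toward
the middle. Exclusions are counted per recording and logged.

Per recording (one acquired voice), vivacity and relaxation are unweighted
means over utterances and

    vitality = w_viv · vivacity + w_rel · relaxation,

with stored defaults w_viv = 0.60, w_rel = 0.40 and decision boundary
0.52. Per subject, recordings accumulated over time give

    mental_activity = w_meanvit · mean(vitality) + w_sd · mean(vitality SD),

defaults 0.75 / 0.25, boundary 0.426. *vitality SD* is the standard
deviation of per-utterance vitalities within one recording — dispersion is
informative because healthy speech varies more between utterances. It uses
the sample (n−1) denominator by default (`IndexWeights.sd_ddof`), and is
defined as 0 for a single-utterance recording. Recording-level means weight
utterances equally; subject-level means weight recordings equally,
regardless of utterance counts.

The weights and boundaries are stored constants, not refit at run time.
`fit_separating_weights` reproduces the fitting procedure on data when
needed: a grid search over convex weight pairs (step 0.01), choosing for
each weight the split-midpoint boundary that maximizes balanced accuracy,
with ties broken toward the weight closest to 0.5 and then toward the
smaller weight. The grid-plus-midpoint rule was an open design choice; it
is exactly reproducible and makes the tie-break explicit. Note the weight
is only well identified when the data vary substantially in the direction
orthogonal to the true discriminant — otherwise balanced accuracy is
nearly flat in the weight and the recovered value can wander by more than
the grid step.

## Segmentation

"Volume" is realized as framewise RMS amplitude, by default over 30 ms
frames hopped every 10 ms (no frame scheme is canonical; these are common
speech-analysis values, both configurable). The state machine: frames with
RMS above a threshold are speech; a silence-to-speech transition opens an
utterance; a silence run of at least `min_silence_s` (default 0.3 s)
closes it; speech runs shorter than `min_utterance_s` (default 0.3 s) are
discarded. The 0.3 s defaults are breath-group-scale conventions, not
reproductions of any stated value. Span edges detected at frame resolution
are refined against non-overlapping hop-length subwindows, so reported
boundaries are accurate to about one hop whenever the threshold sits well
below the speech RMS (roughly, below 0.58 of it); at higher thresholds the
quantization error can approach one frame.

Thresholds are best set per recording (recording conditions vary); the
automatic surrogate takes the geometric midpoint of the 10th and 90th
framewise-RMS percentiles (midpoint on a log scale, floor 1e−8), refuses
constant-RMS input, and logs whenever it is used.

## Emotion scores

The engine that produced the original scores is a proprietary black box;
this package's boundary is its output contract (five independent integers
0–10 per utterance, arriving as CSV). Whether the real components are
jointly constrained is unknown; the contract assumes independence.
`proxy_score` is a deterministic acoustic stand-in mapping per-utterance
RMS, zero-crossing rate and energy slope to the five integers by monotone
binnings. It exists so the audio → indices path is testable end to end;
it has no claim to emotional validity and the evaluation layer never
depends on it.

## Synthetic cohorts

`simulate_cohort` draws each utterance's five scores independently from
N(group mean, emotion_sd), rounds and clips to 0..10. Defaults define the
emulated study conditions:

- group sizes 14 / 24 / 22 (healthy / no depression / depression data);
- emotion_sd = 2.0; group means (anger, joy, sorrow, calm, excitement):
  healthy (3.0, 5.9, 3.1, 4.5, 4.5), no depression
  (3.0, 5.33, 3.67, 4.3, 4.7), depression (3.0, 4.7, 4.3, 4.05, 4.95) —
  calibrated once by Monte-Carlo (8×10⁵ draws) so recording-vitality means
  land near the reported 0.60 / 0.55 / 0.49;
- a subject-level random effect: a N(0, 0.9) shift added to the joy/calm
  means and subtracted from sorrow/excitement, resampled per subject.
  Vitality responds to this shift at about 1/9 per unit, so 0.9 yields
  between-subject vitality SD ≈ 0.10, the spread implied by the reported
  group standard errors (SE·√n ≈ 0.10); with the mean gap of ≈ 0.11 this
  places the expected healthy-vs-depression effect size near d ≈ 1 and the
  expected AUC near Φ(d/√2) ≈ 0.77;
- HAM-D scores from rounded Gaussians truncated by rejection to the
  Zimmerman ranges: no depression N(3.1, 2.3) on [0, 7], depression
  N(16.1, 7.4) on [8, 52]; healthy subjects carry no HAM-D.

What the generator does **not** emulate: any real joint distribution of
the five components (independence is an assumption), within-session serial
correlation of utterances, session-to-session drift, and any acoustic
relationship between voice and scores. Passing tests therefore validate
the index arithmetic, the aggregation rules and the statistical machinery
under the assumed structure — they say nothing about how the real engine's
scores distribute, nor about clinical performance on real voices.

`simulate_vitality_cohort` bypasses the emotion layer and draws vitality
directly from Gaussians a specified d apart (equal SDs), for calibration
checks against the binormal identity AUC = Φ(d/√2).

## Screening evaluation

Groups follow the Zimmerman HAM-D cutoffs: patients with HAM-D ≤ 7 are *no
depression*, ≥ 8 *depression*; healthy controls carry no HAM-D. Repeated
sessions of one patient enter as independent rows — a deliberate
simplification that overstates the effective n when sessions correlate
within subject; the model logs no correction for it.

- Severity correlation: Pearson product-moment r with the two-sided
  t-based p-value (Spearman available as an option).
- Group comparison: Tukey–Kramer studentized-range p-values
  (scipy's `tukey_hsd`, which applies the Kramer unequal-n adjustment),
  family significance 0.05.
- Discrimination: empirical ROC over all distinct thresholds, higher
  vitality indicating health; trapezoidal AUC, which on the empirical ROC
  equals (wins + 0.5·ties) / (n_pos·n_neg) over all healthy–depression
  pairs.
- Operating point: maximal Youden's J = sensitivity + specificity − 1,
  ties resolved toward higher sensitivity (screening prefers not to miss
  cases); a fixed-specificity rule is available.
- Effect size: Cohen's d with the pooled (n−1-weighted) SD.
- Power: two-sided two-sample t-test power from the noncentral t
  distribution, df = n1 + n2 − 2, noncentrality d·√(n1·n2/(n1+n2)).
  Group sizes may be fractional. Where scipy's noncentral-t tails
  underflow to NaN (very large df × noncentrality), the Gaussian limit is
  used; at that point the two agree to double precision.
- Required sample size: monotone root-finding (Brent) on the power
  function in the free group size, returning a fractional n on
  [2, 1000]. Because the noncentrality saturates at d·√(n_fixed) as the
  free group grows, small effects may make the target power unattainable;
  that raises an explicit infeasibility error rather than returning the
  bracket edge.

## Problem sizes and tolerances

Simulation-backed tests use: 200 replicate cohorts at n = 20/group for the
binormal AUC calibration (tolerance ±0.02 on the mean), 500 replicates for
the Tukey–Kramer family-wise type-I bound (≤ 0.07 at nominal 0.05), 50,000
Monte-Carlo t-tests for the power cross-check (±0.01), and 500 points per
group for separating-weight recovery (±0.1). Index identities are asserted
to 1e−12; hand-computed oracles to their printed precision. These sizes
give comfortable margins between sampling noise and the asserted
tolerances while keeping the default suite fast.

## Known limitations

- The proxy scorer is plumbing; end-to-end audio runs demonstrate data
  flow, not screening performance.
- Independence assumptions (between emotion components, between sessions)
  are simplifications; a clustered or mixed-effects evaluation is out of
  scope.
- The automatic segmentation threshold is a surrogate for per-recording
  manual adjustment and can fail on recordings without a clear
  silence/speech bimodality (it refuses constant-volume input).
- Weights and boundaries are treated as fixed constants of the method;
  refitting them on new data is supported but changes the meaning of the
  downstream indices.
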