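# Methods

## The question and the data model

A treatment course produces, per participant, a symptom severity total at
three timepoints: baseline (`pre`), end of treatment (`post`) and a later
follow-up (`fup`). The severity instrument modeled here is the CAPS-5
20-item total (0–80), the sum of four cluster subtotals: intrusion (B, 5
items), avoidance (C, 2 items), negative alterations in cognition/mood
(D, 7 items) and arousal/reactivity (E, 6 items), each item rated 0–4.
Scores are stored as integers; all ratio quantities are computed downstream
in floating point.

The scientific question is whether there is a *response threshold*: a
fraction of baseline improvement at end of treatment beyond which
improvement continues after treatment stops, and short of which it decays.

## Normalization and the responder curve

Each subject's outcome is normalized to their own baseline:
`post_ratio = post/pre`, `fup_ratio = fup/pre`. An improvement of X%
corresponds to a ratio of 1 − X/100. A subject *improved at follow-up* iff
`fup_ratio < post_ratio` (strict). Records with `pre = 0` or a missing
assessment are excluded complete-case, with a logged count.

For candidate thresholds t on a grid (default 0.05 … 1.00 in steps of
0.05), the responder curve is

    f(t) = #{ i : post_ratio_i < t  and  improved_i } / n(t),
    n(t) = #{ i : post_ratio_i < t },

with f(t) marked undefined where `n(t) < n_min` (default 3; tiny subgroups
make the fraction degenerate, and the handling of near-empty subgroups is
a package decision).

## Permutation null and the elbow threshold

The null model is "follow-up trajectory carries no information about
end-of-treatment depth": fup ratios are shuffled across subjects (post
ratios fixed), the improvement flags are recomputed, and the curve is
rebuilt. B replicates (default 1000) give a pointwise mean reference curve.
Because post ratios are fixed, n(t) — and hence which grid points are
defined — is identical across replicates.

The elbow threshold t\* maximizes the signed distance between the observed
and reference curves. Two distance statistics are implemented:

* **weighted** (default): `D(t) = (n(t)/N) · (f(t) − ref(t))` — the gap
  between *cumulative* responder curves, a Kolmogorov–Smirnov-like
  statistic that vanishes at both grid ends and peaks where observed and
  reference responder mass separate fastest. In planted-threshold
  simulations this statistic recovers the true threshold essentially
  always (100/100 cohorts at n = 200).
* **conditional**: `D(t) = f(t) − ref(t)`. Because the permutation-mean
  reference increases with t while a genuine deep-responder plateau is
  flat, the argmax of this form drifts to the deepest defined grid point
  and it does not localize a planted threshold (0/100 in the same
  experiment). It is retained for completeness and for hand-checkable toy
  cases.

The distance is signed, not absolute: the hypothesis is one-sided (deep
responders improve more than chance). Ties at the argmax break toward the
smallest t, i.e. the largest and most conservative improvement percentage.

The reference is either the permutation mean (default) or a fixed
"expected at random" diagonal, configurable as the overall improved
fraction or the identity line — the two plausible readings of a
random-expectation reference for this curve.

Significance: `p = (1 + #{b : max_t D_b(t) ≥ D_obs}) / (1 + B)`, where
each replicate contributes the maximum of its own distance curve over the
same grid. The selection of t\* is thereby built into the null
distribution, and the add-one smoothing keeps p in (0, 1]. With the
replicate set taken as all n! permutations (a test hook), this formula
reproduces the exhaustive-enumeration p exactly.

### Calibration and the effect of score granularity

On null samples of continuous ratio pairs (fup independent of post,
n = 56, B = 200), the measured rejection rate at α = 0.05 is 0.050
(1000 simulations): the counting p is exact under exchangeability.

On cohorts of *integer* scores the same machinery is mildly conservative
(measured ≈ 0.02 under the same design): rounding to integer totals
discretizes the distance statistic, a few percent of replicate maxima tie
the observed maximum exactly, and ties count as exceedances in the
counting formula. This is a validity-preserving bias (the test never
over-rejects) and is inherent to permutation tests on heavily discretized
scores at this sample size; it is covered by a dedicated super-uniformity
test.

## Cluster associations

Per cluster, change ratios `post/pre` and `fup/pre` of the cluster
subtotal are correlated with the total score's change ratios at three
comparisons: cluster-post vs total-post, cluster-fup vs total-fup, and the
predictive comparison cluster-post vs total-fup. The follow-up total in
the predictive comparison is fup/pre by default; a `fup_post` flag
switches to fup/post, since both normalizations are defensible and lead to
the same qualitative question. Clusters with a baseline subtotal of 0
(possible for the two-item avoidance cluster) have undefined ratios and
are excluded pairwise rather than falling back to additive changes, to
keep every comparison on the same ratio scale.

Spearman rank correlation (mid-ranks on ties) is the headline method, with
Pearson available side by side — published analyses of this design report
both, and the two can differ on skewed ratio data. Asymptotic two-sided
p-values come from the standard t-approximation (scipy); in addition a
pairs bootstrap (default B = 1000) gives a percentile 95% CI and an
add-one-smoothed two-sided tail probability of 0 under the resampled
coefficient distribution. On independent pairs (n = 30, B = 200) the
bootstrap test's measured rejection rate at α = 0.05 is ≈ 0.05.

Descriptive sham-arm counts accompany the associations: the number of sham
subjects beyond a given improvement percentage at end of treatment, the
number with any avoidance-cluster improvement, and how many of those
attenuated by follow-up.

## Baseline-severity checks

Two checks that baseline severity does not predict outcome:

* correlation of the baseline total with improvement
  `1 − timepoint/pre` at end of treatment and at follow-up (Spearman and
  Pearson both emitted);
* a two-sided Mann–Whitney comparison of baseline totals between subjects
  whose follow-up total beat their end-of-treatment total (IMPROVED) and
  the rest (WORSENED). Exact ties `fup == post` go to WORSENED — the
  conservative side for a claimed improvement effect — and are logged.
  The p is exact (full enumeration) for group sizes ≤ 12 with tie-free
  pooled values, otherwise a normal approximation with tie and continuity
  corrections.

## Synthetic cohorts

Participant-level data for this kind of trial are not public, so the
package carries two first-class generators.

**Planted-threshold engine.** Baseline totals are truncated-normal,
mean 43.8, SD 9.1 on [23, 80] — the pooled two-arm baseline of the
emulated trial, truncated at the floor of its "moderate" severity band.
Active-arm post/pre ratios default to a truncated normal (mean 0.70,
SD 0.25 on (0.05, 1.2]); sham ratios center near 1 (SD 0.08), with one
planted deep responder per 28 sham subjects whose improvement attenuates
at follow-up, mirroring the emulated trial's sham description. The
planted dependence: subjects with `post/pre < theta` (default 0.65)
improve further at follow-up with probability `p_sustain_below` (default
0.9), others with `p_sustain_above` (default 0.2); the further change is
drawn from a step distribution (truncated normal, mean 0.12 of baseline)
and applied in integer score units, strictly downward when sustaining and
flat-or-upward otherwise. Integer totals are split into cluster subtotals
by largest-remainder rounding of weight-proportional shares, weights
defaulting to the item counts 5:2:7:6 (no cluster-level means are
available to calibrate anything finer); with these weights the
per-cluster maxima can never be exceeded, so generated cohorts validate
by construction.

**Bistable double-well engine.** The mechanistic picture of a response
threshold is bistability: an overdamped state x in the quartic landscape
`U(x) = h (x² − 1)²` (healthy well at −1, pathological at +1; the quartic
is the minimal form with two wells and a barrier — nothing deeper is
claimed). Dynamics are Euler–Maruyama:

    dx = [ −4 h x (x² − 1) − d·1(treatment phase) ] dt + σ dW.

Treatment is a constant bias d during the treatment phase only;
alternatives such as displacing the initial condition were rejected
because a constant bias gives an explicit push-magnitude ↔ threshold
correspondence. With σ = 0 no random numbers are drawn and the well
bottom is an exact fixed point. The step-size guard `dt ≤ 0.05/h` keeps
`dt · U''` well below 1 over the visited range (|x| ≲ 1.5, where
U'' ≈ 23 h); violating it raises an error rather than silently diverging.
The deterministic critical push d\* is located by bisection on the
terminal well; for long treatment phases it approaches the saddle-node
value `8h/(3√3) ≈ 1.54 h` at which the pathological well disappears.

States map to scores by an affine map of clip(x, −1, 1) onto
`[caps_healthy, caps_sick]` (defaults 8 and 44, putting the pathological
well near the emulated baseline mean) plus Gaussian measurement noise,
rounded and clipped to [0, 80]. No quantitative score↔state link exists
in the clinical literature; the map is an explicit artifact convention.
Terminal states are labeled HEALTHY below −0.2, PATHOLOGICAL above +0.2,
else UNDECIDED.

In the end-to-end consistency experiment (σ = 0, measurement noise 0,
t_treat = 2, t_fup = 12, pushes uniform on (0.75, 1.03)·d\*), treatment
ends mid-transit, so subjects that cross the barrier are still descending
at the post assessment and their follow-up is strictly lower: terminal
well labels coincide exactly with the sustained-improvement flag, and the
elbow lands within one–two grid steps of the ratio separating the two
terminal subpopulations. The push cap matters: pushes far above d\*
settle into the healthy well before treatment ends, the clipped affine
map then gives post = fup, and the sustained-improvement flag degenerates
to a tie — a floor effect, not a dynamical failure.

**Null generators.** `generate_null_outcomes` draws (post, fup) ratio
pairs independently — the exchangeable null of the permutation test, on
the scale the test operates on. `generate_null_cohort` is the integer
cohort analogue (used where a full Cohort is needed); its rounding is the
source of the conservatism discussed above.

What the generators do *not* emulate: item-level response patterns
(clusters are deterministic shares of the total, so cluster-total
correlations in planted cohorts are near 1 by construction and carry no
independent information), dropouts and partial assessments, session-level
dynamics of the treatment course, demographic covariates, and any
correlation between baseline severity and response (absent by
construction, which is exactly what the baseline-severity checks should
find). Passing tests therefore demonstrate correctness and calibration of
the *analysis machinery* under the stated structural assumptions, not
clinical validity on real cohorts.

## Problem sizes and reproducibility

Default experiment sizes: threshold recovery uses 100 cohorts of n = 200
with B = 500; permutation calibration uses 1000 null samples of n = 56
with B = 200; bootstrap calibration uses 1000 simulations of n = 30 pairs
with B = 200; the mechanistic experiment uses 80 subjects; Monte-Carlo
transition probabilities use 500 replicates per push. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands.

Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical configuration and seed reproduce
every number bit-for-bit, and pipeline reports embed the resolved
configuration and seed (but not the output directory or timestamps, so
reports from identical runs are byte-identical).

## Known limitations

* The elbow estimate is grid-valued; no confidence interval for t\* is
  provided.
* The permutation p on integer-score cohorts is conservative at small n
  (see calibration section).
* The conditional distance statistic does not localize thresholds and is
  provided for comparison only.
* The bistable engine is a data generator, not an inference target: no
  fitting of h, σ or d to data is attempted.
* Cluster subtotals in synthetic cohorts are shares of the total;
  analyses that need genuinely independent cluster dynamics must
  construct cohorts explicitly (the tests do this where required).
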