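# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `fibconn`. It is the package's own account of its
science; every empirical statement here is one the test suite or the
acceptance script computes.

## The grammar and its annotation

The stimulus grammar is the two-symbol Lindenmayer system with rules
`0 → 1` and `1 → 01`, applied simultaneously to every symbol of the
current string. Starting from the axiom `0`, generation *n* has length
F(*n*) with F(0) = F(1) = 1, and for *n* ≥ 2 equals the concatenation of
generations *n*−2 and *n*−1. Generation 11 (144 symbols) is the
experimental block of the serial reaction-time task. Grammatical strings
contain neither `00` nor `111`: after a `0` the next symbol is forced to
be `1`, and after `11` it is forced to be `0`. Transitions after a single
`1` are probabilistic at the surface.

`parse_down` inverts one rewriting pass by greedy left-to-right chunking
(`01 → 1`, lone `1 → 0`), which is unambiguous because a `0` can only
open a `01` chunk. Iterating it yields the constituent hierarchy: the
level-*k* chunk labels spell out generation *n*−*k*.

**Ambiguity levels.** The annotation assigns each position the smallest
chunking level at which its identity is predictable from the preceding
context. Level 0 applies the two surface rules. A surface-ambiguous
transition always falls on a chunk boundary (its predecessor `1` either
closes a `[01]` chunk or is a lone `[1]` chunk), so the transition is
lifted to the two adjacent constituents one level up and re-classified
there with the same two rules on the label string, recursively. The
determinism context is therefore at most the two preceding labels at
every level, mirroring the surface rules; by the grammar's self-similarity
the regularities are order-2 at every level. Positions that remain
ambiguous at the configured maximum level (default 5; the behavioural
analysis uses levels 0–4) are reported as `unresolved`, and each block is
annotated independently — no context is inherited across block
boundaries.

The assignment is verified against an independent enumeration oracle that
never applies the determinism rules: at each level it collects every
occurrence of the position's (≤ 2-label) context in a long reference
generation (generation 15) and declares the transition deterministic only
if all occurrences are followed by the same label. Rule-based and
enumeration-based levels agree at every position of generations 5–11.

Per analysis level *L*, points are classed as `unambiguous` (level 0),
`disambiguated` (resolved exactly at *L*; a pooling option treats levels
1..*L* as disambiguated instead), `ambiguous` (resolved above *L* or
unresolved), `resolved_below` (resolved at a positive level below *L*),
or `no_context` (first position). The "exactly at *L*" convention is a
deliberate choice; the pooling variant is available because either
reading of "disambiguated at level L" is defensible.

## Task sessions

A session has eight blocks: one 50-item training block followed by seven
repetitions of generation 11 (1008 experimental trials, 1058 total).
The training block draws 31 ones and 19 zeros (the grammatical
proportion 89/144 rounded) and reshuffles until it contains both `00` and
`111`, guaranteeing it is not a grammar output; only the training order
depends on the seed. Stimuli map 0 → red → key `M` and 1 → blue → key
`Z`, with a fixed 500 ms inter-stimulus interval. The artifact emits
stimulus schedules, not an experiment runtime.

## Synthetic cohort and behaviour

Cohort profiles emulate the study demographics: LSBQ composite from a
truncated normal with parent mean 9.01 and SD 2.69 on [5.05, 14.05], age
33.11 ± 9.57 on [18, 57], L2 age of acquisition 6.25 ± 4.63 on [0, 20],
ordinal education, 21/28 female, 2/28 left-handed, and one of six
task-order labels. Note that a distribution truncated to [5.05, 14.05]
cannot have SD 2.69 (the uniform limit is ≈ 2.60), so the configured
mean/SD are parent parameters and the large-sample tests check the
analytic truncated moments.

Trial-level reaction times follow an additive model: baseline 520 ms, a
linear block effect totalling −84 ms from the first to the last block, a
−12 ms offset per LSBQ unit (centred at 9.01), a positive block × LSBQ
interaction at ambiguity levels ≥ 1 (1.0–2.5 ms per block step per LSBQ
unit, growing with level) that flattens the learning slope of more
experienced participants, and an 8 ms slowing per ambiguity level.
Multiplicative noise is mean-one log-normal (σ = 0.12) — right-skewed and
strictly positive, a standard reaction-time noise choice. Correctness is
Bernoulli(0.97). The *shapes* of these effects (signs, block structure)
are what the downstream models are tested against; the magnitudes are
generator configuration, not empirical claims.

Because the training block presents different material from the
grammatical blocks (no ambiguity-level slowing applies to it), the
block-learning check compares blocks 1 and 7 — identical stimuli — and
scales the difference by 7/6 to express it over the full seven block
steps.

## Synthetic resting-state signals

Pre- and post-task recordings are stationary VAR(*p*) processes over the
eight montage regions (medial frontal, left/right central, left/right
temporal, left/right parietal, medial occipital), by default VAR(1) with
diagonal coefficient 0.5 and independent Gaussian innovations of 10 µV.
A directed influence x → y is a non-zero lag-1 coefficient A[y][x]; each
modulated edge adds `baseline + height · exp(−(LSBQ − center)² / 2·width²)`
to that coefficient, so connection strength can peak at mid levels of
bilingual experience (centre ≈ 10) or at the top of the range. The
default ground truth carries one modulated edge (left central → right
parietal, centre 10, width 1.5) with the post-task bump (height 0.5)
twice the pre-task one (0.25), plus a second post-task edge (medial
frontal → medial occipital, height 0.4) — mirroring the qualitative
pre/post pattern the pipeline is meant to resolve. Stationarity is
enforced by refusing coefficient sets whose companion-matrix spectral
radius reaches 1. Simulation operates at ROI level (default 300 s at
128 Hz, the working rate after resampling); an optional mixing mode
spreads each ROI over several electrodes to exercise montage averaging.

What the generator does *not* emulate: volume conduction, 1/f spectra,
non-stationarity, ocular artifacts and real effect sizes. Passing tests
therefore show that the estimators and inference recover the modelled
class of signals, not that effects of any particular published size are
reproducible from real EEG.

## Preprocessing

Filtering is a 4th-order zero-phase Butterworth band-pass (0.1–64 Hz)
followed by polyphase resampling to 128 Hz; no filter family is implied
beyond "zero-phase band-pass", and the high cut is skipped for signals
already band-limited at the working rate. Recordings are cut into
non-overlapping 10 s segments (trailing remainder dropped), and a segment
is discarded if **any** channel violates **any** of four criteria, applied
at the working rate:

| criterion | threshold | window |
|---|---|---|
| gradient | > 10 µV/ms between consecutive samples | — |
| min–max | > 100 µV peak-to-peak | any 200 ms |
| amplitude | outside ±150 µV | any sample |
| low activity | < 0.5 µV peak-to-peak | any 100 ms |

The gradient criterion is interpreted per consecutive-sample pair scaled
by the inter-sample interval to µV/ms. Windows are rounded to whole
samples (26 and 13 samples at 128 Hz). The criteria run fully
automatically — there is no interactive review step. Offline
re-referencing against a standardized reference is out of scope; an
optional common-average reference is provided instead. After rejection,
electrodes are averaged within each montage region and each regional
series is z-normalized (mean 0, SD 1 per recording). The default
region-to-electrode map is a documented, configurable 10–20 grouping of a
32-electrode cap, not a claim about any particular study's exact map.

## Granger causality

For each ordered ROI pair, time-domain bivariate Granger causality is the
log ratio of the residual variance of an order-*p* autoregression of the
target on its own past to that of the bivariate model that adds the
source's past. Both models are ordinary least squares with an intercept
and maximum-likelihood residual variances, so N·GC is the
likelihood-ratio statistic (≈ χ²_p under the null, giving the estimation
bias floor of about p/N on truly independent channels). Lagged
regressors are built strictly within retained segments so that rejection
gaps cannot create spurious transitions. A single model order is shared
by all 56 pairs of a recording, chosen by BIC on the full 8-channel VAR
evaluated on a common sample set (capped at 20 by default); a fixed order
can be configured. GC is invariant to separate rescaling of the two
series, which also makes it insensitive to the montage z-normalization.
Conditional (multivariate) GC and spectral variants are out of scope: the
analysis models a single value per connection.

The estimator is validated against a closed-form oracle: for a bivariate
VAR(1) the stationary covariance solves a discrete Lyapunov equation,
from which the restricted one-lag predictor variance — and hence the true
GC — follows analytically.

## Factor-smooth regression

Each condition's 28 × 56 edge table is modelled as

    gc ~ connection + s(lsbq, by = connection) + age + l2_aoa
         + education + gender + (1 | participant) + (1 | task_order)

with one penalized cubic B-spline smooth per directed connection. Each
smooth uses K = 15 basis functions on an even knot grid over the observed
score range, reduced to 14 by a sum-to-zero constraint (so smooths are
not confounded with the parametric connection term, which the factor
interaction requires). Wiggliness is penalized by a second-order
difference penalty on the basis coefficients with a **fixed** smoothing
parameter of 0.02 — no REML/GCV selection, deliberately. Random
intercepts enter as ridge-penalized indicator blocks (default ridge 1.0);
education is ordinal-coded, gender treatment-coded; handedness is an
optional covariate exercised through the nested-model comparison. The
penalized least-squares problem is solved by Cholesky factorization;
effective degrees of freedom are block traces of the influence matrix
H = (XᵀX + S)⁻¹XᵀX, and the residual variance uses the unbiased divisor
n − 2·tr(H) + tr(HᵀH), which matters because H is not a projection.

**Per-smooth inference.** Each connection's smooth is tested with a Wald
statistic: the coefficient block whitened by the top-r eigencomponents of
its penalized frequentist covariance σ²(XᵀX+S)⁻¹XᵀX(XᵀX+S)⁻¹, with r the
rounded block edf. The reference distribution is the delicate part.
With only 28 observations per smooth and 14 local basis functions, the
whitened contrasts are supported on few observations, and when the
responses are GC estimates near the null their errors are approximately
scaled χ²₁ — strongly skewed and heavy-tailed relative to Gaussian. A
plain χ²_r reference is then anti-conservative, and unacceptably so in
the far tail where the Benjamini–Hochberg step-up operates. The package
therefore offers two references:

* `analytic` — a Satterthwaite-style scaled χ² whose variance includes
  the empirical residual kurtosis; exact χ²_r under Gaussian errors,
  adequate at conventional levels but not in the far tail;
* `bootstrap` (default) — the statistic recomputed under iid resamples
  of errors drawn from the **null model without the smooth blocks**
  (leverage-standardized and centred), pushed through the cached contrast
  geometry. Resampling from the no-smooth fit matters twice over: it
  imposes the null hypothesis, and its residuals are barely shrunk,
  whereas full-model residuals at near-interpolated rows are shrunk
  toward zero and make the bootstrap tail too light. The observed and
  resampled statistics share the same scale estimate, so σ² cancels from
  the comparison. Default 2000 resamples (p-value floor 1/2001, small
  enough for a single BH rejection among 56 tests at q = 0.05).

Simulated calibration under the global null (28-participant cohorts of
independent channels, 500 replicates) holds the per-smooth 0.05 level and
keeps the family discovery probability under BH-FDR at or below 0.05;
the acceptance suite recomputes this check.

The 56 raw p-values are corrected with Benjamini–Hochberg. Nested models
are compared by an approximate likelihood-ratio test (deviance difference
over the full model's scale against χ² with the edf difference) and by
AIC = −2·loglik + 2·edf; the IQR screen flags values outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]. Exact numerical agreement with any
particular external GAM implementation is a non-goal; the construction
(basis dimension, fixed penalty, covariates, random effects, FDR) is the
same, the test machinery is this package's own and is validated by
simulation.

**Behavioural models.** Per analysis level *L*, trials classed ambiguous
vs disambiguated at *L* (ambiguous vs unambiguous at level 0) are fitted
with `rt_ms ~ block * lsbq_c + point_class` and a participant random
intercept (REML, via statsmodels MixedLM), with the score centred at its
sample mean. The tests check recovered *signs*: negative LSBQ offset at
level 0, positive block × LSBQ interaction at levels ≥ 1.

## Problem sizes used in the checks

Simulation-based checks run at sizes chosen to make their Monte-Carlo
error small relative to the asserted margins while keeping the suite
practical to run as a whole: GC oracle agreement uses 10⁵-sample series;
null calibration uses 500 replicates of 28 participants at 10 s per
recording with a fixed order of 1; end-to-end recovery uses 20 replicates
of 28 participants at 30 s per recording with BIC order selection capped
at 6. The pipeline defaults (300 s recordings, order cap 20) are the
full study conditions; the estimator is the same code path at every
length, and the consistency test verifies that its error shrinks with
series length.

## Known limitations

* Pairwise GC is susceptible to common-input and volume-conduction
  confounds; the generator does not model them, so the pipeline's
  specificity on real scalp data is untested here.
* The bootstrap reference assumes errors exchangeable across rows within
  a condition; participant-level error dependence beyond the modelled
  random intercepts is not resampled.
* The behavioural mixed models are a plain random-intercept
  simplification; trial-level autocorrelation within blocks is ignored.
* With 28 participants, smooth estimates near the score range edges rest
  on very few observations; peak localization is only reliable for bumps
  well inside the observed range.
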