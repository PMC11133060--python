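# Methods

This note documents the statistical model behind `fpdiag`, the numerical
choices, the synthetic-data generator, and the limits of what the test suite
demonstrates.

## The fixed-point property and the four-step test

For two fixed base densities f_A, f_B, every mixture p·f_A + (1−p)·f_B
passes through each point where f_A = f_B, independently of p.  The test
asks whether three experimental conditions, assumed to be mixtures of the
same two strategy distributions in proportions that the manipulation moves,
exhibit such a common crossing.

**Step 1 — condition screen.**  Per condition pair, each participant
contributes a summary RT per condition (the mean by default; the summary
function is injectable, e.g. `np.median`).  The paired differences across
participants feed a JZS t-test Bayes factor; the screen passes only if all
three BF₁₀ strictly exceed the condition criterion.  Strict inequality makes
criterion 0 the exact no-screening limit, since Bayes factors are positive.
The choice of participant means (rather than medians or pooled trials) is a
design decision: a paired design across participants is the only structure
consistent with a paired t-test on 44 participants.

**Steps 2–3 — densities and crossings.**  Gaussian KDE with the Silverman
rule h = 0.9·min(sd, IQR/1.349)·n^(−1/5); if one spread estimate is zero the
other is used rather than collapsing the bandwidth.  All three conditions of
a participant are evaluated on one shared 512-point grid spanning
max(0, min − 3·h_max) … max + 3·h_max, wide enough that edge clipping of
density mass is negligible and fine enough that linear-interpolation error is
far below a bandwidth.  Crossings are sign changes of the density difference,
located by linear interpolation; an exact zero at a grid point counts as a
crossing (determinism for synthetic edge cases).  When a pair crosses more
than once, the candidate with the greatest density height wins, ties broken
toward the smaller RT — the fixed point of interest lies where the
distributions carry mass, and an explicit rule beats dependence on search
order.  Participants with a non-crossing pair are dropped listwise from step
4 and recorded in an exclusion log; imputing a crossing would invent data.

**Step 4 — fixed-point Bayes factor.**  The participant × pair crossing
matrix enters a balanced one-way repeated-measures comparison: the null
model has an intercept and a participant random effect; the alternative adds
a condition-pair effect.  Effects carry g-priors on standardised magnitudes
(participant effects N(0, g_a σ²) with g_a ~ InvGamma(1/2, r_a²/2), pair
effects likewise with scale r_b, equivalent to Cauchy priors on standardised
effect sizes), with a Jeffreys prior on (μ, σ²).  The Bayes factor is
reported null-over-alternative so that values above 1 favour a common
crossing distribution — a *present* fixed point.  Default scales are the
conventional r = √2/2 for the t-test, 0.5 for the pair effect and 1.0 for
the participant effect; all are configurable, since the framework's defaults
are an assumption rather than a published setting.

## Numerical integration of the Bayes factors

Both BFs are deterministic quadratures; no MCMC, so identical inputs give
identical outputs bit-for-bit.

*t-test.*  The marginal likelihood under the alternative is a
one-dimensional integral over the g mixing parameter.  With the substitution
g = r²/z² (z standard normal) it becomes a half-line integral with Gaussian
weight, evaluated by adaptive quadrature on a log-stabilised integrand
(the maximum of the log-integrand is factored out first, so t-statistics in
the hundreds do not overflow).  The implementation was validated to
relative error below 1e−8 against an independent route that integrates the
noncentral-t likelihood against the Cauchy prior over the effect size
itself, and against `pingouin.bayesfactor_ttest`.

*ANOVA.*  For the balanced design the marginal covariance
Σ = I + g_a·(participant blocks) + g_b·(centred pair blocks) has three known
eigenspaces — participant means (eigenvalue 1 + a·g_a, multiplicity n),
centred pair means (1 + n·g_b, multiplicity a−1), residual (1) — so the
conditional marginal likelihood reduces to scalars of four sufficient
statistics; the reduction is tested against an explicit dense-matrix
computation.  The two g integrals use a composite Gauss–Legendre product
rule on u = log(g/r²), where the prior weight is scale-free
(∝ exp(−u/2 − e^(−u)/2)) and both tails decay at least exponentially;
55 panels of degree 8 over u ∈ [−10, 45] reproduce a 40,001-point Simpson
reference to ~5e−8 in the log even for |log BF| ≈ 190.  A Gauss–Hermite
rule on the equivalent normal-mixing form was tried first and rejected: its
implicit polynomial assumption gave ~1% errors on extreme cases.  The
Monte-Carlo oracle in the test suite samples g directly from the priors
(≥ 10⁶ draws) and agrees within 3 MC standard errors.

BF magnitudes can exceed float range when conditions are far apart, so all
comparisons and serialised outcomes use log Bayes factors; the linear-scale
`bf10` field may legitimately overflow to `inf` in such extremes.

## Resampling scenarios

Positive controls hold round(P%·n) base-CA trials in condition A (remainder
PR), a 50/50 split in B, and exactly the reciprocal of A in C; rounding is
half-away-from-zero and C's counts are forced complementary so the
reciprocity audit is exact.  Negative controls hold 50/50 splits in all
three conditions but draw A, B, C from the beginning, middle and end thirds
of the session respectively.  Thirds are defined per participant over
responded trials by rank of trial index — the finest unit consistent with
"first third of the data"; with 240 trials the block-based and trial-based
definitions coincide.  Resampling is with replacement (it is a bootstrap); a
without-replacement switch exists because the per-third pools otherwise
bound n_trials.  In the time-on-task scenario only the positives are
permuted over the six condition-to-third assignments; the negatives keep the
identity assignment, which locates the manipulated confound in the positive
controls.  Whether positives should draw from the whole session (as here)
or respect thirds in the reference scenario is an open interpretation; the
whole-session reading matches the plain sense of resampling from the two
experimental conditions.

Seeds follow a spawn hierarchy: one root seed per scenario run, one child
per (replicate, polarity), so results are independent of execution order and
a single polarity can be recomputed in isolation (`bootstrap_polarity`) —
which also enables common-random-number designs where one negative set is
shared across a sweep of mixture proportions.

## Conditional ROC and cAUC

Sweeping the fixed-point criterion from +∞ through every realised BF down to
0 at a fixed condition criterion yields TPR/FPR with *all* positives and
negatives in the denominators; screen failures are permanent non-detections.
The curve therefore tops out at fpr_max ≤ 1 and the conditional AUC is the
trapezoid area over [0, fpr_max] divided by fpr_max, defined as 0 when no
negative survives the screen.  Chance is 25% for CC > 0 — exactly 25% when
the screen passes half of each polarity under exchangeable BFs, which is the
calibration the acceptance script verifies — and 50% for CC = 0, where the
construction reduces to an ordinary ROC.  Confidence intervals are
percentile bootstrap (default 1000 resamples) over replicates, resampled
within polarity; the percentile method is assumption-light given that no
distributional form for cAUC is available.

## The synthetic generator

`generate_experiment` emulates a blocked two-condition lottery-choice task:
conditions alternate over 30 blocks of 8 trials (starting condition
counterbalanced across participants), responses are bounded by a 6.5 s
deadline, and the per-trial expected RT is

    base_mean + condition_effect·1[PR] + tot_slope·(part−1)
              + interaction·(part−1)·1[PR] + participant offset

with part ∈ {1,2,3} the session third of the block.  Defaults: base mean
3200 ms for the slow (calculate) condition, condition effect −730 ms,
time-on-task slope −217 ms per third, interaction −153 ms per third — the
fixed-effect structure a linear mixed model recovers from data of the
emulated task.  Time-on-task enters as a per-third step function rather than
a per-trial drift because every downstream analysis operates at the
granularity of thirds.  Participant heterogeneity is a Gaussian random
intercept (default SD 500 ms), the simplest structure that gives the ANOVA
step realistic between-participant variance.  Trial noise is shifted
lognormal: RT = 0.35·m + LogNormal with mean 0.65·m and σ = 0.5 for cell
mean m, producing the right skew typical of RT data; the family sits behind
a spec object and is swappable, since the machinery under test is
distribution-free.  Deadline violations are redrawn (truncation by
rejection) rather than censored, keeping the retained shape controllable;
omissions are generated independently (default rate 2%) and carry no RT.

Two emulation limits matter for interpreting results.  First, deadline
truncation compresses the slow cells, so the *realised* condition effect is
about 10% smaller than the nominal −730 ms — the recovery test allows for
this.  Second, the generator produces clean, stationary, exchangeable trials
within cells; real data carry autocorrelation, outliers, and strategy drift
that the scenarios deliberately probe only through the modelled time-on-task
term.  Passing scenario tests therefore demonstrates correctness of the
machinery and the qualitative behaviour of the classifier, not performance
guarantees on any particular real dataset — on this synthetic base the
conditional AUCs at P = 100 (~90–97%) are substantially higher than values
reported for real experimental data, where base distributions overlap more.

## Problem sizes and slack in the test suite

The scenario pattern checks run 200 bootstrap replicates per cell (the
reference analyses use 1000–10,000), with replicate seeds shared across
cells and one negative-control set reused wherever its definition is
unchanged; this common-random-number coupling removes most between-cell
noise from pattern comparisons.  Monotone-pattern assertions allow 3
percentage points of slack, sized against the residual sampling error of a
cAUC estimate at 200 replicates.  The end-to-end discrimination check uses
the generator defaults above; at criteria (CC, FPC) = (1, 3) positives are
detected roughly 40 percentage points more often than negatives.

A known intrinsic ceiling shows up clearly in the positive controls: the
three conditions are smoothed with *per-condition* Silverman bandwidths, so
the smoothed mixtures no longer share an exact common crossing even when the
raw mixtures do.  The resulting pair-dependent bias grows relative to
sampling noise as trials increase, which caps the fixed-point BF on true
mixtures at modest values and is one reason the classifier's AUC stays below
ceiling.  A common per-participant bandwidth would remove this particular
bias; per-condition bandwidths were kept as the stated estimator.

## Known limitations

* Only the three-condition design is implemented end to end (the ANOVA
  kernel accepts any number of pair columns, but the pipeline fixes three).
* The ANOVA BF requires a complete crossing matrix; participants with a
  non-crossing pair are excluded listwise rather than imputed.
* Multivariate mixture detection (RT plus accuracy) and parametric ROC
  models are out of scope.
* The 25% chance line is exact only at a 50% screen pass-rate under
  exchangeable polarities; real screen pass-rates vary with the data, and
  the package reports them per cell so users can judge the comparison.
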