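# Methods

## The decay model of conditioned freezing

A retrieval session is scored in 24 consecutive 30-s bins of percent time
freezing; the tone (CS) plays during bins 13–24. Freezing during the tone
window is modelled as exponential decay,

```
y(t) = y0 · exp(−b t),        t = 0, 1, …, 11  (one unit per 30-s bin)
```

with t = 0 at CS onset (bin 13), so `y0` is interpretable as freezing at tone
onset and `b` is the decay rate per bin. Taking natural logs gives
`log y(t) = log y0 − b t`, fitted by ordinary least squares; the decay rate is
minus the slope and `y0` the exponentiated intercept. The fit is exact for
noiseless exponentials (checked to 1e-9 over `y0 ∈ [1,100]`,
`b ∈ [−0.5,0.5]`) and is the maximum-likelihood estimator when noise is
multiplicative lognormal — which is exactly how the synthetic generator
perturbs its curves, so parameter-recovery tests are well specified.

Numerical choices:

- **Zero bins.** 0% freezing has no log. Values below `floor_eps`
  (default 0.1%, configurable) are clipped to `floor_eps` before the log:
  bounded influence, order preserved. If *every* tone bin sits at the floor
  the curve carries no information; a flat fit (`b = 0`, `r² = 0`) is
  returned and flagged `degenerate`, and such animals are dropped from the
  clustering feature matrix with a warning.
- **Constant curves.** With zero variance in log-freezing, the slope is 0
  exactly and R² is undefined (zero total sum of squares); it is reported
  as 0.
- **Scales.** Freezing enters as percent (0–100), matching how the curves are
  plotted; `r_squared` is reported on the log scale, the scale of the fit.
- Component summaries — `phasic_mean` (bins 13–17) and `sustained_mean`
  (bins 18–24) — are arithmetic means of the raw, untransformed percentages.

## Phenotype clustering

Per session the feature matrix has columns `(sustained_mean, b, y0)`. A
two-component Gaussian mixture is fitted by EM:

- k-means++-style seeding with a few Lloyd steps per restart, 20 restarts
  under an explicit seed; best restart by final log-likelihood.
- Convergence at relative log-likelihood change ≤ 1e-8 (default), cap 500
  iterations; the per-iteration log-likelihood trace of every restart is kept
  on the model and its monotonicity is asserted in the test suite.
- Each covariance gets a ridge of 1e-6 × mean feature variance on its
  diagonal, so collapsed clusters return a valid model instead of diverging.
- Covariance families: `spherical`, `diagonal`, `full`; free-parameter counts
  feed `BIC = −2 log L + p ln n` (smaller is better).

The component with the larger mean of the `sustained_mean` feature is
labelled *sustained*, the other *phasic* — the mapping depends only on
component statistics, never on component order. Assignment is by maximum
responsibility; an exact 0.5 tie goes to sustained (the conservative
direction for an anxiety screen) and is flagged.

**Cohort-level defaults.** The pipeline helper `cluster_cohort` clusters each
sex separately with a **diagonal** covariance family. Both choices are
deliberate. The sexes differ additively in sustained-phase freezing, so a
pooled two-component fit faces four sub-populations; single-sex cohorts are
also how such experiments are typically run and analysed. And within the
phasic group, `sustained_mean` is a curved (exponential) function of `b`: an
unconstrained covariance ellipse elongates along that curve and confidently
captures animals with intermediate decay rates that a near-optimal decision
boundary would leave phasic, measurably degrading truth recovery on synthetic
cohorts; the diagonal family does not have this failure mode at cohort-sized
n (~24–48 per sex, d = 3). Likelihood-based family selection does not rescue
the full family — BIC prefers it precisely because the elongated ellipse fits
the curved cloud well — which is a known limitation of choosing the family by
fit quality when the clusters are not Gaussian. `em_fit` itself keeps `full`
as its generic default, and both `per_sex` and `covariance_family` are plain
arguments. Features are not standardised by default; `scale=True` z-scores
them first.

**Variable selection.** The greedy search scores a candidate subset by the
clustering evidence `BIC(k = 1) − BIC(best k = 2)` (positive favours two
clusters); a forward pass adds, then a backward pass removes, the feature
whose step most improves the evidence, stopping when no step improves.
Constant columns are excluded beforehand. If the best subset has non-positive
evidence the result is flagged "no clustering support". This is a simplified
form of stepwise clustering-variable selection; the regression adjustment
used by more elaborate procedures is intentionally not reproduced.

**Shifters.** Consistency is derived solely from the MR1 and MR2
assignments: equal labels → `consistent_*`; sustained→phasic or
phasic→sustained → the corresponding shifter category; a missing session →
`unclassified`. Shift rates are reported conditional on the MR1 group.

**Extreme responders.** Mode `mr1_profile` ranks sustained candidates by
sustained freezing descending with decay rate ascending as tie-break (and the
mirror image for phasic); mode `consistency_oft` restricts to consistent
animals and ranks by open-field periphery time (descending for sustained,
ascending for phasic). Animals lacking the periphery metric are excluded with
a warning; asking for more animals than available is an error that states the
available count. Sorts are stable, so ties beyond the tie-break preserve
input order.

## Trait statistics

- **Correlation matrices:** pairwise-complete Pearson r, two-sided p from the
  t transform with n − 2 df, and a display mask at raw p < α (default 0.05).
  No multiple-testing correction is applied — this matches the usual masked
  display of such matrices but inflates family-wise error; treat the mask as
  descriptive.
- **Cohen's d** uses the classic pooled SD (degrees-of-freedom-weighted
  variances, no small-sample correction); sign is first argument minus
  second, so call as (sustained, phasic).
- **Two-sample tests:** Welch by default (Welch–Satterthwaite df), pooled df
  on request; the degenerate zero-variance-equal-means case returns p = 1
  with a warning rather than NaN.
- **Extinction slopes:** per animal-session component means regressed on the
  retrieval index (MR1 = 1 … MR6 = 6) by pooled OLS over all animal-session
  points in the group — one coefficient per group, no random effects. The
  points are not independent across sessions of the same animal, so the
  printed p is anti-conservative; the slope itself is unbiased.
- **Variance profile:** (n−1)-denominator variance per bin across animals;
  peak bin is the 1-based argmax, ties to the smallest index.
- **Outlier screen:** z-scores with (n−1)-denominator SD, flagged at
  |z| > 2.81 — the two-sided standard-normal critical value at p = 0.005
  rounded to two decimals; a zero-SD sample flags nothing.

## Gene-set overlap

Symbols are upper-cased on load; the universe is an explicit required input
(never inferred), because the hypergeometric p depends directly on it.
Symbols outside the universe are dropped with a warning. The two-sided p is
the exact probability-mass criterion (sum of hypergeometric table
probabilities not exceeding the observed one — the convention of standard
exact-test implementations, verified against a full-enumeration oracle to
1e-10 for all margins ≤ 12). The odds ratio is the sample (a·d)/(b·c), with
Haldane's +0.5 added to all four cells only when some cell is zero.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
mouse biology. Per animal: sex; an MR1 phenotype drawn with
`p_sustained = 0.5`; a decay rate from `N(0.25, 0.05)` (phasic) or
`N(0.02, 0.02)` (sustained) per 30-s bin; an onset level from `N(85, 8)` %.
Per retrieval, the tone-window curve `y0 · e^(−b t)` gets multiplicative
lognormal noise (log-SD 0.25), baseline bins come from `N(8, 4)` %, and all
values are clamped to [0, 100]. Females receive a +10% additive boost on the
sustained-phase bins — an *off-curve* perturbation (the boosted bins no
longer lie on an exponential), chosen deliberately so the sex effect
concentrates in the late bins. The onset level drops by 6% per successive
retrieval (extinction, clamped at 1%). Between MR1 and MR2 each animal
switches phenotype independently with probability 0.30 (sustained→phasic) or
0.17 (phasic→sustained), drawing a fresh decay rate for the new phenotype;
these defaults sit inside the observed shifter ranges (27.5–34% and
15.8–17.5%). Anxiety metrics are drawn per true MR1 phenotype with sustained
animals higher on avoidance measures (periphery/corner time) and lower on
approach measures (object approaches, open-arm and light time); the
magnitudes are generator conventions, not empirical claims. Default cohort
size is 48 per sex, sessions MR1–MR2.

What passing tests on this generator do and do not show: they demonstrate
that the estimator, the clustering, the shifter logic and the statistics
recover known structure under the model's own assumptions (lognormal noise,
Gaussian-ish feature clouds, independent Bernoulli shifting). Real freezing
data have bounded support with mass at 0 and 100, serial correlation within a
session, non-lognormal noise, and phenotype shifts that are not independent
coin flips — none of which the generator reproduces (a heavier-tailed noise
mode can be emulated by raising `sigma_log`). Recovery on synthetic cohorts
is therefore a correctness check of the implementation, not evidence about
any particular dataset.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is deterministic given
it; cohort generation is byte-identical for identical config + seed. The
verification suite uses the sizes at which its guarantees are stated: 1,000
noiseless curves for fit exactness; 100 seeded EM fits (n = 500, 1-D) for
trace monotonicity plus one n = 2,000 comparison against an independent
long-run EM; 40 seeded default cohorts (96 animals) for cluster recovery;
500 animals for shifter-rate recovery; all 2×2 tables with margins ≤ 12 for
the exact test. These sizes keep the full suite and the acceptance script in
the tens of seconds on a single CPU.

## Known limitations

- The log-linear fit weights multiplicative error equally across bins; with
  additive noise near zero freezing the log transform amplifies low-freezing
  bins (mitigated, not removed, by the floor).
- The EM implementation covers exactly what the pipeline needs (k ≤ 2 in
  practice, three covariance families, seeded restarts); it is not a general
  mixture-modelling library.
- Pooled-OLS extinction p-values ignore within-animal correlation (above).
- The correlation mask at raw p < 0.05 is descriptive, not inferential.
- Shifter classification uses hard assignments; posterior uncertainty is
  available per animal but not propagated into the shift rates.
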