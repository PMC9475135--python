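# Methods

## The factorial null-model test

A two-stressor factorial experiment is summarised by twelve numbers: a
mean X̄_x, a sample standard deviation SD_x, and a replicate count N_x for
each arm x ∈ {C, A, B, I}.  The additive null hypothesis is that the
combined effect equals the sum of the individual effects,
X̄_I − X̄_C = (X̄_A − X̄_C) + (X̄_B − X̄_C); the interaction contrast
X̄_I − X̄_A − X̄_B + X̄_C measures the deviation.  Standardising by the
four-group pooled SD

    s = sqrt( Σ_x (N_x − 1)·SD_x² / (ΣN_x − 4) )

and correcting for small-sample bias with J = 1 − 3/(4·df − 1), df =
ΣN_x − 4, gives the effect size ES_Add = J·contrast/s, with variance

    V_Add = J²·( Σ_x 1/N_x + ES_Add²/(2·ΣN_x) ).

The test rejects when ES_Add ± z(α/2)·√V_Add excludes 0 (α = 0.05
two-tailed by default).  df is reported for information; the interval uses
the normal quantile, not a t quantile.  Conventions that the notation
leaves open were fixed as follows:

* J multiplies the standardized contrast (the usual Hedges-g convention,
  consistent with the J² prefactor in the variance); the alternative
  (dividing by J) changes results by less than J².
* The effect size is positive when the combined response sits *above* the
  additive expectation.  Sign conventions differ across the literature;
  classification is made direction-aware so labels never depend on this
  choice.
* J² multiplies the entire variance bracket.  The alternative bracketing
  changes the n = 4 critical effect size by ~1% (1.94 vs 1.96).
* The bias correction uses the standard rational approximation to the
  exact gamma-function form; the two differ by ~1e-4 at df = 18 (checked
  against metafor's SMD in the test suite).

The multiplicative null model, preferable for bounded responses such as
survival probabilities, works on the log scale: ES_Mult = ln X̄_I −
ln X̄_A − ln X̄_B + ln X̄_C, zero exactly when the response ratios
multiply (X̄_I·X̄_C = X̄_A·X̄_B), with the delta-method variance
Σ_x SD_x²/(N_x·X̄_x²), which does not depend on the effect size.  All four
means must be strictly positive; otherwise the additive model applies.  No
small-sample correction is applied on the log scale (j_correction = 1).

## Classification

A non-significant result is always "null" — failure to reject is not
evidence of additivity.  A significant result is labelled from three
quantities on the model's scale: the net individual effect S = E_A + E_B,
the deviation D = observed − expected combined effect, and the combined
effect T = X̄_I − X̄_C (log analogues for the multiplicative model):

| condition (S < 0)          | label         |
|----------------------------|---------------|
| D < 0                      | synergistic   |
| D > 0, T ≤ 0               | antagonistic  |
| D > 0, T > 0               | reversal      |

mirrored for S > 0.  Reversals are thus defined against the *sum* of the
individual effects (an alternative would compare against each individual
effect separately); the sum-based rule matches the standard taxonomy in
the multiple-stressor literature and keeps the partition exhaustive.  Ties
(S = 0 or T = 0, measure-zero under continuous data) are fixed
deterministically: S = 0 gives reversal when T ≠ 0 and antagonistic
otherwise; T = 0 counts as "keeping S's sign".

## Critical effect size

Because V_Add is increasing in |ES|, the rejection condition
|ES| > z·√V_Add(ES) is equivalent to |ES| exceeding a single threshold,
obtained by solving the equality:

    ES_crit = sqrt( z²·J²·Σ(1/N_x) / (1 − z²·J²/(2·ΣN_x)) ).

The library also ships an independent bisection solver for the same root;
the two agree to 1e-8 over n ∈ {3..100} and α ∈ {0.01, 0.05, 0.1} (a
regression test).  The configuration is infeasible when the denominator is
non-positive (only reachable at pathologically small α).  ES_crit is
strictly decreasing in every N_x and in α.  For the multiplicative model
the variance is effect-size-free, so the analogous threshold is simply
z·SE; the table pipeline reports it as such.

## Monte-Carlo power engine

Each simulated experiment draws N_x independent Gaussian replicates per
arm with the configured expected means and SDs (σ_x = E[SD_x]), reduces
them to (sample mean, sample SD with the n − 1 denominator, n), and runs
the additive (or multiplicative) test.  Draws are not truncated even when
the response is a probability; the plain-Gaussian scheme is the object of
study, and truncation to [0, 1] is available as an off-by-default option
(irrelevant for the default configurations, where the means sit several σ
from the boundaries).

* **Power** is the proportion of simulations that are significant *and*
  whose classified label matches the label implied by the population
  parameters; significant results with the wrong label are tallied but do
  not count.  When the population deviation is zero the same routine
  reports the empirical type-I error rate.
* **true_effect_size** is the population contrast divided by the pooled σ
  (no J, which depends on n); this is the denominator of the bias ratio.
* **Detection bias** is the mean |ES| over significant simulations divided
  by the true |ES|.  Since every detected |ES| exceeds ES_crit, the ratio
  is bounded below by ES_crit/|true ES| — the inflation at small n is pure
  selection on significance, not estimator bias (averaged over *all*
  simulations the effect size is unbiased; a regression test checks this
  at n = 200).
* **Minimum sample size** scans n upward with an independent random
  substream per grid point (one top-level seed spawns per-n streams; no
  common random numbers) and returns the first n whose estimated power
  reaches the target, plus the full (n, power, mc_se) trace for power
  curves.

The engine is vectorised over simulations; 1000 simulations per grid point
(the default) and grids to n = 100 run in seconds, so no corner is cut on
simulation size anywhere in the tests or the acceptance script.
`simulate_experiment` exposes the identical generative law one experiment
at a time for inspection and testing.

The default reference configurations set E[X̄_C] = 0.8, E[X̄_A] = E[X̄_B]
= 0.65, σ_x = 0.05, with the combined-arm expectation E[X̄_I] ∈ {0.525,
0.55, 0.60, 0.65} giving true effect sizes {0.5, 1, 2, 3} (the contrast
|X̄_I − X̄_A − X̄_B + X̄_C|/σ evaluates to these values in this order) —
all antagonistic truths; E[X̄_I] = 0.45 gives the synergistic true ES −1.

### Exact benchmark of the engine

Under equal n, ES_Add is distributed as J·√(4/n)·T where T is noncentral t
with df = 4n − 4 and noncentrality (true ES)·√(n/4) — the pooled SD is
independent of the contrast.  This closed form, together with the
rejection threshold ES_crit, gives exact power values that the Monte-Carlo
engine matches to MC error at every configuration checked, e.g. 0.692 at
n = 3 / ES = 3; 0.601 at n = 20 / ES = 1; first n with power ≥ 0.8 equal
to 4, 8–9, 31–32 for ES = 3, 2, 1; no n ≤ 100 reaching 0.8 at ES = 0.5.
Readers comparing with published power curves for this design should note
that figures generated with other software can differ in the small-n
regime (e.g. values nearer 0.5 at n = 3 / ES = 3); the numbers above are
what the equations in this note imply, and the test suite asserts the
Monte-Carlo engine against the noncentral-t form, not against any external
curve.

One consequence of the z-based interval on a t-distributed statistic is a
mildly inflated type-I error at very small n (≈ 0.069 at n = 3, ≈ 0.052
at n = 20, exact values from the same noncentral-t form at zero
noncentrality); calibration tests therefore use moderate n, and the
small-n inflation is inherent to the method, not to this implementation.

## Synthetic experiment tables

The fixture generator builds populations whose *true* label is known, then
samples summaries with the same Gaussian scheme as the power engine.  Per
experiment: a control mean (default U(0.6, 0.9)), two individual stressor
effects (default U(−0.3, −0.05); both endpoints must share a sign so S is
never zero — a mixed-sign range raises an infeasible-mix error), a common
σ (U(0.02, 0.08)), and a non-null deviation of magnitude |D| =
(deviation scale)·σ with the deviation scale drawn from U(0.5, 3.0).  The
combined-arm mean is then placed to realise the assigned label:
synergistic pushes past the additive expectation in the direction of S;
antagonistic pulls back by min(|D|, 0.9·|S|) so T keeps S's sign; reversal
places T on the opposite side of the control by |D|.  Replicate counts are
geometric offsets from the range minimum (mode 3–4, default range 3–30),
mirroring the low replication typical of published multiple-stressor
experiments.  A `*_truth.csv` sidecar records the generating parameters;
tests verify that label recovery matches the power engine's per-experiment
predictions to binomial accuracy.

What the generator does *not* emulate: non-Gaussian or heteroscedastic
replicate noise, correlated arms, bounded responses, unequal per-arm
replication within an experiment, and publication filtering.  Passing
tests therefore demonstrate correctness of the machinery under the
Gaussian generative model, not robustness of the null-model test to
real-data violations of it.

## Numerical and interface choices

* CSV round-trips are exact: writing uses the shortest round-trip float
  repr and reading uses round-trip float parsing.
* Dispersion input may be SD (default), SE (converted via sd = se·√n), or
  variance; blank cells are row-level errors, never imputed, and failed
  rows are carried through result tables with an error code rather than
  dropped.
* Simulations in the multiplicative power engine whose sample means are
  not all positive (log undefined) are tallied as non-significant; this is
  unreachable for configurations whose means sit a few σ above zero.
* All stochastic entry points take an explicit seed; identical
  configuration and seed give bit-identical results.

## Known limitations

Only two stressors at one intensity each; summary-statistic input only (no
replicate-level data); no equivalence testing for "confirming" additivity;
no analytic power approximation (Monte-Carlo only); the critical effect
size is exact for the additive model and a z·SE convenience for the
multiplicative one; no multiple-testing correction across table rows.
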