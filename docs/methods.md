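# Methods

## Model

The partial credit model (PCM) gives the probability that person *n* with
location θ on the latent burnout scale answers item *i* in category
x ∈ {0, …, m<sub>i</sub>}:

    P(X_i = x | θ) = exp( x·θ − β_ix ) / Σ_j exp( j·θ − β_ij ),
    β_ix = δ_i1 + … + δ_ix,   β_i0 = 0,

where δ<sub>ik</sub> is the k-th threshold of item *i* — the location at
which categories k−1 and k are equally probable. Externally items are coded
1–5; internally everything is 0-based. The model assumes
unidimensionality, monotonicity (E[X|θ] strictly increasing, which holds
for any threshold vector, ordered or not), invariance of item parameters
across person groups, and local independence given θ.

## Estimation

**Items (CML).** Conditioning on a person's raw total score removes θ from
the likelihood, so threshold estimates do not depend on the person
distribution — this is the operational meaning of invariance and the
reason CML is used rather than joint or marginal ML. The conditional
likelihood is evaluated through elementary symmetric functions
γ<sub>r</sub> (sums of exp(−Σβ) over all response patterns with total r),
computed by item-by-item convolution in the log domain. The function is
concave in the thresholds; optimization is L-BFGS with the analytic
gradient followed by Newton polishing (finite-difference Hessian of the
analytic gradient) to a per-observation gradient tolerance of 1e-8,
capped at 200 iterations. One direction is unidentified (adding a constant
to every threshold); the gauge is fixed by centring the mean item location
(mean of each item's thresholds, averaged over items) to 0, and standard
errors come from the observed conditional information with that flat
direction deflated exactly and projected out. Persons with extreme totals
carry no conditional information and are skipped.

Every category must be observed among non-extreme persons for its
threshold to be estimable. Under realistic floor effects (low-burnout
cohorts rarely answer "always") top categories can be empty even at
n = 2000, so estimation is preceded by an explicit collapse of unobserved
categories into their lower neighbour; the collapse map is returned and
logged, and any comparison of estimates with an external calibration must
run through that map and re-centre the gauge, because dropping categories
shifts the mean item location.

**Persons (ML).** θ̂ solves E[total | θ] = observed total (safeguarded
Newton); SE = information<sup>−1/2</sup> at θ̂. Raw scores are sufficient,
so persons with equal totals get identical estimates. Extreme scores (0 or
maximum) have no finite ML estimate; they are adjusted 0.3 score units
toward the interior, flagged, and excluded from all fit statistics.

## Fit diagnostics

Standardized residuals are z = (x − E[x]) / √V[x] with moments at θ̂. The
item fit residual standardizes y<sub>i</sub> = Σ<sub>n</sub> z²
by model-implied moments and maps it to a unit-normal scale with a
Wilson–Hilferty cube-root transform (effective df from moment matching).
Two corrections matter and were derived analytically, then verified by
simulation:

* because θ̂ is a function of the raw total and the total is sufficient,
  the moments of z² are computed under the **exact conditional
  distribution** P(X<sub>i</sub> = x | total = r), obtained from the same
  ESF recursions used in estimation — the naive E[z²] = 1 would bias every
  fit residual downward by ≈ −0.8 at 23 items;
* because the CML score equations force observed category counts to equal
  their conditional expectations, y<sub>i</sub> loses the variance of its
  projection onto the item's own sufficient statistics; Var(y<sub>i</sub>)
  is therefore reduced by cᵀI⁻¹c (c the conditional covariance of z² with
  the item's category indicators, I the item's own information block;
  cross-item coupling neglected). Without this the fit residuals have SD
  ≈ 0.6 instead of 1.

With both corrections, null simulations at n = 800 give item fit residuals
with grand mean ≈ 0.00 and per-cohort SD ≈ 0.95–1.05. Person fit residuals
use a first-order shrinkage approximation instead (exact conditional
moments of a within-person sum would need cross-item conditional
covariances); measured null mean ≈ 0.01, SD ≈ 1.01. The fit-residual
standardization is a documented dialect: the exact recipe of commercial
Rasch software is unpublished, and correctness is judged by these
expectation properties, not by matching any published table.

The item χ² compares interval sums of z across g class intervals of θ̂
(g = min(10, ⌊n/50⌋) by default, ties kept together), χ² =
Σ<sub>c</sub>(Σ<sub>n∈c</sub> z)²/|c| with df = g−1 per item; the overall
statistic sums items. The df convention is a dialect; the test is mildly
conservative under the model, which errs on the side of not flagging.
Threshold ordering flags any adjacent reversal; the hybrid hypothesis test
on a reversed pair computes z = (δ<sub>k+1</sub> − δ<sub>k</sub>)/√(SE²+SE²)
and returns *ordered* / *disordered* / *undecided* at α = 0.01 one-sided in
each direction, so a noisy reversal stays undecided.

## Local dependency and unidimensionality

Residual Pearson correlations are flagged at exactly 0.2 above the average
off-diagonal correlation, with within/between-subscale labels. PCA of the
residual correlation matrix (eigendecomposition; deterministic sign
convention) feeds Smith's test: persons re-estimated separately from the
positive- and negative-loading item sets (item parameters fixed), per-person
t = (θ̂⁺ − θ̂⁻)/√(SE⁺² + SE⁻²), proportion of |t| > 1.96 with an exact
(Clopper–Pearson) binomial 95% CI, verdict unidimensional iff the lower
bound ≤ 5%.

One design choice deviates from the classic protocol deliberately: picking
the split from the PC1 of the *same* residuals being tested is optimistic
— a pure-noise residual matrix has λ₁ ≈ (1+√(k/n))² > 1, which inflates
var(t) to ≈ 1.23 at k = 23, n = 800 and the null significance rate to
7–8%. A random split (no selection) gives var(t) ≈ 0.94 and ≈ 4.5–5%,
showing the estimator itself is calibrated. The default therefore
**cross-fits**: persons are split into two seeded halves, each half's PC1
defines the item split applied to the other half, and the t statistics are
pooled. Real structure is estimated consistently from either half, so
power is unchanged (latent correlation 0.6 is still detected in 100% of
runs), while the null rate returns to ≈ 5% with unidimensional verdicts in
≥ 90% of cohorts. The classic single-sample protocol remains available
(`residuals=None`), as does the |loading| ≥ 0.3 selection cutoff (off by
default).

## DIF

Per item, a two-way fixed-effects ANOVA of z on group × class interval
(observation-level, Type II sums of squares via statsmodels): the group
main effect tests uniform DIF, the interaction non-uniform DIF; Bonferroni
across items at base α = 0.01. Empty cells are handled by merging
intervals downward with a warning. Measured at n = 800: a +0.5 logit
uniform shift on one item is flagged in 10/10 seeds; null flag rates are
≈ 0–1 per 230 item tests.

## Testlets and variance decomposition

Each subscale's items are summed into one super-item (EX scores 0–32,
others 0–20; sparse categories collapsed as above) and the PCM is re-fit.
With α_items the coefficient alpha of the 23 item columns and α_testlets
that of the 4 testlet columns: non-error proportion = α_items, common
true-score proportion = α_testlets, unique = difference, error =
1 − α_items, and the headline ratio common/non-error = α_testlets/α_items
(0.94 and 0.81 give 0.86). Subscale latent correlations fit each subscale
as its own PCM, correlate the person estimates, and disattenuate by
√(PSI_a·PSI_b), capped at 1 (subscale alpha available as an alternative
reliability by flag); a generating latent correlation of 0.61 is recovered
within ±0.02–0.05 at n = 800. PSI = (var(θ̂) − mean(SE²))/var(θ̂), floored
at 0, non-extreme persons only.

## Synthetic data

The generator draws subscale-specific person locations from a multivariate
normal — mean −0.95, SD 0.63 per subscale (the published calibration's
person distribution), correlation matrix configurable; the default is the
all-ones matrix, i.e. one shared θ, the strictly unidimensional PCM —
and samples each item from its PCM distribution with the bundled published
thresholds. Floor effects (top categories almost never used, huge SEs for
top EI thresholds) emerge from the thresholds plus the low person mean; no
extra censoring is applied. Uniform DIF shifts the focal group's
thresholds; non-uniform DIF multiplies the focal group's centred θ by a
slope factor (default 1.5); response dependency makes a target item copy a
source item's category with probability ρ. Marginal category frequencies
match a Gauss–Hermite quadrature oracle at n = 50 000.

What the generator does *not* emulate: real response styles (social
desirability, acquiescence), person misfit, missing-data mechanisms beyond
the rule-based injector, and — importantly — the full strength of the
local dependency seen in real multi-symptom scales. With per-subscale SD
0.63 and latent correlation 0.6 the subscale-unique variance is
0.63²·(3/4)·(1−0.6) ≈ 0.12, which yields within-subscale residual
correlations of only ≈ +0.01 (vs between ≈ −0.06): detectable by Smith's
test, but below the average+0.2 flag threshold and too weak to push the
overall χ² into significance at n = 800. Reproducing residual correlations
of ≈ 0.2 would require a subscale SD near 1.2. Passing tests on this
generator therefore demonstrate calibration of the machinery and
qualitative contrasts, not that every diagnostic reaches the effect sizes
seen in strongly dependent real data; the dependency injector exists
precisely to exercise the flagging rule at realistic strengths.

A related metric caveat: the published person distribution (−0.95, 0.63)
belongs to the testlet-level analysis, while the bundled thresholds come
from the item-level analysis. Combining them (as the defaults do) yields a
simulated overall burnout median of ≈ 2.5 on the 1–5 scale rather than the
≈ 2.0 of the calibration cohort; the qualitative profile (low burnout,
exhaustion elevated, floor effects on MD/CI/EI) is preserved.

## Numerical and reporting conventions

Quartiles use linear (type-7) interpolation, so (1,2,3,4,5) → Q1 = 2,
Q3 = 4; one-decimal reporting makes quartile conventions
indistinguishable in practice. Mann–Whitney uses the tie-corrected normal
approximation. Median-age splits put ties in the younger group
(configurable). The pipeline writes a JSON summary (2 decimals for fit
statistics, 1 for descriptives internally rounded as printed) plus CSV
tables; identical input and seed give byte-identical JSON. Problem sizes
throughout the test suite and the acceptance script (n = 800 cohorts, 20
replications; n = 2000 for threshold recovery) were chosen to match the
calibration study's sample sizes while keeping each simulation battery in
the tens of seconds.

## Known limitations

* CML here is full conditional estimation; pairwise-conditional dialects
  of commercial packages will differ in the third decimal, so agreement
  with published threshold tables is assessed by parameter recovery, not
  digit matching.
* Raw CML standard errors are reported; thresholds supported by a handful
  of responses (reversed or extreme categories) get very large SEs and
  their estimates are effectively unidentified — they are excluded from
  recovery tolerances rather than shrunk.
* Person estimates are plain ML with the 0.3 extreme-score adjustment; no
  Warm correction.
* The DIF ANOVA weights observations, not intervals; with very unbalanced
  intervals its F statistics differ from an interval-weighted dialect.
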