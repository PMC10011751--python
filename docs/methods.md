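# Methods

## The MEff correction

Given k outcome measures with correlation matrix **R** (unit diagonal,
positive semi-definite), let λ₁ ≥ … ≥ λ_k be its eigenvalues; they sum to
k. The effective number of independent tests is

    MEff = 1 + (k − 1) · (1 − Var(λ) / k),

and the per-outcome significance threshold is alpha_MEff = alpha / MEff.
The eigenvalue variance uses the **sample** denominator (k − 1). This is a
documented, load-bearing convention: for six equicorrelated outcomes at
r = .4 the squared deviations of the eigenvalues from their mean (always 1)
sum to 4.8, and only 4.8/5 = 0.96 reproduces the published worked example;
the population denominator would give 0.80 and a different alpha. With the
sample denominator the equicorrelated closed form is Var = k·r² and
MEff = 1 + (k−1)(1 − r²), which the tests use as an independent oracle
against the numeric eigendecomposition (agreement required to 1e−10).

MEff interpolates between Bonferroni and no correction: r = 0 gives
MEff = k, r = 1 gives MEff = 1. It is not a new estimator family — the
variance-of-eigenvalues form above is the only one implemented, by design.

Validation of user matrices is strict but non-destructive: symmetry within
1e−6 (then symmetrised), diagonal exactly 1, off-diagonals in [−1, 1],
eigenvalues ≥ −1e−8 (clipped to zero). Indefinite matrices are rejected;
there is deliberately no nearest-PSD "repair", because silently projecting
a user's matrix would change the answer without telling them.

### Presentation rounding

All computation is full precision. Table rendering rounds half-up at the
printed precision (3 dp for alphas, 1 dp for eigenvalues and MEff, 2 dp for
Var), after first quantising at 10 decimals so eigensolver noise just below
an exact tie (0.05/4 computing as 0.012499999…) cannot flip the rounding.

### Block structures and the scalar-r shortcut

A two-factor outcome suite has a block correlation matrix: r within each
block, 0 across. Its spectrum is the union of the blocks' equicorrelated
spectra. MEff is empirically robust to this structural difference: across
within-block correlations .2–.8 and suite sizes 4–8, the adjusted alpha of
the block matrix and of the *uniform* matrix with the same mean
off-diagonal differ by at most .002 (asserted in the tests). This is what
licenses the study evaluator to accept a scalar mean correlation — e.g.
read off a test manual — instead of a full matrix. The matched uniform
comparison is made per suite size: for k outcomes in two blocks of k/2, the
mean off-diagonal is 2·C(k/2, 2)/C(k, 2) · r, so the comparison value
depends on k (at k = 8 it is (12/28)·r). When only a range of plausible
correlations is available, the evaluator reports the alphas at both
endpoints rather than silently picking a point estimate.

The lookup-style function `alpha_from_lookup(k, r)` computes the exact
equicorrelated value at the supplied r; the rounded 3-dp grid is a
presentation artifact and is only consulted in an explicit audit mode
(`use_table=True`, nearest grid row). Intermediate correlations are never
interpolated from rounded cells.

## The latent-factor simulator

Outcomes are indicators of one or two latent constructs that mediate the
intervention effect:

    V_j = a·L + sqrt(1 − a²)·e_j,     L, e_j ~ N(0, 1) independent,

so each outcome has unit population variance and any two outcomes sharing
a latent correlate at a². To target a mean inter-outcome correlation r the
loading is a = sqrt(r); to produce a standardized per-outcome effect E the
latent shift in the intervention arm must be E_l = E / sqrt(r), because
only the fraction a of a latent shift reaches each indicator. r = 0 has no
latent-factor representation (the loading vanishes and E_l diverges), so it
is rejected whenever an effect is requested; it *is* accepted for pure-null
configurations, where it degenerates cleanly to independent standard-normal
outcomes — needed for the independent-outcomes FWER demonstration.

Three layouts:

* **L1** — one factor behind all k outcomes; the intervention shifts it.
* **L2** — two independent factors, each behind a block of outcomes
  (ceil(k/2) and floor(k/2); the first factor takes the extra outcome when
  k is odd, consistent with "the first factor is the affected one" in L2x);
  both factors are shifted.
* **L2x** — as L2 but only the first factor is shifted, so the second
  block of outcomes is null.

Each subject contributes a single simulated value — no pre/post change
scores, no covariates. Draw order (latents, then errors) is fixed, so a
seed pins the dataset bit-for-bit.

What the simulator does **not** emulate: non-normal or binary outcomes,
missing data, unequal loadings across outcomes, correlated latent factors,
more than two factors, or measurement occasions. Passing tests therefore
show that the decision rules behave as claimed under a clean
Gaussian-indicator world; they do not certify behaviour under skewness,
floor effects or attrition.

## The power engine

Per replication: simulate a dataset, compare arms per outcome with a
one-tailed two-sample t-test (alternative: intervention mean greater —
intervention research carries a directional hypothesis), and apply each
decision rule:

* *uncorrected*: any p < alpha;
* *Bonferroni*: any p < alpha/k;
* *MEff*: any p < alpha/MEff;
* *PCA*: one test at full alpha on first-principal-component scores of all
  outcomes, both groups combined, centred, unscaled (the outcomes are
  unit-variance by construction), sign-oriented so the loadings sum
  positive — without that convention a one-tailed test on PC scores would
  be undefined.

Strict inequality throughout. The t-test is the Welch (unequal-variance)
form by default; the generative model has equal arm variances so the choice
is inconsequential, but it is explicit and a pooled-variance switch exists.

The MEff threshold inside a replication is recomputed by default from that
replication's **pooled within-group** sample correlation matrix: each arm
is centred at its own mean before correlating, so a true group effect does
not inflate the apparent inter-outcome correlation. A `meff_corr =
"population"` option uses the known generative matrix instead; both are
legitimate and they agree closely, so neither is asserted as canonical.

Replications use per-replication RNG substreams spawned deterministically
from the root seed, so a run is reproducible and replications are
independent. Power is the positive-replication proportion, reported with
binomial Monte-Carlo standard error sqrt(p(1−p)/n_sims). Default grids
mirror the study conditions: n ∈ {20, 50, 80} per arm, E ∈ {0, .3, .5},
r ∈ {.2, .4, .6, .8}, k ∈ 2…8, 2000 replications.

The analytic single-outcome reference is one-tailed noncentral-t power
(df = 2n − 2, noncentrality E·sqrt(n/2)); the selective-effect (L2x)
reference averages the powered and null single-outcome powers, the
expectation if a lone primary outcome were drawn from either family with
equal probability.

### Problem sizes

Monte-Carlo assertions in the tests run at 2000 replications with 50
subjects per arm — the study's own replication count — for each condition;
distributional checks on the simulator use n = 10⁴ per arm for correlation
recovery (tolerance ±.02) and n = 10⁵ for effect-size recovery (±.02).
Qualitative power comparisons (orderings between rules) are asserted up to
twice the Monte-Carlo standard error, with fixed seeds so the suite is
deterministic.

## Known limitations

* MEff controls the FWER approximately; it is exact at the independence
  and rank-one extremes and mildly conservative or mildly liberal in
  between (the null-calibration tests bound it at alpha within Monte-Carlo
  noise, not analytically).
* The scalar-r evaluator path inherits the ±.002 structural-robustness
  bound; for wildly heterogeneous correlation patterns (e.g. negative
  correlations mixed with strong positive blocks), supply the full matrix.
* A significant subset of outcomes under MEff does not identify *which*
  outcomes truly respond — with exchangeable indicators, which subset
  clears the threshold is substantially chance, and only replication can
  settle a specific pattern.
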