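# Methods

## Model family

Outcomes are binary (failure to graduate within four years of entering
grade nine).  Each of five exposures is observed as three binary period
flags covering ages 0–3, 4–8 and 9–13, giving eight possible trajectory
patterns per exposure.  All models are logistic regressions containing an
intercept, a configurable set of time-invariant covariates, and one block
of trajectory columns per exposure:

* **full** — seven pattern dummies `s100 … s111`, never-exposed `000` as
  reference;
* **accumulation of risk** — the exposed-period count `p1+p2+p3` with one
  coefficient, so two exposed periods carry exactly twice the log-odds of
  one;
* **sensitive period** — the three *marginal* period indicators, each with
  its own coefficient; a person exposed in two periods receives both
  contributions additively;
* **critical period (one per window)** — a single marginal period
  indicator.

Critical and sensitive blocks use marginal indicators (exposed in period
*i*, whatever the other periods) rather than exclusive ones.  This is a
deliberate design choice: with marginal coding every restricted encoding
is an exact linear function of the seven full-model dummies
(`count = s100+s010+s001+2(s110+s101+s011)+3·s111`;
`d1 = s100+s110+s101+s111`; etc.), so all five restricted models are
nested in the full model and likelihood-ratio tests carry
`7 − n_params` degrees of freedom.  Exclusive coding would break that
nesting.  The identities are asserted exactly over all eight patterns in
the test suite.

Covariate strategies: `all` (ten time-invariant covariates including the
grade-9 achievement flag), `birth_only` (drops grade-9), `none`, and
`sibling` (same covariates as `all`, family-clustered fit).  Birth weight
enters as two dummies (≤2500 g, >3500 g; 2500–3500 g reference);
continuous covariates enter untransformed so odds ratios read per unit.

## Selection procedure

For each exposure in turn, the full model of that exposure — with every
*other* exposure saturated and the strategy's covariates present — is the
reference.  Each restricted hypothesis replaces only the target exposure's
block, and is compared by likelihood-ratio test.  The rule:

1. a restricted model with LRT p > 0.05 qualifies;
2. among qualifying models the smallest AIC (of the whole candidate fit)
   wins;
3. otherwise the full model is kept.

By default selection is one-pass: each exposure is tested against
all-others-full, and the final model assembles the winners and is refitted
once.  An iterative variant (`iterative=True`) re-tests each exposure with
the others at their currently chosen patterns until a fixed point; it is
not the default because the one-pass procedure is the primitive the
assembled-model report is defined over, and in practice the two agree on
well-separated data.  Both the 0.05 threshold and the tie-break are
configurable.  AIC differences between candidates sharing the same
"others" blocks isolate the target exposure's parameterization; the
algebraic link `AIC_full − AIC_restricted = 2·df − LRT` is asserted on
fitted values in the tests.

## Estimation

Ordinary fits use statsmodels' logistic maximum likelihood (Newton;
iteratively reweighted least squares as fallback when Newton fails or does
not converge), relative tolerance 1e-8, at most 100 iterations, with the
convergence flag propagated rather than swallowed.  Quasi-separation is
detected as any |coefficient| > 15 on a binary column and raised as an
explicit error naming the column: with registry-realistic pattern
frequencies the always-injured pattern occurs in ~0.02% of records, and
cohorts much below ~50,000 can separate on it.  Wald 95% intervals use
z = 1.959964; profile intervals are not implemented.

The sibling model adds a family-level random intercept with standard
deviation σ, integrated out of the Bernoulli likelihood by Gauss–Hermite
quadrature (15 nodes by default, configurable).  The quadrature is plain
rather than adaptive: cluster sizes here are one or two siblings and σ is
below ~1.5, a regime where fixed-node quadrature at 15+ nodes matches
adaptive implementations to well under reporting precision — the test
suite checks coefficients, σ and log-likelihood against `lme4::glmer`
(`nAGQ = 15`) to ~1e-3.  Keeping the nodes fixed makes the exact analytic
gradient of the objective available, and (β, σ) is maximised by L-BFGS-B
with σ bounded at zero, where the model collapses to ordinary logistic
regression.  Design columns are standardised internally before
optimisation (raw covariates such as calendar year condition the problem
badly) and estimates, covariance and fitted values are mapped back to the
raw scale.  Standard errors come from the observed information, obtained
by central differences of the analytic gradient.  AIC counts σ as a
parameter, matching lme4.  With only singleton families σ and β trade off
along a near-flat ridge; the fit warns and only the marginal predictions
are identified.

## Evaluation

The concordance statistic is computed by an O(n log n) sort-and-sweep over
distinct predicted values, counting concordant and tied case/non-case
pairs (`c = (concordant + ties/2) / pairs`); it is cross-checked in tests
against exhaustive enumeration and the Mann–Whitney rank-sum formulation.
Cross-validation uses stratified folds built by shuffled round-robin
assignment within outcome class (k = 10 default), which degrades
gracefully to leave-one-out; when a test fold lacks both classes the
pooled out-of-fold concordance is reported instead of a per-fold mean.
Bootstrap standard errors resample individuals with replacement
(B = 200 default), dropping and counting failed replicates and erroring
when more than 10% fail.  All resampling is driven by a single seed.

## Synthetic cohort generator

The generator exists because the registry microdata are not deposited; it
reproduces the statistical *structure* the method assumes, not the true
joint distribution.

* **Trajectories** follow a first-order two-state Markov chain per
  exposure: a period-1 start probability, a persistence probability
  P(exposed at t+1 | exposed at t), and an incidence probability
  P(exposed at t+1 | unexposed at t).  Persistence ≫ incidence reproduces
  the heavy never-/always-exposed corners of registry data.  Chain
  parameters for the default scenario are moment-matched to published
  pooled 8-pattern counts; the closed-form pattern distribution is the
  oracle for the simulator in tests.  (The published mobility row sums 30
  short of the cohort N as printed; counts are used as fractions.)
* **Co-occurrence**: a standard-normal latent disadvantage factor, shared
  by siblings, shifts the chain probabilities of the three social
  exposures on the logit scale (loading 0.6 by default).  Published data
  give no cross-exposure correlations; the loading is a modelling choice,
  not an estimate.
* **Covariates**: truncated normals (mother's age 26.2 ± 5.3 on [14, 50];
  family size and birth order rounded to 1–5) and Bernoullis (rural
  0.4738, unmarried mother 0.2983, male 0.5048, birth-weight categories
  4.6% / 48.7% / 46.7%), birth year uniform on 1982–1995 — all pooled
  published marginals.  Siblings share maternal covariates (mother's age,
  family size, rural, unmarried).
* **Grade-9 achievement** is generated as a downstream mediator: a
  logistic draw whose linear predictor is the exposure-plus-birth-covariate
  signal (gain 1.0), intercept solved so 54.6% are below average.  It can
  be toggled exogenous.  This is what lets the achievement flag "soak up"
  earlier effects when included, and lets dropping it raise the exposure
  odds ratios, as the adjusted/unadjusted comparisons show.
* **Outcome**: logistic in the generative trajectory encodings (full-model
  patterns for the three social exposures, sensitive periods for
  externalizing conditions, accumulation for injuries) with published
  adjusted odds ratios as true effect magnitudes, plus covariate effects,
  plus an optional family intercept.  The intercept is solved by root
  bracketing on the realised linear predictors so prevalence hits 24.1%.
* **Families**: a configurable fraction of the cohort sits in sibling
  pairs.  The *default* family intercept SD is 0 — clustering structure
  without outcome correlation — so marginal refits recover the generative
  coefficients exactly; mixed-model analyses use explicit nonzero-SD
  scenario variants (0.75 in the sibling analysis script).

What passing tests therefore show: the pipeline recovers known generative
temporal patterns and effect magnitudes, its null LRT p-values are
uniform, and its diagnostics behave.  What they cannot show: anything
about the true registry joint distribution — real exposure histories are
not first-order Markov, covariates and exposures have richer dependence,
and the achieved c-statistics (~0.83 / 0.74 / 0.68 across covariate
strategies) are properties of the scenario, not estimates of the published
ones (0.859 / 0.790 / 0.734), though they reproduce the ordering and
rough spacing.

## Problem sizes and numerical defaults

Simulation-based checks run at sizes chosen to keep the whole suite to a
few minutes on one CPU while leaving Monte-Carlo error well inside the
asserted tolerances: 500 null replicates at n = 5,000 for LRT uniformity
(Kolmogorov–Smirnov at α = 0.01); 100 replicates at n = 50,000 for
accumulation recovery (≥ 80% required); effect recovery within 3 SE at
n = 200,000; selection and reporting runs at the published cohort size
89,763.  The bootstrap diagnostic resamples a 20,000-person subset so 200
refits stay quick.  Tolerances: fits are compared to closed forms and grid
oracles at 1e-4; LRT statistics are clamped at zero with a 1e-4 negative
slack for convergence noise, below which nesting violations raise.

## Known limitations

* Exposure flags are taken as given; deriving them from raw claims or
  postal-code histories, more than three periods, and continuous exposures
  are out of scope.
* No penalised or GEE estimation; separation is an error, not something
  the fitter works around.
* The multilevel model supports a single random intercept level only.
* The generator's "time-limited condition" convention is implicit in its
  Markov chain; it does not model diagnosis carry-forward rules.
* Loss to follow-up, missing data and record-linkage error are not
  simulated; the analysis is complete-case by construction.
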