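# Methods

## Generative model

Trials are simulated from the random-intercept linear model
`Y_ij = β0 + b_0j + β1 X_ij + e_ij` with `b_0j ~ N(0, σb²)` drawn fresh per
centre and replicate, and `e_ij ~ N(0, σe²)` per patient. The between-centre
variance is parameterized through the intraclass correlation,
`σb² = σe² · ICC/(1 − ICC)`, so ICC round-trips to machine precision.
ICC = 0 is simulated like any other value (σb² = 0), not special-cased.

Default parameters for the equal-size scenarios: β0 = 0 (it cancels in every
treatment contrast, so its value is immaterial), β1 = 0.5 outcome SDs
(a medium standardized effect), σe² = 1, and a 13-point ICC grid from 0 to
0.75. The per-arm size of 90 comes from the normal-approximation sample-size
formula: 84 per arm gives 90% power for δ = 0.5 at two-sided α = 0.05, padded
to 90 (power 91.8% by the same formula) to admit more centre compositions.
Scenario 9 uses β0 = 1.34, β1 = 1.26, σe² = 7, σb² = 1 (ICC = 0.125), the
variance scale of the motivating 511-patient trial.

## Allocation mechanisms

* **balanced** — each centre receives exactly n_j/2 labels per arm, randomly
  ordered. Requires even centre sizes.
* **complete** (chance imbalance) — one trial-wide uniform permutation of a
  fixed vector of ⌈N/2⌉ treatment and ⌊N/2⌋ control labels. This preserves
  the exact 1:1 trial-wide ratio while making within-centre arm counts
  hypergeometric; a per-patient Bernoulli(½) scheme would not fix the overall
  ratio.
* **permuted blocks** — within each centre, consecutive blocks of the design
  block size containing equal numbers of each arm in uniform random order; an
  incomplete final block is a uniform truncation of a fresh permuted block.
  This bounds within-centre imbalance by half the block size. Because each
  centre truncates independently, the *trial-wide* margin may differ by more
  than one patient — a property of the mechanism itself, not a defect.

## Scenario catalogue

Scenarios 1–3 are balanced designs with (J, n_j) = (45, 4), (18, 10), (6, 30);
4–6 use the same compositions with trial-wide chance-imbalance allocation;
7–8 use 17 centres of unequal size with permuted blocks of 2 and 4; scenario 9
reproduces a real 46-centre composition (N = 511, three singleton centres,
largest centre 25) with blocks of 6.

The operative 17-centre composition for scenarios 7–8 is the frozen constant
{1, 1, 4, 5, 5, 5, 8, 8, 10, 10, 10, 10, 15, 15, 20, 25, 28}: it sums to 180
and matches every published summary of that design (sizes 1–28, quartiles
5/10/15, mean 10.6, SD 7.8). Runs log this composition so reports are
self-describing.

## Estimators

All six are implemented against per-centre sufficient statistics of
(1, x, y) cross-products, so a fit costs O(N) and a 1000-replicate cell runs
in seconds.

* **A** — pooled two-sample t-test; df = N − 2.
* **B** — one fixed intercept per centre, absorbed by within-centre
  demeaning. Centres with all patients in one arm carry no information on β1
  and are dropped; df = N_ret − J_ret − 1. (Keeping them as dummies would
  change only the residual-variance estimate, not the point estimate.)
* **C** — REML random intercept. The restricted likelihood is profiled down
  to the variance ratio λ = σb²/σe²: given λ, the GLS coefficients and σ̂e²
  are closed-form via the Woodbury identity, leaving a smooth 1-D criterion.
  It is maximized by a bounded scalar search in log λ on [−30, 12] (xatol
  1e-10), with the boundary λ = 0 admitted explicitly by direct comparison;
  a 2000-point grid search verifies the optimum to 1e-6 in tests. t interval
  with df = N − J − 1, the containing-level convention, which reproduces
  nominal coverage at small J. Degenerate data with zero residual variance
  return a flagged boundary fit with se = 0 rather than an error.
* **D** — GEE with identity link and exchangeable working correlation.
  Moment updates use the small-sample denominators of the classical
  implementation, φ̂ = Σr²/(N − 2) and pair denominator Σ n_j(n_j−1)/2 − 2;
  iteration starts at independence (α = 0, OLS) and stops when the maximum
  coefficient change falls below `tol` (default 1e-8) or after `max_iter`
  (default 2000) sweeps. Non-convergence — cap reached, or α̂ outside the
  positive-definite range (−1/(max n_j − 1), 1) — is *flagged*, never raised;
  the evaluation harness owns the replacement policy. Variance is the
  information sandwich; interval is Wald with quantile 1.959964. If every
  centre is a singleton the fit reduces to independence GEE.
* **E-1 / E-2** — per-centre mean differences `md_j` with
  `se_md_j = sqrt(sd_t²/n_t + sd_c²/n_c)` from per-arm sample SDs (the
  meta-analytic convention); centres lacking two patients in either arm are
  dropped. E-1 pools with weights 1/se², E-2 re-weights by 1/(se² + τ̂²) with
  the DerSimonian–Laird moment estimate of τ² from Cochran's Q. When
  Q ≤ J_used − 1, τ̂² = 0 and E-2 collapses exactly onto E-1. A centre with
  zero within-arm variance (se_md = 0) is reported as an error naming the
  centre.

A `true_se_beta1` utility computes the best-linear-unbiased (GLS) standard
error of β1 for a fixed arm assignment under known variance components —
the analytic anchor (0.149 for the balanced 180-patient design at σe² = 1,
any ICC).

## Evaluation harness

Each (scenario, ICC) cell simulates replicates on the substream path
(scenario id, icc key, replicate index) from one root seed, where the icc key
is round(icc·1e6); identical seeds reproduce cells bit for bit, and
replacement replicates simply take the next replicate index. A replicate
whose GEE fit does not converge is excluded from *all* models' summaries and
replaced, until the requested number of analyzable replicates accumulates
(cap: 10× the target, then an error reporting the exclusion rate).

Metrics per model: bias (mean estimate − truth), empirical SD (n−1
denominator), average estimated SE, MSE (1/n denominator — so MSE ≥ bias²
holds only up to that convention), coverage of the closed 95% interval, and
power (zero strictly outside the interval). Ties at interval endpoints have
probability zero but the conventions make behaviour defined.

## Design calculations

`t_test_power` defaults to the two-sided normal-approximation formula — the
convention consistent with both published anchors (84 per arm for 90% power
at δ = 0.5; 91.8% at 90 per arm) — and exposes the exact noncentral-t power
(`method="exact"`, about 0.2 points lower here; the exact requirement for 90%
power is 86 per arm, available as `exact_sample_size`).
`variance_inflation(icc) = 1/(1 − icc)` quantifies the variance penalty of
ignoring clustering in the naive model.

## What the generator does and does not emulate

The simulator reproduces the study conditions: normal errors, a common
treatment effect across centres (no treatment-by-centre interaction), equal
ICC in every centre, non-informative cluster sizes, complete follow-up, and
1:1 allocation. Passing tests therefore certify the estimators' behaviour
under those assumptions only; they say nothing about skewed outcomes,
heterogeneous treatment effects, informative cluster size, or missing data.
The chance-imbalance mechanism for scenarios 4–6 is a reconstruction (the
design is stated only as "1:1 with chance imbalance"); the trial-wide
permutation used here reproduces the published average-SE profile of all six
models in those scenarios, though the published empirical-SD column there
sits a few percent below its own average SEs, so SD-derived quantities
(e.g. the fixed-vs-random efficiency gap) carry extra reproduction
uncertainty beyond Monte Carlo noise.

## Numerical choices and problem sizes

Wald intervals fix the quantile at 1.959964; t intervals use scipy's t
quantile at the model's df. The REML search tolerances and the GEE stopping
rule are stated above. Monte Carlo tests use 1000 replicates per cell — the
study's own replicate count, which bounds the binomial SE of coverage/power
at about 1.6% — while auxiliary unit tests use smaller counts (50–200) sized
to their assertions. Reference cross-checks (R `nlme::lme` for the mixed
model, statsmodels GEE for the marginal model) run on 20 frozen datasets
drawn away from the σb² = 0 boundary, where reference optimizers are
unreliable; agreement is 1e-6/1e-9 (nlme) and ~1e-14 (statsmodels GEE).

## Known limitations

Only two-arm trials with a single treatment column are supported; no
covariate adjustment, random slopes, ML (non-REML) variants, unequal
allocation ratios, or binary/survival outcomes. Model B's dropped-centre
convention means its residual variance ignores single-arm centres' internal
spread. The GEE implementation assumes an identity link and exchangeable
structure only — precisely the estimator under study, not a general GEE.
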