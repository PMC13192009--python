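# Methods

This note documents the models implemented in `frailtypaths`, the
design of the synthetic cohort generator, the numerical choices, and
the limits of what the validation suite demonstrates.

## 1. Harmonised frailty scoring

Three instruments share one scoring contract: five binary components
are summed to a 0–5 score and classified robust (0), pre-frail (1–2) or
frail (≥3); the binary exposure used downstream is frail vs
pre-frail/robust.

Thresholded criteria are resolved internally with explicit boundary
semantics, read literally from the inequality that defines each:

| criterion | rule | boundary |
|---|---|---|
| shrinking (BMI proxy) | BMI < 18.5 kg/m² | 18.5 exactly → not met |
| shrinking (BMI slope) | annualised loss > 1.48 kg/m²/yr | 1.48 exactly → not met |
| weakness (grip) | ≤ 27.1 kg men, ≤ 16.6 kg women | cutoff exactly → met |
| illness (FRAIL) | ≥ 5 of 11 chronic conditions | 5 exactly → met |

Missing components: the two Fried variants require all five components
(conservative complete-case — the instruments' published usage does not
define partial scores); the FRAIL scale scores subjects with ≥3 valid
components, summing the observed ones. Grip cutoffs are fixed
constants; re-estimating them as within-sample 20th percentiles is left
to the caller (the instrument definition fixes them, and re-estimation
would make scores sample-dependent).

**EAA residualisation.** Each DNAm-age column is regressed on
chronological age by OLS; the residual is the age-acceleration measure.
Residuals are mean-zero and exactly age-orthogonal (normal equations),
and residualising residuals is a no-op — both are tested. Pace-of-aging
measures are rates, not ages, and are consumed untransformed.

**SES index.** Indicators are standardised and the first principal
component of their correlation matrix (not covariance — the indicators
are mixed ordinal/continuous, so scale should not drive loadings) is
re-standardised to a z-score. The sign is fixed by requiring a positive
loading on the education indicator, so higher z always means higher
socioeconomic position. Ordinal indicators default to 1..k integer
coding; any monotone coding can be supplied instead.

## 2. Weighted survival engine

The Cox engine maximises the case-weighted partial likelihood by
Newton–Raphson with step halving; convergence requires the gradient
norm below `tol × max(1, events)` (default `tol = 1e-9`; the event
scaling makes the criterion sample-size invariant), at most 100
iterations. Efron tie handling is the default, Breslow is available
for oracle comparisons. Coefficients diverging past |β| = 15 (hazard
ratios beyond 10⁶) are reported as monotone-likelihood/perfect
separation rather than returned.

Risk-set sums are suffix sums of time-sorted arrays; delayed entry
subtracts a second suffix sum over entry-sorted arrays, giving exact
left-truncated risk sets at O(n log n) per evaluation. The Hessian is
assembled from diagonal-weighted Gram matrices (no n×p×p intermediate),
which keeps one fit at n = 8,000, p = 9 around 20 ms — the property the
bootstrap below relies on.

- *Attained-age scale*: entry = baseline age, exit = age + follow-up.
- *Survey design*: weighted estimation plus a PSU-clustered sandwich
  variance from per-subject score residuals (Breslow form). Full
  Taylor-linearised survey variance with stratum finite-population
  corrections is a documented non-goal; for the designs generated here
  the cluster sandwich is the dominant correction.
- *Baseline hazard*: Breslow step estimator (also under Efron ties — a
  standard simplification affecting only the baseline, not β).
- *PH diagnostics*: Grambsch–Therneau test on weighted Schoenfeld
  residuals against a transform of event time. The default transform is
  one minus the Kaplan–Meier survival ("km"); identity and rank are
  exposed, since the appropriate transform is an analyst choice. The
  global and per-covariate statistics use the inverse information
  scaling; type-I error calibration is verified by simulation
  (0.05 ± 0.02 at 500 replicates).
- *Weibull PH*: fitted directly in the proportional-hazards
  parameterisation h(t) = p·λ·t^(p−1)·exp(x′β) (so β are log-HRs,
  comparable with Cox), by BFGS with analytic gradient plus a Newton
  polish on a numerically differentiated Hessian; optional
  cluster-robust sandwich from analytic per-subject scores.

Weighted Kaplan–Meier uses weighted event counts and risk sets with the
Greenwood variance on the same weighted counts. The survival curve is
invariant to rescaling all weights; the Greenwood SE is kept on the raw
weight scale so that integer weights reproduce the replicated-dataset
SE exactly.

## 3. Discrete-time additive Bayesian network

Survival data are expanded to person-period rows over half-open
intervals [0,w), [w,2w), … (default w = 2 years). A censored subject
contributes ceil(t/w) rows (censoring exactly on a boundary does not
enter the next interval); an event subject's final row is the interval
containing the event time, with the period event indicator 1 only
there. Row and event totals are conserved — both tested.

Continuous predictors are percentile-binned (default 5 bins; 3 gives
the tertile stratification used for descriptive plots) and each value
is replaced by its bin median, then modelled as Gaussian; binary nodes
are binomial. The node score is the penalised log-likelihood
`logL − (k/2)·log n` (BIC form, higher is better; k counts intercept,
slopes, and the Gaussian residual variance). BIC was chosen because it
is deterministic and prior-free; a marginal-likelihood score would need
prior hyperparameters and would not change the exact-search machinery.

Structure search is exact: all admissible parent sets up to the parent
limit are scored per node, and the optimal acyclic assignment is found
by dynamic programming over node subsets (best-parent-set tables, then
order DP), up to 14 nodes. Role constraints are enforced during
enumeration: exogenous nodes (age, sex) admit no parents, the mortality
indicator is a sink, and arcs can be banned or required. Ties break to
the lexicographically smallest parent set, so results are deterministic
and row-order invariant.

`compare_parent_limits` fits limits 1–3 and selects the smallest limit
whose improvement over the previous one falls below 1% of |score|
(configurable); all scores are reported so the caller can override —
the plateau rule and a fixed three-parent limit are both defensible,
and the package takes no side.

Person-period rows repeat subjects, violating row independence; scores
are computed on rows as-is, as discrete-time hazard models do. Network
scores are therefore model-selection devices, not calibrated test
statistics. Sampling weights are deliberately not used in network
scoring; the path models are where design adjustment happens.

## 4. Path models

A recursive system without latent variables factorises over nodes, so
each endogenous node equation is fitted separately — this is exact, not
an approximation. Families: Gaussian → linear, binomial → logistic
(the logistic link keeps the equation coherent with the network's
binomial family), mortality sink → Weibull PH on the subject-level
survival data. Two variants mirror a simple-random-sample analysis
(unweighted, model variance) and a survey analysis (weighted,
PSU-clustered variance). Arc p-values are Benjamini–Hochberg adjusted
across the path table. Path models consume raw (undiscretised) node
values by default; a discretised mode is available via the same
binning helper.

## 5. Four-way decomposition

Implemented exactly as the closed-form Q-kernel construction in the
README. Practical choices:

- **m\*** defaults to the (weighted) sample mean of the mediator;
  user-overridable.
- **Covariate conditioning** defaults to (weighted) sample means;
  `conditioning="average"` instead averages Q over the empirical
  covariate distribution. Both are exposed because the estimand
  differs; on the default generator they agree within a few percent.
- **Rare-outcome approximation**: hazard ratios are read as risk
  ratios. `run_decomposition` warns when events are plentiful relative
  to parameters; the generator's default event fraction (≈8% over 10
  years) keeps the approximation honest, and the validation suite
  checks the estimator against the generator's hazard-scale truth,
  which shares the same kernel.
- **Inference**: nonparametric bootstrap over subjects — over whole
  PSUs when a design is present — with percentile 95% intervals and
  normal-approximation p-values (null 0 for excess-RR quantities, 1 for
  terira). Resamples whose models fail (e.g. zero events) are dropped
  and counted; more than 10% dropped aborts the run. A delta-method
  variance was considered and not implemented: the bootstrap covers the
  proportion summaries (ratios of components) without further
  approximation.
- **Reverse direction**: binary frailty as mediator of an EAA→mortality
  effect uses the Bernoulli Q-kernel with a logistic mediator model;
  exposure levels (a, a\*) are configurable for continuous exposures.
- **Leukocyte covariates**: cell-fraction columns can be appended to
  the covariate set in both directions (immune-inclusive vs
  immune-independent signal).

## 6. Synthetic cohort generator

The generator emulates a community cohort of older US adults and is the
package's study condition, not a tuning knob:

| block | default | rationale |
|---|---|---|
| n, ages | 2,000; uniform 50–85 | typical analytic sample; older-adult range |
| sex, race | 55% female; 55/20/17/8% NHW/NHB/Hispanic/Other | plausible community mix |
| SES | latent normal, loadings on age and race, standardised | one z-scored factor, as the analysis consumes |
| frailty | 5 Bernoulli components, logits with age (+0.35/decade), female (+0.15), SES (−0.45); intercepts set for ≈12% frail | frailty rises with age and social disadvantage |
| EAA panel | means 0 (pace 1.0); SDs ≈ 4–5 y (pace 0.10); correlations 0.15–0.50 | residual-scale clocks; mortality-trained clocks correlate more strongly |
| shifts | frail +2 y on GrimAge EAA (smaller elsewhere); female negative; SES negative | encodes the qualitative sign pattern the path models must recover |
| survival | Weibull PH, shape 1.3, scale 0.0025; θ = (0.50, 0.06, 0.01); covariate log-HRs incl. 0.085/yr age | rising hazard with age; event fraction ≈8% ≤ 10% so the rare-outcome reading holds |
| censoring | administrative at 10 y plus exponential dropout (0.01/yr) | both mechanisms exposed because real cohorts mix them |

Weibull times are drawn by inverse transform, so the event fraction is
analytically checkable (the test integrates the generative survival
function numerically and compares). The mediating clock's conditional
law given exposure and covariates is exactly the linear mediator model,
so `GeneratorConfig.implied_truth()` yields the true decomposition in
closed form; `mc_counterfactual_components` recomputes it by
potential-outcome simulation with common random numbers and batch-based
MC standard errors (50 batches).

Survey designs are attached separately: logistic inclusion
probabilities on demographics give inverse-probability weights, and
subjects are randomised to stratum/PSU labels. MCAR missingness can be
injected into frailty components to exercise the ≥3-valid rule.

**What the generator does not emulate**: real marginal distributions of
any cohort beyond orders of magnitude; measurement error in clocks or
frailty items; informative censoring; time-varying exposure or
mediator; geographic clustering that correlates with outcomes. Passing
tests therefore demonstrate the *estimators* are correct under the
assumed structure, not that the assumptions hold in any real cohort.

## 7. Numerical choices and degenerate inputs

- Cox: tolerances and separation bounds as in §2; singular information
  is reported, not regularised.
- Weibull: exponential-rate starting value; convergence requires the
  gradient below 1e-4 relative to |logL| after polish.
- PCA/OLS: computed by eigh/lstsq; constant indicators and constant age
  vectors are rejected with the offending column named.
- Percentile binning requires ≥2 bins and enough distinct values;
  constant vectors are rejected.
- Decomposition with tereri = 0 returns proportions as missing with a
  warning rather than dividing by zero.
- All generators and the bootstrap take explicit integer seeds;
  identical seeds give byte-identical pipeline artifacts (hashes in the
  run manifest).

## 8. Problem sizes in the validation suite

The suite's simulation studies use 25 recovery replicates (n = 8,000,
200 bootstrap draws), 50 null replicates (n = 4,000), 500 PH-test
replicates (n = 600), 100 chain-recovery seeds (n = 2,000) and 10⁶-draw
Monte-Carlo oracles — sizes chosen so each study's own Monte-Carlo error
is small relative to the tolerance it checks while the whole suite
completes in a few minutes.
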