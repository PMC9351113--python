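# Methods

This note documents the statistical machinery in `mipool`: the data
generator, the amputation and imputation mechanisms, the five pooled
tests, the selection loop, the evaluation metrics, and the numerical and
design choices made where the design was genuinely open.

## Simulated data

Nine predictors are generated from a latent multivariate normal with an
exchangeable correlation ρ (default conditions ρ = 0.2 and 0.6 across all
nine latent variables — the simplest structure consistent with a single
correlation parameter) and the following marginals and outcome
coefficients:

| name  | type            | latent mean | latent SD | coefficient(s)   |
|-------|-----------------|-------------|-----------|------------------|
| Cat1  | 4-level categorical | 2       | 0.95      | 0.5 / 1.5 / 1.5 (dummies vs level 0) |
| Cat2  | 4-level categorical | 3       | 1.0       | 1.5 / 1.5 / 1.5  |
| Dich1 | dichotomous     | 0.8         | 0.45      | −0.5             |
| Dich2 | dichotomous     | 0.7         | 0.55      | −1.0             |
| Cont1 | continuous      | 7           | 1.41      | 0.5              |
| Noise | continuous      | 7           | 1.41      | 0 (pure noise)   |
| Cont2 | continuous      | 140         | 9.5       | −0.1             |
| Cont3 | continuous      | 26          | 3.9       | −0.1             |
| Cont4 | continuous      | 34          | 4.8       | −0.1             |

Cat1 is cut at cumulative probabilities (0.6, 0.8, 0.9), Cat2 at
(0.3, 0.6, 0.8); the cuts are the **theoretical** normal quantiles of each
latent variable, not sample quantiles, so the cut points are identical in
every replication. Dichotomous variables are split at the theoretical
median (the latent mean).

The outcome is Bernoulli with `p = expit(α + Σ βx)` (dummy-coded
categoricals). No intercept accompanies the coefficient table, and the raw
coefficient-times-mean products are far from zero, so α is calibrated by
monotone root finding (Brent, tolerance 1e−10) to a configurable target
prevalence, default 0.5 — this honours every stated coefficient while
producing usable event rates. The default outcome rule is the standard
`y = 1{u ≤ p}`; the inverted comparison (`y = 1` when `p < u`), which
flips all effect signs, is available behind the `paper_literal_outcome`
flag for auditing.

## MAR amputation

Four variables (Cat1, Cat2, Noise, Cont4) are made incomplete. Each has a
distinct, always-observed driver (Cont1, Cont2, Cont3 and Dich2
respectively — distinct drivers keep the mechanism unambiguously MAR).
Row i of target j is masked with probability
`expit(γ0_j + γ1 · z_ij)` where z is the standardised driver, γ1 = 0.4,
and γ0_j is solved per target so the marginal missing rate equals the
requested rate (default 20%). With four targets at 20% this leaves roughly
55–60% of rows incomplete. Setting γ1 = 0 degrades the mechanism to MCAR;
the tests verify both the γ recovery and the conditional-independence
property (given the driver, a variable's own value carries no signal about
its missingness).

## Imputation

Chained equations, m = 5 by default, 10 sweeps (a standard burn-in; the
sweeps parameter is exposed). Every conditional model regresses the target
on all other predictors (categoricals dummy-coded) plus, by default, the
outcome; a flag reproduces the outcome-excluded sensitivity analysis.
Conditional families by target type:

* continuous — Bayesian linear regression (σ² from the scaled inverse
  chi-square, β* from its normal posterior) with type-1 predictive mean
  matching, k = 5 donors, so imputations are always observed values;
* dichotomous — logistic fit, parameter draw from N(β̂, Cov), Bernoulli;
* 4-level categorical — baseline-category multinomial logit (own Newton
  solver), parameter draw from N(vec B̂, Cov), categorical draw.

Missing cells are initialised by resampling observed values; the m chains
are independent streams spawned from the replication generator. A
conditional fit that fails unpenalised is retried with a mild ridge
(multinomial λ = 0.05, logistic λ = 1e−3, intercept unpenalised); if that
also fails the replication is re-drawn by the study driver.

## Pooled tests

With per-imputation estimates Q̂ₗ and covariances Ûₗ (k-dimensional block),
Q̄, Ū, B as usual and T = Ū + (1+1/m)B:

* **RR** (k = 1): t = Q̄/√T against Student t with the Barnard–Rubin
  degrees of freedom, `ν = (1/ν_old + 1/ν_obs)⁻¹`,
  `ν_old = (m−1)/λ²`, `ν_obs = ((ν_com+1)/(ν_com+3)) ν_com (1−λ)`,
  `ν_com = n − p_model`, λ = (1+1/m)B/T.
* **D1**: `r1 = (1+1/m) tr(B Ū⁻¹)/k`, `D1 = Q̄′Ū⁻¹Q̄ / [k(1+r1)]` against
  F(k, df2); with t = k(m−1), `df2 = 4 + (t−4)[1 + (1−2/t)/r1]²` for
  t > 4, else `t(1+1/k)(1+1/r1)²/2`.
* **D2**: `r2 = (1+1/m) var(√dₗ)`,
  `D2 = (d̄/k − (m+1)/(m−1) r2)/(1+r2)` against F(k, df2) with
  `df2 = k^(−3/m)(m−1)(1+1/r2)²`; a negative statistic is truncated to 0
  (p = 1).
* **D3**: per-imputation LR statistics d̄; both parameter vectors averaged
  across imputations and the likelihoods re-evaluated at those pooled
  parameters give d̃; `r3 = (m+1)/(k(m−1)) (d̄ − d̃)` floored at 0,
  `D3 = d̃/[k(1+r3)]` with the D1 df2 form.
* **MPR**: the median of the m per-imputation p-values (mean of the two
  middle order statistics for even m).

Degenerate limits are exact: when the between-imputation variance vanishes
(r = 0) every F reference collapses to χ²_k/k, so on m identical datasets
each method reproduces the single-dataset Wald/LR test — the null
calibration of the whole pipeline rests on this.

Per-imputation inputs to D2 and MPR are likelihood-ratio chi-squares /
p-values for multi-df (categorical) blocks and Wald statistics for 1-df
terms.

## Selection

Backward elimination removes the variable with the **largest** pooled p
while that maximum strictly exceeds p-out (so p-out = 1.0 keeps the full
model); categorical blocks move as a unit; ties break toward the variable
later in the canonical order. Two pooling routes exist: `mixed` (RR for
1-df terms, the named method for categorical blocks — the route used for
the main study, matching how the methods are deployed in practice) and
`uniform` (the named method for everything). The complete-data reference
runs the same loop on the pre-amputation data with exact per-step
refitting and likelihood-ratio drop tests — deliberately exact rather than
the fast-backward Wald approximation some software uses.

Because the greedy path at a stricter threshold is a continuation of the
path at a looser one, a descending p-out grid is resolved in a single
elimination pass with snapshots at each threshold crossing; a test
verifies the pass equals from-scratch runs at every grid value.

Model fits are a hand-written Newton–Raphson logistic solver with step
halving, warm starts and a ridge fallback for separation; it is validated
against statsmodels to machine precision in the tests. This is what makes
a 4-condition × several-hundred-replication study (thousands of small
fits per replication, D3 doubling the fit count) run in minutes on one
CPU.

## Evaluation metrics

* **Selection frequency**: percent of replications whose final model
  contains a variable.
* **Median log p**: median over selecting replications of the log of the
  variable's final pooled p. Base 10 by default — the published medians
  are only consistent with base-10 logs (a natural-log reading would
  violate the selection bound at p-out 0.05) — with a switch for natural
  logs.
* **Agreement**: percent of replications where a method's final set
  exactly equals the complete-data final set (paired within replication),
  aggregated over conditions.
* **Stability**: the ten most frequent unique complete-data models are
  identified; the table reports how many method replications land in that
  set, under **two** denominators — total replications (the worked-example
  convention, 375/500 = 75%) and complete-data replications inside the
  top ten (the tabulated convention, 425/483 = 88.0%) — because the two
  published conventions disagree and both are reproduced.

## Study driver

Per-replication seed = condition seed + replication index, so any single
replication can be re-run in isolation; a replication with an
unrecoverable fit failure is re-drawn with a fresh offset seed and
counted in the manifest (keeping method comparisons paired within
replications). Results are independent of the worker count. Output CSVs:
records, selection frequency, median log p, agreement, stability, plus a
YAML manifest echoing the configuration and seeds.

The shipped acceptance run uses 200 replications per condition (down from
500 in the full study) with the p-out grid {0.5, 0.3, 0.1, 0.05}; at 200
replications a percentage near 10% carries a Monte-Carlo standard error
of about 2 points, which the acceptance tolerances account for. The
p-out = 1.0 column is omitted from comparisons: under "remove while
p > p-out" it trivially returns the full model for every method.

## What the generator does and does not emulate

The generator reproduces the study conditions (marginals, correlation,
categorisation, calibrated prevalence, MAR rates), not any real cohort:
all latent marginals are normal, effects are linear on the logit scale,
missingness is logistic-in-one-driver. Passing tests therefore demonstrate
correctness of the pooling/selection machinery under these conditions, not
performance on real data with non-linearities or MNAR mechanisms. The
exact amputation formulas behind the original missingness pattern are
under-determined; the logistic driver mechanism here is a documented
design choice, and regenerated frequency tables are expected to match
published ones in pattern (noise containment, MPR's advantage for
categorical variables, near-100% selection of strong predictors at
n = 500) rather than cell by cell.

## Known limitations

* No joint-model (multivariate normal) imputation, passive imputation or
  interaction terms; no MNAR; no non-normal latent marginals.
* No forward/stepwise-both selection, AIC/BIC criteria or shrinkage
  (LASSO-style) alternatives.
* D2 assumes the same k in every imputation; D3 is likelihood-based only
  (no Wald variant).
* The complete-data reference is exact stepwise LRT, which can legitimately
  differ from fast-backward approximations near a threshold.
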