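# Methods

## Model and screening procedure

The analysis unit is a jurisdiction-year. Within each state stratum and
year, and separately for each outcome Y (all lower-is-better rates), two
nested linear models are fit by ordinary least squares on identical units:

- step 1 (context only): Y = α + β₁Z + e
- step 2 (full): Y = α + β₁Z + β₂X + e

Z collects contextual covariates the jurisdiction's health department
cannot readily change; X collects mechanism covariates under some
departmental control. Categorical context (community type: metropolitan /
micropolitan / rural) enters as indicator columns against the metropolitan
reference, the modal category. Fitting is within-state by design: it
absorbs state-level differences in how expenditures and outcomes are
measured and keeps the residual scale comparable across a state's peers.

The two fits are compared by a likelihood-ratio test, 2(ℓ_full − ℓ_reduced)
against χ² with the effective-rank difference as degrees of freedom, using
the maximum-likelihood error variance RSS/n in both models (the χ²
reference requires ML, not REML, variances). The LRT is reported but does
not gate anything: screening always uses the step-2 (full-model) residuals,
for consistency across cells, with the context-only source available as a
configuration option and exercised by the parsimonious sensitivity variant.

A jurisdiction is flagged in a cell when its externally studentized
residual

  t_i = e_i / (s₍ᵢ₎ √(1 − h_ii)),  s₍ᵢ₎² = (RSS − e_i²/(1−h_ii)) / (n−p−1)

is strictly below the threshold (default −1). "Studentized" is interpreted
as *externally* studentized: internal studentization bounds residuals at
√(n−p) and lets a gross outlier inflate the pooled variance that scales its
own residual, weakening exactly the detection this screen exists for. Under
a correct Gaussian model t_i follows Student-t with n−p−1 degrees of
freedom, which gives the threshold its calibration (P(t < −1) ≈ 0.16 at the
panel's cell sizes). The strict inequality at the threshold and the −1
default follow the screening convention this pipeline implements; −2 is too
restrictive in practice and is exercised only as the monotonicity check
(flags at −2 nest within flags at −1).

### Influence and sensitivity

"Influential leverage points" are units with both high leverage
(h_ii > 2p/n) and high influence (Cook's D > 4/n); the joint rule reflects
that the phrase names both properties, and both cutoffs — the standard
rules of thumb — are exposed as parameters. Each cell is refit without its
influential points; a jurisdiction's flag is *robust* when the two runs
agree (a unit that was itself removed has no recomputed flag and is counted
robust vacuously). Covariate sensitivity reruns the whole screen dropping
one member of every highly correlated covariate pair (|r| > 0.8 within some
state; the member with the larger mean absolute correlation to the other
covariates is dropped, ties alphabetical) and with the parsimonious
context-only residual source, reporting Jaccard similarity of each
variant's flagged set against the primary run.

### Consolidation

Flags are assembled into a jurisdiction × (outcome, year) matrix (cells
that could not be fit are recorded as absent, not false). The final
positive-deviant set keeps jurisdictions flagged in at least `min_cells`
(default 2) cells, counting across outcomes and years: two outcomes in one
year qualify, as does one outcome in both years.

## Numerical choices

- OLS is computed by singular-value decomposition. Rank-deficient designs —
  which sensitivity variants can produce deliberately — get the
  minimum-norm solution, with the effective rank used as p everywhere
  (leverage sum, residual df, LRT df). Results are oracle-checked against
  pseudo-inverse formulas to 1e−8.
- An RSS that is zero up to rounding (relative to the outcome's total sum
  of squares) is treated as a perfect fit: the log-likelihood takes an
  infinite sentinel, and an LRT involving it reports p = 0 with a
  degeneracy flag (p = 1 if both fits are perfect). Residuals that are zero
  up to rounding studentize to exactly 0; units with h_ii = 1 get NaN
  scores, are never flagged by the threshold, and surface in the influence
  report instead.
- A cell is fittable when its complete records exceed the encoded design
  size plus one, leaving at least one degree of freedom for external
  studentization. Missing data are handled by listwise deletion per cell's
  model columns — a record missing only outcome A still participates in
  outcome B's cell — with whole-panel exclusion of any incomplete
  jurisdiction available as the stricter switch.
- All iteration orders are lexicographic and identification contains no
  randomness; repeated runs with the same configuration write byte-identical
  data outputs.
- The LRT uses the χ² reference. In finite samples this is anticonservative
  by a computable amount: rejecting when n·ln(RSS_r/RSS_f) exceeds the χ²
  critical value is equivalent to an F-threshold, giving an exact null
  rejection rate of sf_F(q, n−p_f)((e^{χ²_q(0.95)/n}−1)(n−p_f)/q) — about
  0.061–0.069 at n = 60 with q = 3 and small designs, approaching the
  nominal 0.05 only as n grows or with a Bartlett-style correction, which
  is deliberately not applied (the plain LRT is the procedure being
  modelled). An F-test variant is not implemented.

## Synthetic panels

The generator emulates the data structure the screen assumes, with known
ground truth. Defaults define the study conditions: 3 states of 35, 67 and
48 single-county jurisdictions (150 total, 300 jurisdiction-years over
2009–2010); 9 continuous context variables (log-normal expenditures,
population, Medicaid births, provider supply; scaled-Beta percentages;
a standard-normal disadvantage index) tied by a Gaussian copula with 0.3
baseline correlation and one deliberately collinear pair at 0.85
(disadvantage index × child poverty — light-tailed marginals, so the
raw-scale sample correlation tracks the copula parameter; the
expenditure–population pair sits at 0.5, its raw correlation attenuated by
the heavy tails); a 3-level community type at the 52/23/25
metro/micro/rural mix; two Bernoulli mechanism indicators and one latent
service-delivery score; and four outcomes whose noise σ is set from the
closed-form signal variance so full-model R² spans roughly 0.2–0.65 —
values in the plausible working range for county-level outcome regressions,
since the restricted source data publish no effect sizes to match.

Context and mechanism variables are drawn once per jurisdiction and held
fixed across the two years (they are slowly varying attributes); outcome
noise is independent across years and outcomes. Planted positive deviance
is an additive mean shift of −2.5σ on the outcome — the simplest mechanism
consistent with "better than the model predicts" — applied to ~10 % of
jurisdictions in 2–3 (outcome, year) cells each and ~5 % in exactly one
cell, allocated to states proportional to size. Seeding uses one master
seed with per-state, per-block substreams keyed by state name, so adding a
state leaves existing draws untouched.

What the generator does *not* emulate: the real joint distribution of the
administrative source data, spatial autocorrelation between neighbouring
counties, time trends, serial correlation of outcomes across years, or
measurement error in the covariates. Passing recovery tests therefore shows
the pipeline is correct under its own model assumptions, not that the
screen has any particular sensitivity on real panels.

## Validation studies and their scale

The acceptance layer recomputes, on one CPU in about a minute: closed-form
studentized residuals against physical leave-one-out refits and OLS against
pseudo-inverse formulas (100 problems, n = 50, p = 6, agreement to 1e−8);
LRT null calibration (2,000 panels, n = 60, 3 added columns on a
2-covariate base); the pooled t-tail of null residuals (500 study-shaped
replicates); planted-deviant recovery through consolidation (200
replicates); and coefficient bias and 95 % interval coverage (500 single-
state replicates). Replicate counts are chosen so Monte-Carlo standard
errors are a few parts per thousand, small against every margin tested.

## Known limitations

- At threshold −1 with four outcomes × two years, a *null* jurisdiction
  accrues ≥ 2 chance flags with probability ≈ 0.35–0.40 (eight nearly
  independent ~0.16 events), so the consolidated set mixes genuine deviants
  with a sizeable chance-level contingent; the measured exclusion
  probability for single-cell planted deviants is ~0.45, not higher, for
  the same reason. This is a property of the screening rule itself — no
  multiple-testing correction is applied, by design — and is why the output
  is a candidate list for qualitative follow-up rather than a verdict.
- The χ² LRT is anticonservative at these cell sizes (see above).
- Rates are consumed as already-computed, unitless rates; the package does
  not derive them from numerator/denominator counts, impute missing data,
  or model negative deviance ("worse than expected").
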