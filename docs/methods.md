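# Methods

This note documents the statistical machinery in `seatrend`: the models,
the defaults and why they are set where they are, the numerical choices,
and what the synthetic-data generator does and does not emulate.

## Populations, aggregation and inclusion

The unit of analysis is a *population*: one taxon at one monitoring
station. Raw records are averaged to annual means; years without records
are absent, never zero-filled, and all regressions use observed years only.
A recorded zero abundance is a true observation and counts as an observed
year — absence of a row is non-observation. This convention matters for the
inclusion rule and is deliberately asymmetric: imputing zeros for unvisited
years would manufacture declines.

Inclusion requires `n_obs ≥ 5` observed years and presence in at least 50%
of the monitoring period. The "monitoring period" is the population's own
first-to-last observed year (endpoints inclusive). We chose the
population's own span rather than the station's because it is
self-contained — it needs no assumption about when a station "really"
operated — and conservative: a species genuinely present for a station's
full history is unaffected, while a species recorded only in a short recent
window is not penalised for the station's earlier history. The station-span
alternative is available via `inclusion_filter(..., station_span=...)`.

Years are centered on the population's first observed year before fitting.
Coefficients are reported on this centered scale; trend classification
depends only on coefficient signs and significance, which are invariant to
the centering.

## Candidate models and screening

Up to six candidates per population: degrees {1, 2} × families
{Gaussian on ln(x+1), Poisson, negative binomial}, the count families on
abundances rounded to the nearest integer, with a log link. The negative
binomial is not a free competitor: it enters the candidate set for a given
degree only when the same-degree Poisson fit shows overdispersion (Pearson
X² against χ²_df at α = 0.05) or fails outright. Treating it as the
overdispersion fallback keeps the implicit number of hypothesis tests per
population down; fitting it unconditionally adds two extra ungated 5%-level
tests and measurably inflates the family-wise false-positive rate on null
data. Its dispersion is estimated by maximum likelihood, with a
method-of-moments fallback (α̂ = Σ[(y−μ̂)²−μ̂]/Σμ̂², then a fixed-α GLM, +1
AIC parameter) when the ML optimizer fails.

Gaussian and Poisson fits are screened at α = 0.05: Shapiro–Wilk on
residuals (raw for Gaussian, Pearson for Poisson), Breusch–Pagan against
the fit's own design. Exactly-constant residuals make the normality test
inapplicable and are treated as a pass. A fit is *valid* iff all applicable
screens pass; negative binomial fits carry no residual screens.

**Significance** of a candidate is the Wald test of its highest-order year
term: β₁ for linear fits, β₂ for quadratics. This is one of two defensible
readings (the other being an omnibus model test); testing the polynomial
term means a quadratic candidate is only "significant" for what
distinguishes it from a line.

**Selection** takes the lowest AIC among valid, significant candidates.
AICs of count families are directly comparable (same response); the
Gaussian fit's AIC is computed on the transformed response, so we add the
change-of-variables (Jacobian) term 2·Σ ln(xᵢ+1) to place its log-density
on the original response scale before comparison. Without this correction
"most parsimonious across families" is not a well-defined comparison; the
naive comparison can be restored by using `CandidateFit.aic` instead of
`comparable_aic`. Exact AIC ties (|ΔAIC| < 1e-9) break to the lower degree,
then to family order gaussian_ln < poisson < negbin.

A degenerate special case: an exactly constant response is reported as
trendless (slope 0, p = 1) rather than letting floating-point-noise
coefficients with floating-point-noise standard errors through the Wald
test.

## The nine trend types

- No valid significant candidate → **neutral** (populations where *no*
  candidate even passed the screens are additionally flagged
  `any_valid_model = False` and drop out of the duration-analysis
  denominators).
- Best model linear → **positive/negative linear** by sign(β₁).
- Best model quadratic with sign(β₁) ≠ sign(β₂), vertex −β₁/(2β₂) inside
  the observed range, and the Mitchell-Olds & Shaw condition satisfied →
  **unimodal** (positive-to-negative for β₂ < 0, the reverse for β₂ > 0).
  Our MOS implementation tests the fitted derivative β₁ + 2β₂t at both
  range endpoints (delta-method Wald tests, α = 0.05) and requires both to
  be significant with opposite signs — the curve must demonstrably rise on
  one side of the mode and fall on the other.
- Best model quadratic otherwise → **accelerating/decelerating,
  positive/negative**: direction is the sign of the fitted net change
  f(last) − f(first); accelerating iff |f′(last)| > |f′(first)|. The
  archetype pictures pin down the four quadrants; this net-change/derivative
  reading is our formalisation.

## Weighted vote count and duration analyses

Vote-count weight is `n_obs` (years with observations), not span — a gappy
series should not outvote a dense one of equal length. Shares per scope sum
to 100 by construction.

The two duration analyses are binomial mixed logits with station and
species as crossed random intercepts: (a) indicator(non-neutral) on
monitoring duration, over populations with at least one valid model; (b)
indicator(any valid model) on duration, over all populations. "Duration"
defaults to span (first-to-last year); `duration="n_obs"` is available
since either reading of "monitoring duration" is defensible.

## Multilevel meta-analysis

Effects are the Gaussian *linear* slope and its squared SE, taken from
every population whose Gaussian linear fit was valid — regardless of
whether a polynomial or count-family model won the AIC selection. This
keeps all effects on one common scale (per-year log change) at the cost of
using a deliberately simplified trend summary for curved populations.

The model is y = Xβ + Zu + ε with u the station random intercepts,
Var(εᵢ) = vᵢ known. σ² is estimated by REML, profiled in one dimension:
the station blocks make V = diag(v) + σ²J block-diagonal, so the restricted
likelihood is accumulated per station with the Sherman–Morrison inverse and
the matrix-determinant lemma — O(k) per evaluation, no dense solves. The
optimizer is bounded scalar minimization (xatol 1e-10) on [0, 10·max(var y,
max v)], with an explicit comparison against σ² = 0 so the boundary answer
is exact whenever the observed dispersion is within the sampling variances.
Inference is Wald-z (normal) throughout, matching the z-value/CI
presentation conventional for this model; no small-sample (Knapp–Hartung)
adjustment and no multiplicity correction across taxa is applied.

Rank-moderated runs use indicator (no-intercept) coding so each coefficient
is its level's pooled mean. Class-level runs use the full effect table;
order/family/genus runs are performed within component subsets (plants;
phytoplankton; fish; birds; macrozoobenthos + zooplankton) so that small
groups are estimated against comparable neighbours. Only station enters as
a random effect; a species-level intercept is deliberately omitted by
default (the effect table typically has few repeats per species within a
subset, making that variance poorly identified).

Winner/loser calls are purely interval-based: winner iff CI lower bound
> 0, loser iff upper bound < 0. The annotated dendrogram encodes the calls
as node labels (`name|positive` etc.) on a unit-branch-length taxonomy
tree — it is a classification display, not a phylogeny.

## Mixed logit engine

Both duration analyses and the timeline models share one engine: binomial
and baseline-category multinomial logit with crossed random intercepts,
one variance per grouping factor (shared across response categories),
reference state *neutral*. Estimation is Laplace-approximated ML: for
fixed variances, fixed effects and random modes are maximized jointly by
damped Newton (step-halving, so the penalized objective is monotone; the
reported log-likelihood is the best over outer iterations), and the
variances are optimized by Nelder–Mead on their logs. As σ² → 0 the
criterion reduces exactly to the ordinary logit likelihood, which is the
basis of the engine's degenerate-case tests. "Year predicts the state" is
operationalized as a likelihood-ratio test of the year block (p < 0.05);
the quadratic year term is kept when it lowers AIC, with ties to linear.

Known properties of the Laplace approximation apply: its error against
exact (quadrature) integration grows with the random-effect variance
relative to the per-group information, from ~2e-4 at σ² ≈ 0.05 to ~2e-2 at
σ² = 0.5 on a 4-observation binary group. For the data sizes here (tens of
observations per group) it is accurate to well under the inferential noise.
Coefficients beyond ±15 on the standardized predictor scale are flagged as
separation. Predictors are internally centered and scaled to half-range;
all reported coefficients and predictions are transformed back.

## Time-specific analysis

Yearly states are the sign of the chosen model's derivative at each
calendar year of the monitoring period (exact-zero tolerance 1e-12);
neutral populations are neutral throughout. Group timelines fit the mixed
logit above and the cluster bootstrap resamples *populations*
(species × station clusters) with replacement, refits, and takes percentile
2.5/97.5 bounds of the predicted population-level probabilities. Two
bootstrap choices are ours:

- **B defaults to 1000** (minimum 200 enforced) — percentile intervals are
  unstable below that.
- **Variance components are held at the full-sample estimates during
  replicate refits** (fixed effects and random modes are fully
  re-estimated). Predictions at the population level (random effects at
  zero) depend on the variances only weakly, re-optimizing them per
  replicate is an order of magnitude slower and noisier near the σ² = 0
  boundary; `reestimate_variances=True` restores the full refit. Interval
  coverage under the default is checked by simulation in the test suite.

The per-year verdict applies, in order: (1) positive and negative CIs
overlap → *cancelled*; (2) both probabilities < 0.5 → *neutral*; (3) the
state with the higher probability. Overlap is checked first because
cancellation is the stronger statement (the data cannot distinguish the two
directions); the reverse ordering is available via `overlap_first=False`.

## Synthetic data

The generator emulates the structure the pipeline assumes: six ecosystem
components, stations per component, balanced abstract taxonomy
(`Class_<component>_<i>` — deliberately no real taxon names), series
lengths log-normal with median 30 clipped to [5, 91], interior observation
gaps at rate 0.1 (endpoints kept, ≥50% presence preserved), and the nine
trend archetypes as polynomials on the log scale. Archetype defaults:
directional slope 0.1/year on the log scale (a strong but realistic
monitoring-scale trend), unimodal amplitude 1.5 log units with the vertex
mid-period, baseline 3.0 log units (≈ 20 individuals), lognormal σ = 0.3,
negative binomial dispersion 0.5. Decelerating archetypes place their
vertex at 1.25× the period — curvature without an interior extremum.
Noise families per component: lognormal for phytoplankton and plants,
Poisson for zooplankton and birds, gamma-Poisson (negative binomial) for
macrozoobenthos and fish.

Presets: `null` (all neutral — type-I-error calibration), `mixed` (a
mixture echoing the ~61% neutral / negative-heavy directional composition
seen in large monitoring syntheses), `classbias` (two classes with true
mean slopes ±0.05 across 30 stations — meta-analysis recovery), and `flip`
(all populations peak at year 15 of a 31-year window — timeline
detection).

What the generator does **not** emulate: spatial autocorrelation between
stations, within-year seasonality (the pipeline aggregates to annual means
anyway), observation-effort changes over time, species interactions, and
taxonomic misidentification. Tests passing on this generator therefore
demonstrate the statistical machinery under the stated noise models — not
robustness to survey-design pathologies of real monitoring programs.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen to make Monte-Carlo error small
relative to the asserted margins while keeping the suite fast: 1000
populations for null calibration, 200 for directional power, 500 replicates
for meta-analytic coverage, 100 replicates for flip detection and the
duration analyses, cluster bootstraps at B = 200 (the enforced minimum).
The acceptance script uses lighter versions of the same computations
(e.g. 400 null populations) and reports the size next to every value.

## Known limitations

- The Laplace likelihood is an approximation; variance components of
  sparse groups (few observations per level) are estimated with bias, as
  for any Laplace-based GLMM fitter.
- The family-wise false-positive rate of the full candidate procedure on
  null data exceeds the per-test 5% by construction (~13–16% depending on
  the count-family dispersion of the data); the restricted single-family
  path is calibrated at the nominal rate. This is a property of
  any-significant-model-wins selection, documented rather than corrected.
- Wald intervals everywhere: no profile or small-sample intervals.
- The meta-analysis treats slopes from curved populations as linear
  summaries; populations whose Gaussian linear fit failed the screens are
  absent from the meta-analysis entirely (~25% under mixed noise).
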