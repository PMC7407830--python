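# Methods

This note documents the statistical model behind `synertri`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real plates.

## Data model

One row of the long CSV is one well-measurement: endpoint, compartment,
treatment label, control class (`s` stimulated / `ua` inactivated / `us`
unstimulated / `bud` positive control / `treated`), concentration (µg/mL,
total concentration for the equal-parts combination), time (h), replicate
and value (pg/mL). TEER wells carry the paired `value_before`/`value_after`
resistances (Ω) in a single row because the analysed statistic is their
difference and the pairing must be explicit. Budesonide's concentration is
µM and lives in dataset metadata, never on the shared µg/mL axis.

## Normalisation

* Mediators: percent of stimulated control, `100·r/s̄`, where `s̄` is the
  arithmetic mean of the stimulated-control replicate wells of the same
  compartment and time point. Only the upper anchor is used; the lower
  (inactivated) level is left to the curve fit's free bottom parameter.
  Division precedes the multiplication by 100 so the anchor maps to
  exactly 100.0 in floating point.
* TEER: difference stored as `after − before` (decline negative); any fixed
  sign convention yields identical normalized values because the anchors
  absorb it, and reports state the convention. Normalized scale:
  `100·(d − d̄_s)/(d̄_us − d̄_s)`, so the stimulated control is exactly 0 %
  and the unstimulated monolayer exactly 100 %.

## Dose–response model

Four-parameter logistic on log₁₀ concentration:

    r(x) = bottom + (top − bottom) / (1 + 10^{hill·(log10 x − log10 m)})

* Inhibition (mediators): `top` *fixed* at the stimulated-control level
  (100 on the percent scale), `bottom ∈ [0, top]` free, `hill ∈ (0, 10]`,
  `log10 m` bounded to the data range ± 3 decades. `m` is the curve's own
  midpoint (the standard "relative IC50").
* Enhancement (TEER): rising orientation, `bottom` fixed at 0 %, plateau
  free in (0, 100].
* Loss: least squares on well-level residuals (not per-concentration
  means), so the t quantile's degrees of freedom are `n_wells − 3`.
  Mediator fits use iteratively reweighted least squares with
  variance-stabilising `1/fitted` residual weights (two reweighting
  passes, weights held fixed within each pass): ELISA-type errors scale
  with the response level, and without the weighting the asymptotic
  intervals overcover materially. TEER differences carry roughly constant
  absolute error, so enhancement fits stay unweighted.
* Optimisation: trust-region reflective least squares with a multistart of
  5 midpoints log-spaced across the data range (the 4PL likelihood is
  non-convex); Hill start 1; convergence tolerance 1e-10 on the relative
  sum-of-squares reduction, at most 2000 iterations per start.
* Confidence interval: symmetric asymptotic interval on log₁₀ m from the
  Jacobian-based covariance and the t quantile at the residual degrees of
  freedom, back-transformed to µg/mL (so intervals are right-skewed on the
  concentration scale, matching how such assays report them). A singular
  covariance yields an explicitly unbounded interval rather than a number.
* Flat-curve verdict: a series whose per-concentration means all sit within
  one residual sd of the no-effect plateau has no concentration dependence;
  no IC50 is reported. A treatment is *inactive* for an endpoint when the
  curve is flat **or** no concentration level is Dunnett-significant
  against the stimulated control; the run report records which trigger
  fired.

## Significance layer

Pooled-variance one-way ANOVA, or a two-factor fixed-effects ANOVA
(treatment, time, interaction) for mediators measured at 4/24/48 h, followed
by Dunnett's multiple-comparison test against the stimulated control.
Adjusted two-sided p-values integrate the exact multivariate-t tail with the
one-factor control correlation structure (λᵢ = √(nᵢ/(nᵢ+n₀))) by
deterministic quadrature — 80-node Gauss–Hermite over the shared control
variate and adaptive quadrature over the chi-distributed error scale — so
the reported stars are reproducible without a seed and accurate to ~1e-9
(the k = 1 case agrees with the pooled two-sample t-test to machine
precision). Two-way Dunnett comparisons are made within each time point
against the same-time stimulated control, using the pooled two-way error
term; the slicing is a documented choice, as is the decision to apply no
additional multiplicity correction across endpoints. Star bands: * < 0.05,
** < 0.01, *** < 0.001, **** < 0.0001.

## Combination index

For the equal-parts ternary mixture, `IC50_comb = IC50(combination)/3` and
`CI = Σ IC50_comb / IC50_i` over the *active* components; inactive
components contribute no term (at least one must remain). Terms are
computed as `total/(3·IC50ᵢ)` and summed with compensated summation so the
equal-potency case returns exactly 1.0. Interaction bands are half-open,
closed at the lower edge — [0.1, 0.3) strong synergism (++++), [0.3, 0.7)
synergism (+++), [0.7, 0.85) moderate (++), [0.85, 0.9) slight (+),
[0.9, 1.10] nearly additive (0), then (1.10, 1.20] slight, (1.20, 1.45]
moderate, (1.45, 3.3] antagonism, (3.3, 10] strong antagonism — a fixed
convention needed because the source bands overlap at their edges; values
beyond [0.1, 10] clamp to the outermost band with an out-of-scale flag.
Pipeline mode computes CI from full-precision fitted values; replication
mode from the published integers; reporting rounds to 2 dp.

The parametric-bootstrap interval on CI (log-normal resampling of each
fit's log₁₀ half-max at its asymptotic standard error, percentile 2.5/97.5)
is an uncertainty-propagation extension beyond the point index and is
flagged as such in the run report.

## Synthetic-data generator

The generator draws the full plate design: for each mediator endpoint, a
reference level (ua or us, pg/mL), the stimulated level as reference ×
fold-induction (defaults: IL-6 8.5, TNF 3.3, macrophage PGE₂ 6.4, IL-8
12.1, MCP-1 1.6, epithelial PGE₂ 34 at 48 h; earlier time points scale the
inducible span by 0.4/0.8), and treated means along a 4PL with configurable
true IC50, Hill slope and floor. Inactive cells are flat at the stimulated
level. TEER wells embed a rising Hill recovery curve in paired before/after
resistances (baseline 500 Ω, 30 % stimulated decline, 10 % unstimulated
gain). Observed values are means × LogNormal(0, σ) with σ matched to the
configured CV — multiplicative because immunoassay error scales with level
and values must stay positive. The combination curve has its *own* true
IC50 rather than being composed from the parts, which makes the implied
true combination index a free, testable parameter.

Design sizes (the package's defaults): 8 log-spaced concentrations per
treatment across the assay's stated ranges (myrrh 0.1–100, coffee charcoal
1–500, chamomile 0.1–200, combination total 0.25–150 µg/mL), 3 treated and
6 control replicate wells, noise CV 0.15 (0.05 for the low-noise published-
table preset). Simulation-based tests use 200 plates for recovery/coverage
and 1000 null datasets for familywise calibration — sizes chosen to keep
Monte-Carlo error well below the tested margins on a single CPU.

What the generator does **not** emulate: inter-experiment (day/passage)
variance components, plate-position effects, ELISA standard-curve
nonlinearity at the assay limits, cytotoxic distortion of high-dose wells,
or any mechanistic coupling between endpoints. Passing recovery tests
therefore demonstrate the estimators are correct and calibrated under the
assumed noise model, not that real plates meet that model.

## Known limitations

* Components whose half-maximal concentration sits near or beyond the top
  of its tested range (e.g. a true IC50 of ~270 µg/mL on a grid ending at
  200, or a shallow 1.6-fold window such as MCP-1) are weakly identified;
  their fitted IC50s and hence the downstream combination index carry
  intervals spanning decades at realistic noise. This is an information
  limit of the design, not of the fitter — the efficient-estimator bound
  for such cells is ≳20 % relative IC50 error at 5 % well CV.
* The flat-curve test is reliable for truly constant series but is
  deliberately conservative under noise; the Dunnett trigger is the primary
  route to the inactive verdict in pipeline runs.
* Relative (midpoint) IC50 only; no absolute-IC50, 5PL or robust-loss
  variants.
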