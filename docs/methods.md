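# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `landclim`, stage by stage in pipeline order.

## Land-use change

Two categorical rasters (one per epoch) are first harmonized onto a common
category scheme via an explicit code map (unmapped codes are an error;
codes may be mapped to nodata to drop classes such as littoral cover),
resampled by nearest neighbour where resolutions differ, and masked
mutually so both epochs share an identical nodata footprint. An optional
geometry mask (e.g. a road network) removes all pixels whose centre lies
within a configurable buffer (default 75 length units) of the geometry —
`shapely.dwithin` on pixel centres, so the buffer is closed.

Per coarse square (default 10 abstract km, indexed `(col,row)` from the
lower-left corner) the pipeline computes: per-category cover fractions over
valid pixels (squares below 50 % valid pixels are dropped — configurable;
the choice matters only for heavily masked edge squares), fractional change
(modern minus historical; rows sum to 0 by construction), land conversion
`L` = share of valid pixels whose category changed (this bounds any single
category's net change from above, a tested invariant), and pixel-fate
transition rows for a focal category (probability vectors). Utilities for
pixel agreement and per-square RMSD support comparisons between alternative
digitisations of the same map.

Temperature trends are OLS slopes of annual mean temperature on year,
multiplied by 10 to give °C/decade. Sub-annual series are averaged to
annual means first, removing seasonal autocorrelation from the naive OLS
fit; fewer than three annual values inside the window yields a missing
trend. Per-taxon windows are configuration (the British defaults — plants
1961–99, birds 1973–2006, Lepidoptera 1961–2004 — ship as constants).

## Outcomes from records

Records `(species, taxon, square, period)` become presence matrices per
period. A species occupied in period 1 contributes: outcome 1 if recorded
again in period 2; outcome 0 if absent *and* some other species of its
taxon was recorded in the square in period 2 (a verified absence); no
outcome otherwise (the square may simply not have been visited).
Colonisations are recorded separately under the symmetric period-1 coverage
rule and feed only the trend analysis. The coverage rule uses the full,
unfiltered species list of the taxon. Species recorded in ≤ `min_squares`
unique period-1 squares are excluded (exclusive threshold, default 100 as
in national-scale applications; scaled-down synthetic runs use 30 — at 256
squares a 100-square filter would leave almost nothing, and 30 preserves
the filter's intent of guaranteeing enough outcomes for a 7-parameter
logistic fit).

Before fitting, each species is screened for separation: if, along any
single predictor, the persistence and extirpation values occupy
non-overlapping ranges (or ranges touching at exactly one value —
quasi-separation, treated as separation by default since both leave the
logistic MLE unbounded), the species is removed from species- and
taxon-level analyses. All-one or all-zero outcome vectors are flagged
"degenerate outcome". This range screen does not catch separation along
linear *combinations* of predictors; fits that remain unbounded are caught
by an explicit score-norm convergence check and excluded with a reason.

## Frescalo effort and trends

Neighbourhood weights: for each square, the `G = 200` geographically
nearest squares (self included, rank 1) are candidates; they are re-ranked
by Sørensen similarity of pooled species composition and the `K = 100` most
similar retained with weight `(1-(r_sim-1)/K)^4 (1-(r_dist-1)/G)^4`. Local
frequency `f_ij` is the weighted neighbourhood mean presence. The
sampling-effort multiplier `α_i` solves
`mean_benchmark(1-(1-f_ij)^α) = Φ` by bisection (|residual| < 1e-8), where
benchmark species are the top 27 % (configurable) of species with nonzero
local frequency — ranking by `f` equals ranking by rescaled `f*` because
the rescaling is monotone. The **recorder-effort covariate is `1/α_i`**:
under-recorded squares need a large multiplier to reach the target Φ, so
effort is its reciprocal; this direction is what makes effort decrease when
a square's detections are thinned (a tested monotonicity). The effort
covariate is estimated from first-period presence only (it controls for
historical recording intensity); rescaled frequencies
`f* = 1-(1-f)^α` for the trend machinery come from the pooled two-period
data.

Per species and period, the time factor solves
`Σ_{i visited} (1-(1-f*_ij)^TF) = observed squares` (bisection, tol 1e-8;
`TF = 0` with no records; capped at a configurable maximum, default 20,
and flagged when the equation has no finite root). The decadal trend is
`(TF₂-TF₁) / (Δmidpoint/10)`; only its sign is consumed downstream. TF uses
pooled-data `f*` and raw per-period totals rather than per-period
effort re-weighting — a documented simplification that the sign-level use
is robust to. The Telfer cross-check regresses logit second-period
occupancy proportion on logit first-period proportion across species,
weighted by the inverse binomial variance of the response
(`w = N p₂ q₂`), and standardizes the weighted residuals. Being a
*relative* index, its sign only matches the absolute Frescalo trend when
trend direction is not confounded with initial range size; the property
suite therefore checks agreement on worlds where expanders and decliners
start from the same occupancy.

Effort estimation needs a reasonably rich species pool: the benchmark mean
is an average over ~27 % of species, so its sampling noise — and hence the
between-square CV of effort under truly uniform recording — shrinks with
species count. The uniform-effort calibration world uses a 120-species
flora (national plant datasets are several hundred species).

## Model suite

PCNM spatial controls: Euclidean distances between square centroids are
truncated at `t` = the longest minimum-spanning-tree edge, with larger
distances replaced by `4t`; the truncated matrix is squared, double-centred
and eigen-decomposed; the two leading positive eigenvectors,
unit-normalised with sign fixed by the first nonzero loading, enter every
formulation. Degenerate geometries with fewer than two positive eigenvalues
are an error.

Logistic fits are Newton/IRLS maximum likelihood (statsmodels) on
internally z-scored covariates with coefficients mapped back to the raw
scale; convergence demands a score norm below 1e-6 on the standardized
problem in at most 100 iterations. Standardization changes nothing
statistically (log-likelihood is invariant to affine reparameterization — a
tested invariant) but conditions the Newton steps. The mixed (per-taxon)
model integrates a species random intercept by **adaptive** Gauss–Hermite
quadrature: each cluster's integrand is re-centred at its posterior mode
with curvature-matched scaling before applying 25 Hermite nodes, then
`(β, log σ)` is maximised by L-BFGS-B. Plain (non-adaptive) quadrature is
badly biased once clusters hold hundreds of observations — the integrand is
orders of magnitude narrower than the prior — which is why the adaptive
scheme is not optional. The implementation reproduces `lme4::glmer`
(`nAGQ = 25`) estimates to ~1e-2 on test problems (a cross-check in the
suite runs R directly). AIC counts the variance component as a parameter;
ties break toward fewer parameters.

AME for variable `v` is `unit · mean_i (β_v + β_int w_i) p_i(1-p_i)` with
`w` the interaction partner; it equals central finite differences to 1e-6
(tested). Units: 0.1 °C/decade for warming, 0.1 (ten percentage points) for
conversion; reports multiply by 100 to give percentage-point changes in
persistence probability. Requesting the AME of a variable absent from a fit
is an error, never silently zero. Confidence intervals are parametric
bootstrap percentile intervals (default 100 simulations, seeded): simulate
outcomes from fitted probabilities, refit, take the 2.5/97.5 percentiles;
refit failures are dropped and counted. With 100 simulations the percentile
end-points are themselves noisy, and measured coverage of nominal 95 %
intervals sits near 90–93 % — the calibration experiment in
`scripts/acceptance.py` reports the realized value rather than asserting
nominal coverage.

Mixed-model R² follows the latent-scale logistic convention:
`R²m = σ²_f/(σ²_f+σ²_u+π²/3)`, `R²c = (σ²_f+σ²_u)/(σ²_f+σ²_u+π²/3)`.
Collinearity reports are pairwise Pearson tests (r, d.f. = n−2, two-sided p
from the t transform).

## Interaction assessment

For species whose best model is interactive, both the interactive and the
matched additive fit predict persistence on an 11 × 11 grid: observed
minimum, the nine deciles (linear-interpolation percentiles) and maximum of
each predictor, controls at their medians — 121 paired predictions. A
constant predictor makes the grid degenerate and flags the species. The
paired *t* test on the 121 differences uses a Bonferroni threshold
`α/m` over the m-species family; zero-variance differences give p = 1 (all
zero) or a flagged infinite-t case (constant nonzero). Degrees of freedom
are reported honestly as valid pairs − 1 (120 for a full grid). Note the
test responds to a systematic *shift* between the two prediction surfaces:
a strong fitted interaction whose disagreement is sign-balanced across the
grid is — deliberately — not "meaningful" by this criterion. The
difference table sorts, for each grid level of one predictor, each
species' maximum absolute prediction difference across the other
predictor's 11 values into size bins (max is the default statistic; mean is
available since the tabulation convention is genuinely ambiguous); each row
sums to the species count by construction.

## Cohorts and reporting

Species with best formulations 2–4 are classified by coefficient sign into
T±, L± or the four additive sign pairs (coefficient sign equals AME sign in
non-interactive logistic models); controls-only, interactive,
exactly-zero-coefficient and separation-flagged species are excluded with
recorded reasons, and the bookkeeping identity (cohorts + exclusions =
input species) is asserted in tests. The cohort × trend-sign table
(zero-trend species dropped) is tested by Pearson chi-square without
continuity correction; empty cohort rows are removed and the reduced
degrees of freedom reported.

## Synthetic worlds

The generator emulates the study design at configurable scale. Spatial
structure comes from smoothed Gaussian latent fields (wrap-around
`gaussian_filter`, bandwidths configurable). The historical raster maps one
fine-scale latent field through its rank-uniform transform onto category
bins, so realized cover fractions equal the configured proportions
(default: urban 4 %, semi-natural grassland 65 %, arable 22 %, woodland
6 %, water 1 %, improved grassland 2 %) up to tie rounding. Per-square
conversion intensity is a Beta(2, 3) quantile transform of a coarse latent
field; the warming surface shares that latent field with a mixing weight
solved numerically against the realized fields so the sample
conversion–warming correlation hits `rho_LT` (default 0.5, the observed
range being roughly 0.38–0.58); an unattainable target raises an error
rather than clipping. Converted pixels are redrawn from a transition
kernel whose grassland row sends most converted semi-natural grassland to
improved grassland and arable.

Species persistence follows
`logit P = b0 + bT z_T + bL z_L + bI z_L z_T + bE z_E + bM z_M` in
**standardized** covariates, so coefficient magnitudes are comparable
across covariates and "strong effect" has a single scale; fitting on raw
covariates selects identically because all five formulations span the same
column spaces under affine maps. Unoccupied squares colonise with a
per-group probability (default 0.05), giving the trend analysis both gains
and losses. Detection is `P = 1-(1-q_j)^{E_it}` with species detectability
`q_j ~ U(0.4, 0.9)` and gamma(4, 0.25) square-period effort (mean 1).

Default problem sizes are deliberately desk-scale: 16 × 16 squares of
10 × 10 fine pixels and ~100 species for pipeline runs; 40 × 40 squares
with near-saturated occupancy (≥1500 occupied squares per species) for the
recovery experiments; the acceptance suite and script complete in a couple
of minutes on one CPU. What passing recovery tests show is that the
estimators are consistent and correctly implemented under the generator's
assumptions — smooth fields, logit-linear persistence, effort-thinned
detection. What they do not show: robustness to misclassified land cover,
non-stationary detectability, phylogenetic or dispersal-driven dependence
between species, or spatial autocorrelation beyond what two PCNM axes
absorb. The microclimate covariate is an arbitrary smooth field treated as
given, and the synthetic geography is a torus-smoothed abstract grid, not
a real coastline.

## Other numerical choices

- Bisection/brentq tolerances: 1e-8 or tighter for the Frescalo equations;
  effort multipliers with no root (all benchmark frequencies 0 or 1) are
  NaN and flagged, never clipped.
- AIC ties (to 1e-10) break toward fewer parameters.
- The quasi-separation screen treats touching ranges as separation by
  default (`include_quasi=False` restores the strict definition).
- Raster I/O: ESRI ASCII grid as the plain-text interchange format, plus
  single-band TIFF with a JSON sidecar for geo-metadata via `tifffile`;
  both round-trip exactly.
- Determinism: every stochastic component takes a seed or Generator; a
  rerun with the same configuration is byte-identical for report artefacts.
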