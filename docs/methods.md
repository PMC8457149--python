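# Methods

This note documents the models implemented in `rootdepth`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Leaf hydraulics

The vulnerability curve is `K_leaf(ψ) = A·e^(−B|ψ|)` with A, B > 0 and
all water potentials stored as non-positive MPa. The exponential is
evaluated on |ψ| so conductance *declines* under drying; a literal
`e^(−Bψ)` with negative ψ and positive B would rise, contradicting the
curve's purpose, so the magnitude convention is adopted and enforced
throughout. `K_max,leaf` is the curve value at ψ = 0 (the maximum over
the physical domain), hence `FLC = e^(−B|ψ|)` is independent of A.
Ψ₂₀ = ln(0.8)/B is the critical exposure threshold Ψ_crit.

Fitting uses the closed-form log-linear regression of ln K on |ψ| as the
start (exact on noiseless data) and polishes with nonlinear least squares
in the conductance domain; at low noise the two agree, and the nonlinear
step removes the log-transform bias at higher noise. Trait proxies
predict B from WSG and LMA and then A from B and LMA with the printed
polynomial coefficients; a non-positive predicted A or B flags the
species and excludes it from depth estimation rather than clamping —
silent clamping would distort FLC dynamics.

## Soil column

The full land-surface scheme behind the original water-potential fields
is not re-implemented; the inversion only needs ψ(z, t) with realistic
seasonal and depth structure. A 9-parameter bucket cascade over the
13-node grid Z = (0.01 … 13) m stands in, with layer interfaces at
arithmetic midpoints (top 0 m, bottom 15 m):

* Campbell retention `ψ = ψ_sat (θ/θ_sat)^(−b)` and conductivity
  `K = K_sat0 e^(−z/k_efold) k_adj (θ/θ_sat)^(2b+3)` (mm d⁻¹).
* Daily explicit update: interception (counted as canopy evaporation),
  infiltration into layer 1 capped by free pore space (excess → runoff),
  root-weighted transpiration `et_scalar · VPD` with a linear
  soil-wetness stress factor (full supply above 0.40 θ_sat, zero at the
  residual 0.10 θ_sat), then a top-down drainage cascade limited by donor
  water and receiver pore space; bottom drainage is discharge.
* The water balance closes to float rounding and is asserted at 1e−6
  relative to cumulative precipitation on every run.
* Optional warm-up years (the first forcing year repeated) are discarded
  to remove the initialisation transient; calibration-style runs use the
  standard 5-year spin-up convention, synthetic worlds use 3 warm-up
  years.

Default parameters (K_sat0 = 30 mm d⁻¹, k_efold = 100 m, b = 3,
θ_sat = 0.45, ψ_sat = −3 kPa, root_efold = 1.2 m, interception 0.12,
et_scalar = 4 mm d⁻¹ kPa⁻¹) were chosen so the column reproduces the
qualitative field situation the method assumes: surface minima near
−3 MPa, a dry-season drawdown front that weakens with depth, deep layers
(>2 m) above −0.5 MPa with small interannual dynamics, and seasonal
ψ-amplitude decaying monotonically down the column. Two structural
points matter for identifiability and were deliberate: roots are
confined to roughly the top two metres, so deep-layer dynamics are
*cascade-filtered recharge* rather than direct extraction — depth then
maps onto a smooth family of increasingly lagged, smoothed rainfall
responses, which is what makes depth confusions concentrate among
adjacent layers; and conductivity decays only weakly with depth, so deep
layers recharge in most wet seasons instead of locking at saturation or
drifting monotonically.

Calibration: Latin-Hypercube draws over explicit parameter ranges;
objective = mean over observation streams of RMSE divided by the
stream's SD (equal weighting across streams of different units); the
top-k members form the water-potential ensemble. Drought flagging: per
day-of-year, pool the realization-mean ψ across years, take the 5th
percentile, and flag (year, DOY) strictly more negative; pooling across
individual realizations is available by flag.

## Growth processing

Census tables are reduced to species growth series as: per-tree interval
growth (Δdbh/Δt, cm yr⁻¹); selection of canopy trees (species maximum
height ≥ 30 m) that are ≥ 30 cm dbh at entry, alive and measured at every
census, and free of outlier intervals (bounds −0.5 to 7.5 cm yr⁻¹,
configurable ForestGEO-style defaults — the original outlier rule is not
published in the main text); per interval, pooled OLS of growth on
ln(dbh at interval start) to remove the size effect (a pooled model is
stabler than per-species fits at small n; configurable); residuals
z-scored within the interval; species value = median over its trees,
kept only with ≥ 3 trees. A tree with any outlier interval is dropped
entirely (the "complete records" reading).

## Depth inversion

`VPD̂*` is a polynomial GPP proxy of VPD, floored at 0 and min-max
standardized over the full period. The site-specific polynomial is not
published; the default quadratic `2v − v²` encodes the known shape
(growth rises with VPD to a threshold, then falls as stomata close) and
is configurable. `FLC*` is min-max standardized within species over the
full period, per depth; a constant (fully unstressed) series maps to 1,
so a depth with no dynamics reduces the factor to the VPD term.

Three model structures are implemented: the main multiplicative form
(mean of FLC*·VPD̂*), an additive form (interval means of FLC* and VPD̂*
as separate regressors), and a leaf-area variant (FLC*·VPD̂*·LAI* with a
parametric seasonal LAI curve). Per depth, ordinary least squares of the
species series on the interval factor(s); the best depth maximizes R²
(AIC available), with exact ties to the shallower depth. Depths whose
fitted slope is negative are preferred against: a growth *limitation*
factor must act positively, and negative-slope winners are in practice
anticorrelated artifacts of a distant layer (the preference is
configurable off; if no depth has a positive slope the constraint is
dropped). The published selection statistic is not available; max-R²
with these two guards is this package's documented choice.

Species ERD = the median of per-realization best depths (lower median on
even counts, so the estimate stays on the discrete grid);
SE = SD(best depths)/√n, reported alongside the full distribution, and 0
for a single realization. Structure selection ranks candidate structures
by the R² of a linear regression of ERD on xylem-water δ²H (≥ 3
overlapping species required), ties resolved toward the earlier-listed,
more parsimonious candidate.

## Demography

Mortality `M = (D/N)·(100/d)` % yr⁻¹ on the ≥ 10 cm dbh population
(distinct from the ≥ 30 cm growth population). Exposure = % of interval
days with realization-mean ψ at the ERD layer strictly below Ψ_crit
(boundary days do not count; averaging per-realization exposures is
available by flag). Mortality–ERD regressions run per census interval
and leaf-habit group (all deciduous habits pooled), flagged at α = 0.05
and α = 0.1 with no multiple-testing correction. Trait associations use
Spearman rank correlations (midranks on ties) with ≥ 4 overlapping
species.

## Synthetic data generator

The generator implements the forward version of every model the pipeline
inverts, on a 365-day no-leap calendar, deterministically from a single
seed (independent substreams per component).

* **Climate.** Raised-cosine seasonal cycles (dry season mid-December
  through April): rainfall as seasonal occurrence probability ×
  gamma-distributed wet-day amounts (intermittency drives the surface
  layers), mean annual total 2627 mm with ±20% interannual variability
  in yearly totals; VPD dry-season-peaked with daily noise. Drought
  years are stratified — at least one per 5-year census interval, extras
  Bernoulli to match the marginal rate 0.2 — and come in three seasonal
  types (prolonged dry season, delayed wet-season onset, mid-wet-season
  failure) applying a windowed rainfall deficit (0.5× the base factor
  0.6 inside the window) and VPD inflation (1.2×), so different depths
  carry different drought signatures.
* **Species.** WSG ~ U(0.3, 0.8), LMA ~ U(50, 200); B and A from the
  trait proxies plus additive noise (rejection-resampled to keep both
  positive); true ERD layers cycle through grid indices 5–11
  (0.37–7.8 m), the depth span over which the method is informative —
  centimetre-scale surface layers are hydrologically near-degenerate for
  this purpose; alternating evergreen/deciduous habits; β₀ ~ U(0.1, 0.3),
  β₁ ~ U(0.5, 1.5).
* **Hydrological ensemble.** Realizations multiply the base soil
  parameters by uniform jitters: ±5% on the surface-flux parameters
  (well constrained by calibration against moisture, ET and discharge)
  and ±30% on the depth-profile parameters (k_efold, root_efold), which
  calibration leaves far more uncertain. Growth truth is driven by the
  realization-mean ψ field; the inversion then fits each realization, as
  with real data.
* **Growth.** G = β₀ + β₁·factor(true layer) + N(0, σ); σ defaults to
  25% of the species' noiseless signal SD (an absolute σ is available).
  Per-tree dbh trajectories consistent with the species means (plus
  tree-level noise) exercise the census-processing stage.
* **Mortality.** Binomial deaths with a logistic link,
  logit(p_annual) = logit(0.015) + slope·exposure%, evergreen slope 0.04
  vs deciduous 0 by default, so the evergreen-only mortality–depth
  association is reproducible. The logistic link keeps probabilities
  valid; it is a stand-in for recovery testing, not an estimate of any
  real mortality process.
* **Isotopes.** δ²H(z) = −55 + 35·e^(−z/2 m) + N(0, 1.5‰) at the true
  ERD: strictly monotone toward the surface, as required for δ²H to
  index uptake depth.

What passing recovery tests show — and do not show. Under these
conditions the pipeline recovers the exact true layer for >80% of
species on typical seeds (100% at zero growth noise) and is within one
layer for ~95%, with residual confusions concentrated among adjacent
layers. The generator shares the inversion's own FLC/factor code for the
forward model, so recovery tests validate identifiability and
implementation consistency, not the realism of the bucket column; real
data add census-date irregularity, measurement error structure,
species-specific phenology and climate nonstationarity that the
generator does not emulate.

## Numerical choices and degenerate inputs

Explicit daily stepping with drainage limited to available water
guarantees stability and exact balance. Constant growth series give
R² = 0 at every depth (shallowest layer returned). Constant FLC maps to
1; a constant VPD̂ series is an error. Zero-variance observation streams
are a standardization error. Single-realization ERD has SE 0 by
definition. Seeds derived from the user seed stay below 2³¹.

## Experiment problem sizes

The standard recovery experiment uses 12 species, 25 years of daily
forcing, 5 census intervals and 20 realizations; calibration recovery
uses 500 LHS draws (top 20) over 6 forcing years — identifiability of
the truth member is length-independent since truth is in the ensemble;
structure selection uses 20 seeds at 5 realizations and 10% growth
noise. These sizes are the package's standard study conditions and keep
the full suite and the acceptance run each within a few minutes on one
CPU.

## Known limitations

No Richards solver, energy balance, aquifer or lateral flow; no stem or
root vulnerability curves or capacitance; ERD is a single
central-tendency depth, not a rooting profile; the ensemble emulates a
calibrated posterior by parameter jitter rather than by re-running the
full calibration; mortality and isotope generative links are invented
stand-ins; alternate growth-model structures cover the
multiplicative/additive/LAI axes only.
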