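# Methods

This note documents the models, numerical choices and known limitations of
`seasonair`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Exposure aggregation

Gridded seasonal concentration surfaces (µg/m³, one raster per pollutant ×
season) are averaged over the member cells of each statistical sector —
plain zonal statistics with equal cell weights, since membership is
exclusive and cells are uniform in size. Missing cells (nodata) are excluded
from every mean; a sector whose cells are all missing is a hard error. The
annual sector mean is the unweighted mean of the four seasonal means: the
seasons are equal-length aggregates of monthly surfaces, and the seasonal
contribution shares they imply sum to one by construction.

Seasonal shares of annual residential exposure are, per season, the
population-weighted mean of sector seasonal means divided by the sum over
the four seasons. Population weighting is the default because the quantity
of interest is residential exposure; an unweighted variant
(`weighted=False`) is kept for sensitivity. Sectors with zero population are
accepted but carry no weight (a warning is logged).

## Seasonal ratios

The summer/winter ratio of a stratum (sector, land-cover class, DEGURBA
class, or the whole grid) is the ratio of the stratum-mean summer
concentration to the stratum-mean winter concentration — one fraction of
aggregates, not a mean of cellwise ratios. The cellwise-mean alternative is
available (`cellwise=True`) for sensitivity; the two differ whenever
concentration and ratio covary across cells within a stratum.

Uncertainty is a seeded nonparametric bootstrap over cells (default
B = 1000, percentile 2.5/97.5). The min–max range of cellwise ratios is
available as an alternative interval (`interval="range"`), because interval
semantics in reported stratum tables are not always explicit; output rows
carry an `interval` column naming the method used. Winter dispersion is
reported as the standard deviation across stratum cells.

Distance to roads is a Euclidean distance transform (uniform cost surface)
from each cell center to the nearest road cell, normalised by its maximum
over the grid, so a cut such as 0.05 reads as a fraction of the largest
road distance. Concentration–distance profiles are LOESS fits (plus a
parallel ordinary linear fit) of cell concentration against normalised
distance; percent declines between the curve value at the origin and at a
cut distance are reported as `100·(c₀ − c_d)/c₀` at a configurable rounding.

## LOESS

`LoessRegression` implements classical locally weighted regression: at each
evaluation point the ⌈span·n⌉ nearest observations (distance ties broken by
lower index — deterministic) are fit with a weighted polynomial of degree 1
or 2 under tricube weights `w = (1 − (d/d_max)³)³`. The fitted value is the
local intercept. Pointwise standard errors use the local hat vector and a
global residual variance `σ² = RSS/(n − tr(L))`; confidence bands are
fitted ± 1.96·se. No robustness iterations are applied, and evaluation
outside the data range is an error (no extrapolation). Defaults span = 0.75,
degree = 1 are conventional; both are echoed in all outputs. There is no
automatic bandwidth selection.

## Preventable fraction

The exposure–response model is log-linear: RR per 10 µg/m³ (RR₁₀) rescales
to an increment CON as `RR = exp(ln(RR₁₀)/10 · CON)`, and the preventable
fraction is `PF = 1 − 1/RR`. Defaults are the ELAPSE all-cause-mortality
estimates (NO₂ 1.045 [1.026–1.065]; PM₂.₅ 1.118 [1.060–1.179]) and the WHO
2021 long-term guidelines (10 and 5 µg/m³).

Two conventions for CON are implemented because the choice is substantive:

- `counterfactual="guideline"` (default): CON is the excess of the annual
  sector mean over the guideline, clipped at zero. This is the only reading
  under which a sector at or below the guideline has PF = 0, consistent
  with a counterfactual of exactly reaching the guideline.
- `counterfactual="zero"`: CON is the raw concentration (counterfactual of
  zero exposure).

RR₁₀ uncertainty is propagated by Monte Carlo: draws from
Triangular(a = CI low, c = point estimate, b = CI high) via inverse CDF on a
seeded uniform stream (deterministic given the seed; a degenerate a = b
returns the constant). Default 10,000 iterations. Per iteration, every
sector's PF is computed from the drawn RR₁₀ and the national PF is the
population-weighted mean of sector PFs; the interval is the 2.5/97.5
percentile over iterations and the point estimate uses the RR₁₀ mode.
"Population-weighted sum" is read as a weighted mean of sector PFs; the
alternative — PF of the population-weighted mean exposure — is available
(`aggregation="pf_of_mean"`); the two differ under the nonlinearity of PF.
An RR below 1 (possible only with user-supplied protective ERFs) is clipped
to PF = 0 with a warning. Mortality counts and DALYs are out of scope: the
analysis stops at the fraction.

## Disparity curves and the turning point

Deprivation curves smooth a sector metric (annual mean or summer/winter
ratio) against the deprivation decile — treated as numeric 1..10, matching
the continuous presentation such curves usually receive — separately per
DEGURBA class, with the package LOESS. Strata with fewer than 5 sectors are
skipped with a warning.

The accessibility/car-ownership turning point is detected by an explicit
rule (visual inspection of a smoothed curve is not testable): fit LOESS of
cars per household against the score, differentiate the fitted curve on a
fine grid (401 points), and report the smallest score at which the
derivative falls below −0.5 × max|derivative| and stays below it for the
remainder of the detection window. Three refinements make this stable:

- The detection window ends once the curve has completed 90 % of its total
  decline. Car ownership saturates at zero, so with an early changepoint
  the smoothed curve flattens at the floor and the flat segment carries no
  regime information; requiring "below threshold" through it would make
  detection impossible. The window's closing boundary point is likewise
  exempt.
- The derivative is moving-average smoothed over 9 grid points (~2 % of the
  score range) before thresholding, damping the wiggle of the local fits.
- The detector's LOESS span defaults to 0.15, small enough to resolve a
  changepoint near the edge of the score range; wider spans smear the
  corner and bias the detected point toward the interior.

A curve already descending at threshold rate from the start of the range has
no regime change (`detected_ = False`), as do constant curves. Pre- and
post-turning-point slopes come from straight-line fits on either side.
Detection is invariant under adding a constant to the response. All rule
parameters (span, threshold fraction, completion tolerance, smoothing
width) are constructor arguments and echoed in outputs.

## Synthetic region generator

The generator emulates the statistical structure of a small northwest
European study region at desk scale; it is not a dispersion model.

**Concentration surfaces.** Before noise,
`conc = f_s·bg_winter + g_s·inc_winter·exp(−d/L)` with `d` the distance
(cells) to the nearest road cell and `L` the decay scale (default 3 cells).
Winter has `f = g = 1`; spring and autumn scale both terms by one factor
each (0.75 and 0.70 for both pollutants), so their ratio to winter is that
factor everywhere; for summer, `f` and `g` are solved so the cellwise
summer/winter ratio equals the planted road ratio exactly at d = 0 and the
planted background ratio in the far field. Defaults anchor to observed
Belgian magnitudes: winter backgrounds 20 (NO₂) and 14 (PM₂.₅) µg/m³, road
increments at source 15 and 3 µg/m³, planted ratios 0.78 (road) / 0.46
(background) for NO₂ and 0.56 / 0.51 for PM₂.₅ — NO₂ strongly
traffic-modulated, PM₂.₅ nearly flat across space, winter everywhere above
summer. Cell noise is independent Gaussian (default sd 0.5 µg/m³) with a
0.1 µg/m³ positivity floor.

**Sectors.** The grid is partitioned into contiguous sectors by a
rectangular tiling perturbed by random merges (union-find over adjacent
tiles). Populations are lognormal with mean ≈ 500 (the size of a Belgian
statistical sector). DEGURBA classes are road-distance tertiles (1 = city,
closest). Deprivation deciles rank a latent score in which urban deprived
sectors sit closest to roads and rural deprived sectors farthest — the
empirical gradient the disparity analysis should recover; the global
ranking guarantees all ten deciles appear whenever there are ≥ 10 sectors.
An additive urban-NO₂ deprivation term (`slope·(10 − decile)`, default
0.8 µg/m³ per decile) is scaled per season by the background profile, so it
strengthens the deprivation–NO₂ gradient without disturbing any
summer/winter ratio, and is zero on road cells (no residents on road/rail
land; keeps the planted road ratio exact). Land cover uses a reduced
6-class palette (urban fabric, road/rail, industry, arable, pasture,
forest) — enough to exercise stratification without a 44-class nomenclature.
Accessibility scores are near-uniform on [0, 10] with a mild urbanity tilt;
cars per household follow a plateau (default 1.1, near the Belgian average
of ~1.06) with a linear decline (default −0.4 per score unit) beyond the
planted changepoint (default 8.0), Gaussian noise (sd 0.05), floored at 0.

**Randomness.** One master seed; each component draws from its own
`default_rng([seed, k])` substream in documented order, so fields and
sectors are individually bit-reproducible and regenerating with the same
seed is identical.

**Recorded truth.** Alongside the outputs the generator records, computed
from the noise-free surfaces: per-sector seasonal means, per-stratum
summer/winter ratios (land cover and DEGURBA), the planted ratios, and the
car-ownership changepoint parameters. Noise-free pipeline runs recover the
per-sector means and stratum ratios to 1e-9; at the planted ratios this
exactness holds at road cells by construction and in the far field up to
`exp(−d/L)` leakage of the road increment (tests use d/L > 20, where the
leakage is below 1e-9).

**What the generator does not emulate.** No meteorology, atmospheric
chemistry or dispersion physics; no long-range transport (the main reason
real PM₂.₅ patterns are flatter and less interpretable than NO₂); no
irregular sector geometries; no multi-year trends (year-to-year comparison
reduces to independent runs); no correlation between population size and
urbanity. Passing recovery tests therefore demonstrates the correctness of
the estimators under the planted statistical structure, not the realism of
that structure.

## Problem sizes and defaults

The default region is 60 × 80 cells (4,800) with 48 sectors — large enough
for stable stratum means and bootstrap intervals while keeping a full
pipeline run around a second. Turning-point recovery studies use 600
sectors: the analysis this emulates operates on the order of 10⁴ sectors,
and changepoint location from a smoothed derivative needs a few hundred
points for the local fits to resolve a corner under ownership noise of
0.05 cars/household. Monte Carlo uses 10,000 iterations (PF interval
endpoints reproducible to well under 5 % relative across seeds); ratio
bootstraps use B = 1000.

## Known limitations

- The LOESS standard error uses a global residual variance; bands are
  approximate where noise is heteroscedastic (e.g. near roads).
- The distance transform is plain Euclidean; no road-network routing or
  anisotropic cost surface.
- Stratified ratios treat strata as fixed cell sets; no uncertainty is
  attached to the stratification itself.
- The turning-point rule detects a single sustained-decline regime change;
  multiple changepoints or non-monotone regimes are out of scope.
- GeoTIFF support writes plain single-band TIFF with a JSON sidecar for
  grid metadata rather than embedded geo-tags; ESRI ASCII grids are the
  self-contained interchange format.
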