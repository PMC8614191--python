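# Methods

## The thermal-dynamics model

Daily maximum water temperature `T_w` around an extreme date is modeled as

    dT_w/dt = [ a (T_aM − T_w) + b (T_am − T_w) ] / Q + c

with `T_aM`, `T_am` the day maximum and minimum air temperatures (°C), `Q`
streamflow (m³/s here; any consistent flow unit works), `a` and `b` the day
and night thermal sensitivities (flow · day⁻¹) and `c` the non-convective
thermal flux (°C/day).  The two convective terms pull water temperature
toward warm daytime and cool night-time air, with the pull damped by flow
volume; `c` absorbs advection and other processes not explicitly modeled.

**Discretization.** The continuous derivative is discretized by a forward
difference with regressors evaluated at day *t*:

    T_w[t+1] − T_w[t] = a·x₁[t] + b·x₂[t] + c,
    x₁ = (T_aM − T_w)/Q,  x₂ = (T_am − T_w)/Q.

The synthetic generator steps the same recursion forward (explicit Euler),
so the OLS estimator and the generator are exact inverses: noise-free
windows recover (a, b, c) to machine precision, which pins down the whole
estimation path in tests.  The scheme is stable only for (a+b)/Q < 2; the
generator validates configurations against this bound, redraws individual
site tails that violate it, and the simulator raises on any remaining
violation rather than producing oscillating trajectories.

**Fit.** Each site × extreme event contributes one 15-day window (±7 days
around the event date; 14 differences, 3 parameters).  Windows with any
missing day are refused outright — with so few degrees of freedom,
imputation artifacts would be indistinguishable from signal.  Estimates are
plain OLS with classical standard errors; `a`/`b` are not sign-constrained,
and negative estimates are flagged rather than clipped.  A `trajectory` fit
mode is also available (nonlinear least squares matching the integrated
trajectory from the first observation) for sensitivity analysis; the
derivative mode is the default because of the exact generator/estimator
duality.  The model is identifiable only up to the scaling (a, b, Q) →
(ka, kb, kQ); fits are interpreted in the units of the supplied flow.

## Extreme-date identification

The per-site seasonal expectation of `T_w` is a cyclic P-spline: 12 cubic
B-splines wrapped on day-of-year (period 365.25, leap years rescaled), a
wrapped second-difference coefficient penalty, and the smoothing parameter
chosen by generalized cross-validation over a 25-point log grid.  A date is
a regional extreme when its residual exceeds the site's q-quantile
(default 0.98) at a minimum fraction of sites (default 0.5); runs of
consecutive qualifying days collapse to the day with the largest
network-mean residual.  Two caveats: (i) this anomaly rule is this
package's own documented procedure — detection on real data should be
treated as approximate, and an externally supplied event list can bypass it
entirely; (ii) strict monotonicity of the *collapsed* event list in q and f
can be broken when lowering a threshold merges two runs; the monotonicity
guarantee holds for the underlying qualifying-day set.

Meteorological seasons are fixed month blocks (Dec–Feb winter, Mar–May
spring, Jun–Aug summer, Sep–Nov autumn).

## Landscape metrics

All zonal statistics are raster-based: footprints are shapely polygons
rasterized by cell-center containment on the site's DEM window.  Planar
metric coordinates throughout; no CRS handling.

- **BFI** — smoothed-minima separation: non-overlapping 5-day blocks,
  block minima, a minimum is a turning point when 0.9·mᵢ ≤ mᵢ₋₁ and
  0.9·mᵢ ≤ mᵢ₊₁; first/last block minima anchor the baseline; linear
  interpolation between turning points at the days the minima occurred,
  capped at observed flow; BFI = baseflow volume / total volume over the
  anchored span.  Always in [0, 1]; invariant to rescaling the flow.
- **Shade** — the angle between the surface normal (8-neighbour Horn
  gradients, borders replicated) and the solar-noon sun direction, clamped
  to [0, 90°]; 90° is full shadow.  Solar noon uses the day-of-year
  declination formula (23.44° sin(2π(284+n)/365)), noon elevation
  90° − latitude + declination, azimuth due south.  A ray-march along the
  sun azimuth (default reach 200 m) marks cast shadows (shade = 90°)
  wherever the local horizon exceeds the sun elevation.  Cast shadows are
  ON by default: vegetation shading of a water surface is physically an
  occlusion effect, and with pure incidence a flat water cell would never
  respond to bank canopy at all.  A flag restores pure-incidence mode.
  The site value is the *median* shade over water-surface cells in the
  footprint, averaged over the extreme dates.
- **Water surface** — reaches with drainage area ≥ 1 km² enter the mask;
  below 50 km² a fixed 2 m half-width corridor around the channel line,
  above it a drainage-scaled width (0.5·√A m) standing in for a mapped
  water polygon.
- **Sinuosity** — per reach, polyline length over the straight endpoint
  distance ("mean axis" read as the straight segment between reach
  endpoints — the simplest defensible interpretation); the site value
  weights each upstream reach's sinuosity by the channel length it
  contributes inside the footprint.
- **Channel slope** — elevation drop between points 2 km upstream (main
  stem at junctions) and 2 km downstream of the site along the network,
  over the channel length actually walked (truncated with a warning).
- **Elevation** — DEM value at the site cell.  **Area** — catchment
  polygon area.  **Level** — daily median water level averaged over the
  extreme dates.
- **Land cover** — proportions of the eight aggregated categories (AGRI,
  ARTI, BROAD, HERBA, FORESTS, NEEDLE, OTHER, WATER) over footprint cells;
  an 18→8 class mapping table can be applied when a finer product is
  supplied; unmapped codes are a named error, never silently dropped.

The six footprints per site are the upstream catchment CA; buff_1/buff_2 =
CA ∩ 1 km/2 km discs centered on the site; ripa = CA ∩ a 50 m-per-side
corridor along the upstream network; buff_k_ripa = ripa ∩ buff_k (enforced
cell-for-cell).  Shade and sinuosity live on the watercourse, which is the
same within each CA/ripa and buff_k/buff_k_ripa pair, so those pairs share
values; AREA, SLOP, ELEV, LEVEL and BFI are station-scale and replicated
across all six.

## Stepwise regression

Predictors are z-scored (sample sd, ddof 1); constant columns are a named
error.  Selection starts from the full 15-predictor model and is
bidirectional: at each step every single add/drop is scored by Gaussian
AIC (−2 log L + 2(p+1)) and the best strictly-improving move taken, ties
broken by the fixed predictor order.  When no move strictly improves, an
AIC-neutral *drop* is accepted (parsimony on ties — relevant only for
degenerate perfect fits, where the RSS is floored at relative numerical
noise so that exact fits tie instead of ranking by rounding error).  The
selected set is refit by OLS; significance stars follow the conventional
bins (≤0.001 ***, ≤0.01 **, ≤0.05 *, ≤0.1 #).  p-values are not adjusted
for multiplicity; the report says so.  Rows with missing values are
dropped listwise per model with a logged count.  The start-full
bidirectional convention matches the standard stepAIC workflow; starting
direction was an open choice and is documented here rather than exposed,
since the endpoint coincides with exhaustive best-subset AIC on the
orthogonal designs used for validation.

## The synthetic study

The generator's defaults are the study conditions: 92 sites, daily records
2012–2018, 17 summer heat waves on the reference extreme dates (amplitude
+8 °C, 3 days, triangular), latitude 50° N.

- **Network/terrain**: each basin is a rectangular valley (2:1 aspect,
  2–12 km², snapped to the 10 m grid so polygon areas equal rasterized
  cell counts exactly) with a sinusoidal main stem (amplitude per basin,
  zero → sinuosity exactly 1) and three straight tributaries; drainage
  area grows strictly downstream.  Terrain falls along the stem
  (per-basin gradient) and rises away from it (cross-slope 0.02), so flow
  paths descend monotonically.  Riparian canopy blocks (22 m — a mature
  gallery forest, and tall enough that one 10 m cell south of a water
  cell occludes a 63° summer sun) are placed within 50 m of the stem with
  per-basin probability `tree_density`, using nested uniform draws so
  raising the density only ever adds canopy; canopy cells are forest in
  the land-cover raster, whose background is patchwise multinomial from
  per-basin Dirichlet proportions.
- **Climate**: seasonal cosine (mean 10 °C, half-range 10 °C, peak day
  201) + regional AR(1) (sd 2 °C, ρ 0.7) + site offsets (elevation lapse
  −6.5 °C/km) + the scheduled waves; diurnal range 9 ± 1.5 °C, floored at
  0.5 °C so `T_am ≤ T_aM` always.
- **Discharge**: constant site baseflow (lognormal, median 2 m³/s, σ 0.25)
  plus exponentially recessed storm pulses with regional timing; the
  pulse scale is set so each site's long-run quickflow fraction equals its
  drawn share (mean 0.4), making the computed BFI strictly decreasing in
  that share — the BFI dial.  Level = k·Q^0.4 (k per site), a monotone
  stage relation.
- **Ground truth**: the 15 covariates are first *measured* from the
  generated rasters/series at the CA scale by the package's own landscape
  code, standardized, and the true (a, b, c) are linear in them —
  intercepts (0.55, 0.4, 0.1); active slopes SHADE −0.15 / AREA +0.18 /
  LEVEL +0.15 on a, BFI −0.18 / OTHER +0.15 / NEEDLE +0.12 on b,
  OTHER +0.12 / SINUO +0.10 / AREA −0.08 on c; site noise sd 0.06.
  Using measured (not target) covariates means the full pipeline recovers
  the generating relationship *exactly* when both noise terms are zero
  (regression R² = 1), the strongest possible end-to-end check.
  Magnitudes were fixed by the Euler stability bound against the baseflow
  distribution and by keeping the (a, b) ≥ 0.02 positivity floor rare
  (≈5–10% of sites; floored and stability-redrawn counts are recorded in
  `truth.json`).  (a, b, c) are constant per site by default; an
  `event_mode="jitter"` redraws them per event, since how they vary
  between events at one site is not observable from the aggregated
  summer analysis.
- **Water temperature**: explicit Euler of the model with the event
  triple inside ±7 days of each event and the site triple elsewhere,
  started at the local equilibrium, plus 0.2 °C observation noise.

What the generator does *not* emulate: rainfall–runoff dynamics and
hydraulic routing, hyporheic processes, sub-daily variability, realistic
catchment shapes and stream orders, spatially correlated land-cover
between basins, and measurement gaps.  Passing tests therefore demonstrate
the correctness and statistical behavior of the *methods* under the
model's own assumptions — not that real streams satisfy those assumptions.

## Numerical choices and degenerate inputs

- Window fits require full rank; a window where air and water
  temperatures do not separate (e.g. all equal) is a named degenerate-fit
  error, not silent zeros.
- BFI needs ≥ 3 complete blocks; shorter series are an error.  Turning
  points use ≤ comparisons with the 0.9 factor.
- The baseline spline's GCV grid spans λ ∈ [10⁻², 10⁶]; the basis
  reproduces constants exactly, so a constant series has zero residuals.
- Hillshade borders use replicated-edge gradients; the shadow ray-march
  skips shifts beyond the grid.
- Rasterization is cell-center containment; analytic-area tests
  (half-disc clipping, corridor widths) pass at ~2% at the default
  resolution, and exactly where geometry snaps to the grid.
- Problem sizes in the test suite and the acceptance script (500 recovery
  windows, 100 selection replicates, 1,000 BFI series, one full 92-site
  study) were chosen to keep the whole run in the low minutes on one CPU
  while leaving Monte-Carlo margins wide relative to the asserted bounds.

## Known limitations

- The extreme-date detector is a stand-in; real-data event lists should be
  supplied externally when available.
- Water level and discharge enter both the generator and the fitted model
  as the same daily series; with field data, stage–discharge inconsistency
  would add errors-in-variables bias not studied here.
- Shade is purely geometric (no diffuse radiation, no transmissivity);
  cast shadows depend on raster resolution relative to canopy height.
- With 14 observations per window, `c` is weakly identified; its
  regressions should be read with the same caution as any short-window
  intercept.
- The deposited per-scale site tables of the original monitoring campaign
  are required for the real-data reproduction path (`data/supplementary/`)
  and cannot be bundled here.
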