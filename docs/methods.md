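# Methods

## Model structure

The simulator couples three process modules over one lattice state:

1. **Vegetation dynamics**, run once per 3-month season;
2. **Wind field**, computed per wind event (20 events per season);
3. **Slab sediment transport** with shadow zones and avalanching,
   run per event on the wind field.

Fire and grazing act on the vegetation state at the seasonal
boundary. The state at the end of a season is the initial state of the
next; the vegetation update is synchronous (all decisions are functions
of the previous snapshot plus per-cell uniform draws), which makes it
provably independent of cell iteration order — a property the test
suite checks against a scalar cell-by-cell oracle.

### Assumptions

- One plant per cell; a cell is occupied or bare. "Population density"
  is occupied cells / total cells; per-species cover is counted the
  same way (crowns are not distinguished from trunks).
- Cell size 1 m, so plant footprints are ~one cell and wake lengths are
  metre-scale; slab height 0.1 m (classic slab-model convention).
  Both configurable.
- Periodic boundaries by default: sediment mass is then conserved
  exactly (testable to the slab); an open mode exists for sensitivity
  runs and truncates neighbourhoods, wakes and shadows at the edge.
- Precipitation is the only climatic driver of plant growth;
  temperature is not modelled. Wind affects plants only through the
  sediment balance (burial/exposure stress).
- Soil nutrients exist as a per-cell placeholder attribute with no
  dynamics.

## Vegetation parameters

Growth pathways are normalised logistics in growth units g:
biomass = b_max·σ̃(g/g_max), height = h_max·σ̃(g/g_max), with σ̃ scaled
to hit 0 at 0 and 1 at 1. Porosity is a species constant. Reference
parameterisation (declared stand-ins, tunable in `EcologyConfig`):

| parameter | grass | shrub | tree | units |
|---|---|---|---|---|
| g_max | 8 | 40 | 100 | growth units |
| lifespan | 20 | 160 | 400 | seasons |
| b_max | 2 | 30 | 400 | kg (relative) |
| h_max | 0.5 | 2 | 8 | m |
| porosity | 0.15 | 0.55 | 0.40 | – |
| harsh threshold | 15 | 30 | 45 | mm / season |
| optimum | 220 | 110 | 160 | mm / season |
| sediment tolerance | 2 | 5 | 8 | slabs / season |
| burn probability | 0.35 | 0.70 | 0.15 | – |
| palatability | 1.0 | 0.05 | 0 | – |

Two orderings matter and are deliberate:

- **Harsh thresholds** grass < shrub < tree: drought kills trees first,
  grasses last, producing the wet-to-dry site gradient (tree savanna →
  grass-dominated steppe).
- **Optima** grass > tree > shrub: C4 grasses keep converting extra
  summer rain into growth where woody growth has saturated. This is
  what makes the grass:shrub ratio increase monotonically along a DJF
  rainfall ramp — with grass optimum below the shrub optimum both
  species saturate below realistic wet-season totals and the ramp
  response disappears (we verified this variant and rejected it).
- **Burn probabilities** shrub > grass > tree: fire here removes
  individuals outright, so the probabilities encode net demographic
  fire mortality — perennial grass tussocks resprout (low net kill),
  shrubs suffer topkill, mature trees resist. An early variant with
  grass most likely to burn inverted the fire gradient (more fire →
  shrub encroachment) and was rejected.

Mortality: p = p₀ + (1 − p₀)·m̄^γ with m̄ the weighted mean of the seven
stress components, weights (0.15 neighbourhood, 0.30 precipitation,
0.15 biomass, 0.15 age, 0.10 sediment, 0.075 grazing, 0.075 fire),
p₀ = 0.01/season, γ = 3. The power form was chosen over a logistic
squash because it is exactly p₀ at zero stress, exactly 1 at full
stress, monotone, and keeps routine dry-season stress from producing
implausible background mortality. Age stress ramps linearly over the
last quartile of the species lifespan.

Neighbourhood interaction: signed shell sums over Chebyshev rings 1–5
with weights (+1.0, +0.5, −0.4, −0.6, −0.8)/ring-size on relative
neighbour biomass (facilitation close, competition far), squashed by a
logistic with gain 2 so an empty neighbourhood gives the neutral
stress 0.5.

Recruitment: P(establish) = 0.4 · max-species moisture response ·
(1 + 0.5·facilitation), requiring a positive moisture response.
Species choice uses the pioneer prior (0.75, 0.20, 0.05) on bare or
freshly burned ground and biomass-weighted neighbour copying
(shells 1–2, ε = 0.05 pseudo-count, still multiplied by the prior)
elsewhere. Biomass weighting is the mechanism behind grazing-driven
shrub encroachment: defoliated grass seeds weakly, intact shrubs win
vacated cells.

Grazing intake is 2 × 10⁵ growth units per LSU per season — calibrated
once so the 0.06 LSU ha⁻¹ stocking rate visibly suppresses grass on the
reference lattice; fires occur in SON, the late dry season. A burned
cell's fire flag acts in the same season's recruitment (bare-ground
prior) and echoes at half strength into the next season's stress
vector.

## Wind and transport parameters

- Recovery length L = c·h·(1 − porosity), c = 7 (heights-to-recovery
  scale of the wake literature). Residual in-wake velocity factor at
  the element = its porosity (a fully porous element casts no wake).
  Corridors are one cell wide by default (crown ≈ cell), rasterised
  along the nearest of 16 compass bearings with Chebyshev/Bresenham
  steps; overlapping wakes combine by **minimum** (strongest shelter
  wins; a product rule is switchable).
- Exponential recovery reaches 0.99 at one recovery length; the tree
  profile is a logistic (steepness 10) renormalised to the same
  endpoints, giving the slow initial rise of a tall-canopy wake.
- Topographic compression: u × (1 + 0.5·tan(upwind slope)), capped at
  1.5.
- Flux: q(u) = A·(u − 5.1)·u² slabs per cell per event, A = 1/((10 −
  5.1)·10²) so a 10 m s⁻¹ wind over bare sand moves ~1 slab — only
  relative transport matters for the normalised landscape statistics,
  so the event duration is absorbed into A. Fractional slab counts are
  realised by stochastic rounding.
- Erosion/deposition probabilities: p_e = 1 on bare sandy cells,
  × 0.3 under vegetation (the Bernoulli draw precedes the volume
  computation); p_d = 0.6 bare, 1.0 vegetated or shadowed; hop length
  one cell along the straight downwind ray.
- Shadow zones: a lee line descending at 15° is propagated downwind one
  step at a time (S ← max(surface, S − step·tan 15°)); a cell is
  shadowed when the line lies strictly above its surface.
- Avalanching: steepest-descent single-slab moves among 8-neighbours
  whenever surface slope exceeds tan(30°) at bare or tan(40°) at
  vegetated source cells, with seeded random tie-breaks, iterated to
  convergence (guarded at 10⁵ sweeps). Only sand moves; substrate is
  immobile.

## Synthetic climate generator

The generator emulates the statistical structure the experiments need,
not any real station record:

- Seasonal totals = site baseline + linear trend·(year − start) +
  N(0, σ_season), truncated at zero (not resampled; bias is negligible
  at the σ/mean ratios used). σ_season = σ_annual/2 so four independent
  seasonal deviates recompose the annual-equivalent variance; the two
  stationary variability regimes are σ_annual = 30 mm (low) and 160 mm
  (high).
- Transient realisations perturb a trajectory with σ(t) from centred
  5-year moving seasonal standard deviations (ddof = 1, edges shrink to
  a 2-year minimum) of the trajectory itself.
- Three site presets (maun / tshane / tsabong) span a wetness gradient
  with mild drying trends; their numbers are declared fixtures.
- Wind: seasonal Weibull (shape ~2, scale 4.8–6.5 m s⁻¹, windiest in
  SON) and a 16-bin, northerly-dominated direction table; sampled
  directions are bin centres.

What it does **not** emulate: spatial rainfall structure (forcing is
domain-uniform), within-season event timing, serial correlation of wet
and dry years, wind speed–direction dependence, or any covariance
between rainfall and wind. Passing tests therefore demonstrate the
mechanisms and their directional responses, not site-calibrated
predictions for real locations.

## Numerical and design choices

- All randomness flows from one integer seed through
  `SeedSequence`-keyed child generators keyed on (seed, year, season,
  stage, event), so skipping a stage (e.g. a calm event) cannot shift
  any other stream, and every entry point is bit-reproducible.
- The vegetation update draws exactly three uniform fields per season
  (mortality, establishment, species choice) in a fixed order.
- Grass:shrub ratio with zero shrubs is reported as +inf with a
  `ratio_defined=False` flag and excluded from means; the cover
  threshold analysis uses strict `<`.
- Equilibrium forcing for a key year is the per-season mean over the
  21-year window centred on it; fire/grazing matrices summarise the
  11-year windows centred on the key years.
- Calm events (speed × compression cap ≤ threshold) short-circuit the
  wind/transport pipeline; avalanching runs only after events that
  moved sand.
- Werner-convention ambiguities (corridor width, wake combination rule,
  erosion draw before volume) are resolved as above and switchable in
  config.

## Problem sizes

The shipped full-scale profile is 150 × 150 cells with 200-year
equilibrium runs and 10-member transient ensembles over 1960–2100. The
test suite and examples use the package's smoke scale — 11–50 cell
lattices and 3–20 model years, with the directional experiments
(rainfall ramp, porosity contrast, fire × grazing corners, zero-rain
collapse) at 50 × 50 with matched seeds — sizes chosen so the full
suite runs in about a minute while every mechanism is still exercised
at meaningful amplitude.

## Known limitations

- No fire-front propagation or herbivore agents (fire is domain-wide
  probabilistic, grazing spatially averaged).
- No seed-dispersal kernels, CO₂ effects, or soil-moisture store; the
  moisture response reads the current season's total only.
- No suspension/dust, grain-size classes or crusting in transport; no
  turbulence or lateral wake spreading in the wind field.
- Lattice anisotropy: corridors and shadows are rasterised on 16
  bearings; rotation symmetry is exact only for cardinal/diagonal
  directions.
- The ecological parameterisation is a declared reference stand-in;
  absolute statistics (e.g. the intake constant, flux coefficient) are
  only meaningful relative to it.
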