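# Methods

## Model structure and assumptions

The marsh is a zero-dimensional column of annual soil cohorts, newest at
the surface. Each cohort carries four mass pools per unit area (g/cm²):
mineral sediment, labile organic matter, refractory organic matter, and
live roots. There is no horizontal transport, channel or scarp
dynamics, or storm forcing: the model represents the marsh-plain
interior, where dated cores are collected, on an annual time step.

Elevation is the running sum of cohort thicknesses referenced to local
MSL. Each model year executes, in order: (1) mineral deposition at the
current elevation (a new surface cohort; net-erosive years strip mass
from the top of the column instead), (2) vegetation cover update and
organic production, with last year's live roots dying into the dead
pools, surface litter entering the new cohort, and belowground input
distributed down the root profile, (3) decomposition of every cohort's
labile pool, and (4) the elevation budget
ΔE = MAR + OAR − DECOMP − SLR. The three volume terms are measured as
total-thickness differences across steps (1)–(3), so the budget closes
exactly by telescoping; the tests assert closure to 1e-9 cm over
century runs.

### Soil volume and compaction

Bulk density of the mineral + dead-organic mixture follows the ideal
two-component mixing model ρ = 1/(o/k₁ + (1−o)/k₂) with k₁ = 0.0823 and
k₂ = 1.876 g/cm³ (organic and mineral self-packing densities,
calibrated values; `fit_mixing_model` re-estimates them from interval
core data by linear least squares on 1/ρ). Decomposition therefore
shrinks cohorts — compaction is emergent, not imposed. Live roots are
excluded from the mixing model and occupy volume at their own packing
density of 0.2 g/cm³.

### Live roots

The live-root pool is the standing stock of the current year's
belowground production; it turns over completely each year into the
labile/refractory split. Two alternative readings were rejected after
numerical analysis: refreshing a standing stock at 0.2 g/cm³ × cohort
thickness and releasing its decrease into the dead pools creates a
positive feedback in organic soils (released mass → thickness → larger
root target; gain 0.2/ρ(o) exceeds 1 for o near 1) that drives runaway
peat growth, and turning such a stock over wholesale would inject an
order of magnitude more organic matter than dated cores record. Because
the productivity polynomials predict *total* dry biomass, root
mortality is already part of the production input, and the standing
stock must not be double-counted.

### Decomposition

Labile mass decays annually by the fraction A(age)·exp(−k·d) at cohort
mid-depth d, with age classes 1 (deposited this year), 2 (last year),
and 3+ (older); k = 0.05 /cm. Mid-depth is used because annual layers
are thin, making the choice of evaluation point nearly unbiased.
Mineral and refractory pools never decompose; refractory mass is
conserved, which the property tests assert.

### Tides and mineral deposition

One year of 15-minute water levels is reconstructed from the eight
largest tidal constituents and rescaled so the realized MHHW−MLLW
matches the site tide range (exact in one step, because all datums are
homogeneous in the water level). Datums are computed from high/low-water
extrema: MHHW/MLLW as the means of daily higher-highs and lower-lows,
MTL as (MHW + MLW)/2.

Bed shear stress is τ₀ = λγ|U| with U = nD/λ, where n is the
water-level rate of change (m/s) from successive 15-minute samples and
D the depth; λ = (8/3π)·U₀/K² with U₀ = 0.2 m/s and K = 10 m^½/s. Note
λ cancels, so τ₀ = γ|n|D with γ = 9807 N/m³; the magnitude of n is used
since stress does not depend on flow direction. Settling
(w_s = 1e-4 m/s) switches off above τ_d = 0.1 N/m², erosion
(Q_e0 = 3e-4/2600 kg m⁻² s⁻¹ per unit excess stress ratio) switches on
above τ_e = 0.4 N/m². On ebb steps the suspended concentration decays
by explicit Euler of D·dC/dt = −w_s·C (factor floored at zero); it
resets to the ambient value whenever flood resumes or the surface
rewets. Dry steps carry no flux.

Annual deposition is tabulated once per tide realization on an
elevation grid as a settling column at C = 1 mg/L plus a
concentration-independent erosion column, so
MAR(z, C₀) = C₀·settle(z) − erode(z) holds to machine precision — the
identity the sediment calibration inverts, and the reason the tabulated
model is exactly as accurate as a direct run. Tide-range amplification
under SLR (0.024–0.061 cm per cm of SLR, site-specific) is handled by
caching tables at a few scale factors and interpolating linearly
between them.

### Vegetation

Cover evolves as dP_i/dt = P_i·r1_i·(1 − ΣP)·S_i(z): logistic growth
scaled by elevation suitability under one shared carrying capacity; no
explicit competition coefficients, since field-derived suitability
already folds in biotic limits. Where S_i = 0, cover decays at rate
r1_i; a seeding floor of 1e-3 lets species colonize newly suitable
ground. The ODE is integrated with four midpoint (RK2) sub-steps per
year, which keeps the logistic within 1% of a high-order reference up
to r1 ≈ 2 /yr, clamped to the cover invariants. Production is the
cover-weighted sum of clamped second-order polynomials in percent time
inundated; salinization multiplies it by (1 − 0.027·ΔPSU), floored at
zero. The surface is classed as mudflat when total cover is below 20%
(strictly; exactly 20% counts as vegetated).

Root:shoot = 0.05 partitions gross production: the belowground fraction
rs/(1+rs) goes down the exponential root profile (decay r₂ = 0.1 /cm,
root zone 30 cm — r₂ is a config parameter with no published value; the
default gives a 10-cm e-folding typical of marsh rooting depths), the
remainder enters the surface cohort as litter.

### Calibration

Core MAR and OAR integrate (1−o)·ρ and o·ρ over the depth accreted in
50 years at the core's dated rate. The ambient concentration is solved
in one step from the MAR linearity along the prescribed 100-year track
(surface rising at the dated rate, MSL following the quadratic
hindcast): C₀ = (MAR_core + ⟨erode⟩)/⟨settle⟩. The organic scaler is
fitted by running the full forward model from the core's 100-yr-ago
elevation and matching mean net organic accumulation over the last 50
years to the core OAR. Modeled net OAR rises with the scaler only until
the marsh outgrows its vegetation band, so the mismatch can vanish at
two scalers; the fit therefore brackets the *first* upward crossing on
a geometric grid and refines it by bisection (Brent, xtol 1e-3), which
selects the physical branch. Non-bracketing data raise a diagnostic
error.

### Scenario engine

Spin-up bisects the constant SLR rate on [0, 20] mm/yr over 200-year
runs until the final elevation matches the start within 0.1 cm (≤60
iterations; non-bracketing configurations return the boundary rate with
a warning). The low/intermediate-low SLR curves are linear to their
2016–2100 totals (29, 39 cm → 3.4, 4.6 mm/yr); the mid/high curves are
quadratics anchored at the historic 2.1 mm/yr initial rate and
constrained to the printed totals (99, 167 cm), since only the totals
and their non-linearity are published — any per-year curve can be
supplied instead. Sediment futures: historic C₀, constant 0.6·C₀,
declining 0.6·C₀·(1−0.016)^t, increasing 1.25·C₀. Interannual sea
level adds a 2-cm nodal sinusoid (18.6 yr) and ENSO years drawn
Bernoulli(1/4) with random sign ±5 cm — the draw law is a package
choice; only the amplitude and mean return interval are published.

Monte Carlo draws each uncertain parameter (C₀, organic scaler, the
three decomposition A values, salinity penalty ω) *uniformly* within
±1 SD of its mean, reading "randomly selected within one SD" literally;
the sea-level forcing realization is shared across draws so ensemble
spread isolates parameter uncertainty, and a zero-SD ensemble collapses
bitwise onto the deterministic run. The threshold sweep runs constant
rates of 1–10 mm/yr for 300 years from a common spin-up; the threshold
is the smallest rate whose end state is mudflat. DEM projection
interpolates per-initial-elevation trajectories linearly across the
raster (grid −0.5–2.0 m by 0.1 m plus 2.5–5.0 m by 0.5 m by default);
pixels outside the grid are masked and counted.

## Synthetic data

`tidalmarsh.synth` emulates every input the pipeline needs. Site
presets carry the published constants for three San Francisco Bay
estuary marshes (MSL, tide range, calibrated SSC mean±SD, decomposition
A triples, refractory fractions, root:shoot, tide amplification rates).
The five species' suitability spans and productivity polynomials are
package fixtures — the published curves exist only as figures — chosen
so that zonation sits in the intertidal frame (upper limits near MHHW)
and so that net organic retention at full cover lands near the
100–200 g m⁻² yr⁻¹ that dated cores record; the per-species `o_scale`
of 0.15 is the biomass-to-soil-organic-input conversion that achieves
this, leaving the site-level calibration scaler a neutral multiplier
near 1.

Synthetic cores are produced by the forward model itself: the marsh is
spun up, sited at its dynamic-equilibrium elevation for the mean
historic SLR rate (as long-established marshes are), run 150 years
under the MSL hindcast with known (C_true, scaler_true), discretized to
2-cm intervals, and given 5% multiplicative lognormal noise on bulk
density and organic fraction. Equilibrium siting matters: a marsh in
transient climb violates the steady-accretion assumption inside the
calibration identity and biases recovery by tens of percent. Surveys
draw presence Bernoulli(S(z)) at uniform random plot elevations; DEMs
are smoothed Gaussian random fields rescaled to a target hypsometry
with a nodata ring.

What passing tests therefore show: the calibration recovers parameters
from data *generated by the same process it assumes* (well-posed
round-trip identification), and the coupled dynamics reproduce the
qualitative behaviors expected of real marshes (equilibrium rates of
~1–6 mm/yr, drowning thresholds of ~5–9 mm/yr, carbon accumulation
rising with SLR rate until collapse). They do not show that the fixture
productivity curves, the deposition magnitudes, or the noise structure
match any real site; with real cores, surveys, and gauge constituents
the same code path applies unchanged.

## Numerical choices and problem sizes

- Units: cm, g/cm², g/cm³ internally; g m⁻² yr⁻¹ only at reporting.
- Cohorts below 1e-12 g/cm² total mass are pruned.
- Elevation/deposition tables use a 5-cm elevation grid from −2 to
  5.5 m; calibration results shift by <1% under a 2.5-cm grid.
- The test suite and acceptance script size simulations to run in a few
  minutes on one core: spin-up contracts are checked at five initial
  elevations, Monte Carlo behavior at n = 100 with 12-member
  reproducibility variants in unit tests, DEM projection on ~10³–10⁴
  pixel synthetic rasters.

## Known limitations

- The shear-stress formulation is used literally as published; its
  dimensional bookkeeping (γ in specific-weight units times a velocity)
  is validated behaviorally (branch switching, magnitudes spanning the
  τ_d/τ_e thresholds at marsh-plain depths), not derived from first
  principles.
- Negative annual mineral balances erode the surface cohorts
  proportionally; there is no bed-armoring or consolidation memory.
- The sediment calibration inherits the steady-accretion assumption of
  its 100-year track; for strongly transient marshes the recovered C₀
  is biased (the synthetic generator documents and avoids this regime).
- Salinity affects only production, linearly; long salinization ramps
  extrapolate beyond the fitted range.
- No storms, no spatial sediment routing, no upland land-use dynamics.
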