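# Methods

## Scope and model

trawlkit standardizes bottom-trawl survey catches to swept-area densities
and fuses fleet VMS pings with daily landings into gridded effort maps. The
underlying model is the classic swept-area method: a haul sweeps
`SD × GW / 1000` km² of seabed (`SD` swept distance in km along the cut GPS
track, `GW` gear width in m), and every measured quantity is raised to the
whole catch and divided by that area.

Raising uses two factors. `SP = fraction_weight / subsample_weight ≥ 1`
scales the measured subsample up to the whole sorted fraction; `DP` does
the same for the sorted subsample of the discard fraction and is fixed at 1
for landed catch, natural debris and marine litter. Both are raising
factors (multipliers ≥ 1), not proportions: the standardization equations
multiply counts and weights by them, which only balances dimensionally for
a total/subsample ratio.

Group aggregates divide the sum of per-sample values by the number of hauls
`N` in the group, not by the number of samples `NS`. With landed and
discarded fractions per haul, `NS ≈ 2N`, and the within-haul fractions are
effectively summed before averaging across hauls. A species absent from a
haul contributes zero to the sum but the haul still counts in `N`, so
aggregates are averages over sampling effort, not over presences.

## Length–weight relationship

Field individuals carry length only; laboratory individuals are weighed.
The conversion `W[g] = a·L[cm]^b` is calibrated per species by ordinary
least squares on `log W = log a + b·log L`. The back-transformed `a` is the
geometric-mean calibration (no smearing correction): the residual scatter
used downstream is the log-scale residual SD, which also drives the
length–weight outlier QC rule (flag when |log-residual| > k·SD, default
k = 3, with a 1e-9 absolute floor so exact fits never flag rounding noise).
Weights are carried in grams because the length–weight literature reports
`a` for gram/cm calibrations; biomass converts to kg at the end.

## Geometry

Distances use the haversine formula on a sphere of radius 6371.0 km; at
haul scale (km) the difference from an ellipsoidal geodesic is far below
GPS noise. The haul is cut from the GPX track by inclusive timestamp
filtering against the first/last onboard position; no boundary snapping or
interpolation, so cutting is deterministic and idempotent. Multiple GPX
segments are concatenated; inter-point gaps over 10 min log a warning.

## Length classes

Bin widths are 1 cm for fish and cephalopods and 0.5 cm for crustaceans
(whose measured carapace lengths span only a few cm), configurable per
taxon group. Bins are half-open `[m·w, (m+1)·w)` with a 1e-12 relative
guard so values on a boundary land in the upper bin regardless of float
representation.

## VMS pipeline

Trips are one vessel-day (local calendar date, default Europe/Madrid),
because landings are reported daily. Each trip's ping series is densified
to a 10-min mesh anchored at the trip's first ping — anchoring at the ping
rather than at the wall clock makes the operation idempotent and
independent of the trip's start time. Positions are interpolated linearly
in (lat, lon); over ≤ 2-h segments at trawling latitudes the deviation from
a great-circle segment is negligible. Interpolated pings get their speed
recomputed as mesh-segment distance over duration, in knots.

Fishing classification is a conjunction of a speed filter (default
[1.0, 4.5] kn — a convention for otter trawling, configurable) and a depth
filter (default [50, 1000] m, the legal trawling band of the emulated
shelf). Bathymetry is supplied as a callback; missing depths mark the ping
not fishing and are logged. Fishing time is 10 min per fishing ping; trips
exceeding the 12-h daily legal limit are warned about, never truncated.

Each day's landed kg and € per species are split equally over that day's
fishing pings. Trips with landings but no fishing pings are reported as
unallocated and excluded from the maps, so conservation statements apply to
allocatable landings. Rasterization uses a local equirectangular km
projection centred on the grid's mid-latitude (adequate over the ~100-km
extent of a regional fishery; a proper projected CRS can be substituted by
reprojecting inputs); default cell size 1 km. Revenue per unit effort per
cell is Σ€ / (Σh × cell area), matching the €/(h·km²) unit; cells without
effort are masked NaN.

## Synthetic data generator

The simulator emulates the monitoring design: per survey vessel-day, one
haul in each of three depth strata; a 60-min tow at 3 kn with 4° heading
noise per minute, GPS at 1-min cadence, onboard fixes every 15 min; catch
per species drawn Poisson in (true stratum density × swept area), lognormal
lengths clipped to the species' valid range, weights `a·L^b` times
lognormal noise (SD 0.05); catches over 120 individuals per fraction are
subsampled (weight-based SP), 30% of measured individuals are "laboratory"
weighed. The fleet side emits one steaming ping out, four fishing pings
towing along-shore, one steaming home, at the 2-h VMS cadence, with gamma
landings per species priced at fixed €/kg.

Geography is a synthetic shelf: an east–west coast at 41° N with depth
increasing linearly at 15 m/km offshore. That gives a closed-form
bathymetry and land polygon shared by the simulator and the VMS stage.

Five default species span the taxon groups (hake, red mullet, two
deep-water shrimps — one with the 2-cm Mediterranean MCRS — and octopus)
with literature-range allometric parameters and per-stratum densities of
0–900 indiv/km², typical of NW Mediterranean trawl grounds.

What the simulator does not emulate: movement ecology, tide/current track
distortion, seasonality beyond the haul date, size-selective gear
retention, price dynamics, misreported landings. Passing tests therefore
show the computation chain is correct and conservative, not that the
filters' default bounds are optimal for any real fleet.

One `numpy.random.SeedSequence` stream per entity (haul, fleet-day) is
spawned from the master seed, so enlarging the fleet or the campaign does
not perturb existing draws, and the same seed reproduces the output
byte-for-byte.

## Numerical choices

- Swept-area consistency on `Haul` is enforced to 1e-9 absolute.
- Composition trees sum upward exactly (float addition in fixed, sorted
  order); serialized artifacts round to 6 significant digits and are
  byte-identical across rebuilds.
- Aggregations use pandas group sums; equality with a pure-Python oracle is
  asserted to 1e-9 relative in the tests to bound summation-order effects.
- QC severity policy: range and MCRS violations are warnings (true extremes
  exist); referential breaks, missing tracks and impossible weights are
  errors. QC never mutates data.

## Problem sizes

Default test and acceptance runs use campaigns of 9–36 hauls, ~1000–4000
measured individuals, and fleets of 20–30 vessel-days (~120 reported /
~2500 interpolated pings), chosen so that every statistical check
(parameter recovery at n = 500 pairs, density recovery across strata,
classification recovery over 120 labeled pings) has enough data to be
stable at fixed seeds while the full suite runs in seconds.

## Known limitations

- The equirectangular grid distorts cell areas by < 0.5% over a 100-km
  north–south extent; fine for maps, not for legal-boundary work.
- Equal splitting of landings over fishing pings is the standard fusion
  heuristic; it ignores within-day catch dynamics.
- The log-log OLS `a` is biased low under lognormal noise by the usual
  `exp(σ²/2)` factor (~0.1% at SD 0.05); no smearing correction is applied.
- The CLI loads whole campaigns into memory; it targets survey-scale data
  (10⁵–10⁶ individuals), not fleet-wide VMS archives spanning decades.
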