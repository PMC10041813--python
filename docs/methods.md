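# Methods

## Problem and scope

The package estimates, for a county-scale health system on a planar grid,
(i) travel time from every populated location to the nearest hospital able
to transfuse blood, (ii) a demand- and supply-aware spatial accessibility
index per enumeration area (EA), (iii) a competition (attractiveness) index
per transfusing hospital, and (iv) the statistical association between that
index and the hospitals' blood-unit volumes. All coordinates are projected
planar metres; no geographic (degree) computations are performed anywhere,
which is adequate at county scale and keeps the shortest-path metric simple.

## Travel-cost surface

The friction surface is a single class grid assembled by priority stacking:
vector roads and travel barriers are rasterised onto the land-cover grid,
with **roads > barriers > land cover** per cell — a road crossing a river is
a bridge and remains traversable, a river or protected-area cell without a
road is impassable (speed exactly 0). When several roads share a cell the
fastest class is burned. Lines are burned into every cell whose centre lies
within half a cell of the line; polygons into every cell whose centre they
contain.

A travel scenario maps each class to a mode and speed. The shipped defaults
are documented placeholders in the ranges used by comparable accessibility
studies, fully overridable through the config:

| class | mode | km/h |
|---|---|---|
| wetland | walking | 1 |
| tree cover, shrubland | walking | 2 |
| grassland, bare, built-up | walking | 4 |
| rural / settlement road | motorcycle | 20 |
| government road | motorcycle | 25 |
| minor road | motorcycle | 30 |
| secondary road | vehicle | 50 |
| primary road | vehicle | 65 |
| national road | vehicle | 80 |

Walking speed is slope-corrected with Tobler's hiking function normalised to
the base speed: moving from cell a to b with rise-over-run s, the factor is
exp(−3.5·|s + 0.05|)/exp(−3.5·0.05), equal to 1 on flat ground, peaked at a
gentle downhill, strictly decreasing in |s + 0.05|. Motorised modes ignore
slope — an adopted convention (anisotropic walking only), recorded here
because the alternative (slope-corrected driving) is also defensible.

## Least-cost travel time

Cells are nodes of an 8-connected graph (diagonal distance √2·cell).
The directed edge time a→b is the centre-to-centre distance times the mean
of the two cells' time-per-metre, slope-corrected per endpoint cell when
that cell's mode is walking. Times to the nearest facility are exact
multi-source Dijkstra distances (sparse-graph implementation), computed on
the transposed graph so that asymmetric walking edges are traversed in the
direction of travel toward the facility. Unreachable cells are nodata in
rasters and +inf in matrices, and count as marginalised in zonal statistics.
Grid registration: cell-centre coordinates, half-open pixel membership,
row 0 northmost.

The EA-by-facility matrix runs one single-origin accumulation per facility
and samples it at EA centroids; the joint surface equals the elementwise
minimum of the single-facility surfaces (asserted in tests), so both views
are exposed.

## 3-SFCA accessibility

Gaussian decay f(t) = exp(−t²/β) with a hard cutoff beyond T_max = 60 min
(the emergency-transfusion threshold). β defaults to T_max²/ln 100 ≈ 781.73
min², a transparent calibration making the weight at the catchment edge
exactly 0.01; it is configurable because the value used in the original
analysis is not recoverable. The three steps are

1. G_ij = W_ij / Σ_{j: T_ij ≤ T_max} W_ij (selection probability),
2. R_j = S_j / Σ_{i: T_ij ≤ T_max} G_ij P_i W_ij (supply–demand ratio),
3. SPAI_i = Σ_{T_ij ≤ T_max} G_ij R_j W_ij,

with demand P_i the EA population and supply S_j the hospital's total
inpatient admissions over the reporting window. The decay weight W enters
once in W itself and once through the G normalisation; "accounting for
alternatives" lives entirely in G. EAs with no facility in reach get an
all-zero G row and SPAI 0, reported in a no-access list; facilities with no
weighted demand get an undefined (NaN) R excluded downstream — never NaN
propagation or division by zero.

**Conservation.** Σ_i P_i·SPAI_i = Σ_j S_j over facilities with defined R,
algebraically exact and verified to ~1e-16 relative in tests.

**Monotonicity.** Raising any S_j weakly raises every SPAI (R_j is linear
in S_j with everything else fixed). Raising a single T_ij does *not*
necessarily lower SPAI_i: it also shrinks EA i's contribution to R_j's
denominator, and the induced rise in R_j can dominate. This is a real
property of the three-step scheme, not an implementation artefact, so the
test suite does not assert travel-time monotonicity.

Classification: fixed thresholds ≤ 0.5 low, (0.5, 1.5] moderate, > 1.5 high
by default (the boundaries under which the published EA counts were
reported); a quantile mode splitting at the empirical 40th/80th percentiles
(five quintiles collapsed 2-2-1) is provided for sensitivity, with constant
input degrading to all-moderate plus a warning. Marginalisation is reported
under both definitions — persons beyond the 1-hour catchment and persons in
low-SPAI EAs — with per-sub-county differences and ratios, because the
index definition generally flags more people than travel time alone
(travel time ignores congestion of supply).

## Spatial competition

Within each transfusing hospital's 1-hour catchment: n_i low-level
(level-3/4, non-transfusing) facilities and k_i alternative transfusing
hospitals; dispensaries (level 2) are excluded from the analysis entirely.
Bed weight W_i = beds_i/Σbeds. The printed index formula
SCI_i = (1/n_i)·Σ^{n_i} (1/k_i)·W_i has a summand that does not vary with
the summation index, so the default evaluation is the collapsed form
W_i/max(k_i, 1), with divisor 1 for a monopoly (k_i = 0) and a warning when
n_i = 0. A `per_low_level` variant evaluates k per served low-level
facility l (k_l = transfusing hospitals reaching l) and averages W_i/k_l
over l — the only reading under which the 1/n average is meaningful.
Neither reading is asserted as the original one; the packaged hospital
table's SCI column is treated as given data, not a recomputation target,
because no simple variant reproduces it exactly.

Market share defaults to the transfused-units basis (received and
received+transfused are available); the published share column matches none
of these bases, so it too is carried as given data.

## Validation statistics

Pearson's r by the product-moment formula; t = r√(n−2)/√(1−r²) on n−2
degrees of freedom with a two-sided p; confidence interval
tanh(atanh r ± z/√(n−3)). Q–Q diagnostics use plotting positions
(i − 0.5)/n against standard-normal quantiles. Coverage of the Fisher
interval at ρ = 0.7, n = 15 is verified by simulation (93–97% over 1,000
replicates, fixed seed).

On the packaged 15-hospital table the full-precision computation gives
r = 0.730 (received) and r = 0.737 (transfused), both p ≈ 0.002. These are
computed from the table's 2-decimal SCI column; with indices that small
(0.01–0.21), printing precision alone shifts r by a few hundredths, which
is why the values reported alongside the original table (0.70 / 0.71)
cannot be recovered exactly from the printed numbers. The sign,
significance and magnitude of the association are unaffected.

## Synthetic county generator

The generator emulates the study setting, deterministically from a seed:

- **Extent.** 280×280 cells of 300 m (≈ 84 km across). The original
  analysis ran at 10 m; 300 m keeps a full county run around a second while
  preserving the geometry that matters (towns more than an hour apart,
  walking-dominated interiors). 100 m and finer are supported.
- **Terrain.** A smooth random relief (≈ 1,200–2,100 m) plus one mountain
  massif (to ≈ 4,300 m) wrapped in a protected-area barrier; one river
  crosses the county.
- **Land cover.** Six classes (tree cover, shrubland, bare, grassland,
  built-up, wetland) assigned from smoothed random fields, elevation and
  the urban mask; all six are guaranteed present.
- **Roads.** Seven classes: one national trunk through the towns, primary/
  secondary spokes to the 12 sub-county seats, and minor/government/
  settlement/rural spurs to nearby EA seeds (~35 per sub-county).
- **Administrative units.** 1,400 EA seeds (denser in towns) label cells by
  nearest seed; sub-county membership follows the EA seed, so EAs nest
  exactly and both layers partition the county by construction. EA
  polygons are exact unions of member cells.
- **Population.** 1,734,900 persons distributed with a rural floor, strong
  concentration along roads (exponential in road distance, 1.8 km scale)
  and an urban boost — a dasymetric-style pattern without modelling any
  external population product. The generator reproduces the study-like
  regime: population-weighted mean travel time ≈ 29–39 min across seeds,
  80–90% within one hour.
- **Facilities.** 250 facilities, ~81% level-2 dispensaries (never
  transfusing), one level-4 referral. The 15 transfusing hospitals are
  placed on road cells (urban_fraction = 0.8 of them inside towns), with
  log-normal bed counts boosted 2.5× in towns; admissions are
  ≈ 150/bed-year over the 4-year window. Blood units received are
  blood_units_per_bed (default 15 per bed per window, matching the
  published table's ≈ 16,662 units / 1,112 beds) times beds times a
  log-normal noise exp(ε), ε ~ N(0, 0.5); units transfused are received
  times Uniform(1.0, 1.6) — more blood is transfused than issued centrally
  because of family replacement donors. This induces the positive
  size–volume association the validation step is meant to detect.

What the generator does **not** emulate: seasonal and traffic variation in
speeds, within-EA household placement (EA centroids stand in for homes),
referral behaviour, stock-outs, or any real road topology. Passing tests
therefore demonstrate correctness of the algorithms and the qualitative
regime, not calibration to any real county.

## Numerical choices

- Exact shortest paths (no heuristic); the test oracle is min-plus value
  iteration, validated against exhaustive simple-path enumeration on tiny
  grids.
- Supply conservation asserted at 1e-6 relative (observed ~1e-16).
- Market shares and bed weights asserted to sum to 100 and 1 at 1e-9.
- Class boundaries are closed on the left class (0.5 is low, 1.5 moderate).
- Zonal travel-time bands are half-open intervals (0, 30], (30, 60], (60, ∞),
  with non-finite times in the open band.
- Determinism: one `numpy` Generator seeded from the scenario; identical
  configs yield byte-identical artifacts (asserted in tests).

## Known limitations

- SCI and market-share formulas in the source material are ambiguous; both
  implemented readings are documented above and the packaged table's
  printed values are used as data.
- The decay friction β of the original run is unknown; SPAI magnitudes are
  therefore comparable only in distributional shape, not cell-for-cell.
- The per-low-level SCI variant needs facility-to-facility travel times
  for *all* level-3/4 facilities, which grows linearly in facilities; at
  desk scales this is negligible.
- Travel-time monotonicity in T_ij does not hold for 3-SFCA (see above);
  consumers ranking EAs by SPAI should be aware the index reflects
  congestion, not distance alone.
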