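# Methods

## Scope and model structure

`phosload` predicts annual mean total phosphorus (TP) concentrations in
standing waters from catchment attribute tables. The chain is:

1. **Local sources** (per sub-catchment): diffuse land export from an
   export-coefficient table; per-capita loads for the sewered and riparian
   septic populations; additive extra point sources.
2. **Water balance**: annual runoff = max(0, precip − AET) with
   AET = min(precip, PET); discharge = runoff × land area.
3. **Routing**: loads and discharge accumulate down the sub-catchment tree
   (a forest of directed trees; each node has at most one downstream link).
4. **Lake model**: the OECD empirical relation converts accumulated load
   and outflow into an in-lake concentration; retention truncates the load
   passed downstream.
5. **Classification**: WFD status from site breakpoints, trophic class,
   traffic light, and load headroom by exact model inversion.

GIS preprocessing (land-cover mapping, slope derivation from elevation
models, climate-grid interpolation, FAO56 PET, soil-hydrology classes) is
out of scope: the package consumes its results as CSV columns. PET is a
required input; an optional per-catchment `runoff_coeff` multiplier lets
users emulate soil effects on runoff.

## Parameters and defaults

| parameter | default | units | notes |
|---|---|---|---|
| export coefficients | packaged table | kg P/ha/yr | 18 categories × 3 slope bands × {min, median, max} |
| slope bands | 0–4, 4–13, 13+ | degrees | half-open, lower-inclusive |
| urban per-capita load | 0.9125 | kg P/person/yr | sewered population via treatment works |
| septic per-capita load | 0.25 | kg P/person/yr | riparian septic population only |
| OECD shallow preset | a=1.02, b=0.88 | – | mean depth ≤ threshold |
| OECD combined preset | a=1.55, b=0.82 | – | mean depth > threshold |
| depth threshold | 3.0 | m | boundary depth assigned to the shallow preset |
| trophic thresholds | 10, 20 | µg P/l | boundary values assigned to mesotrophic |
| traffic-light amber band | 0.10 | fraction | configurable; amber within 10% below the target boundary |

The median export coefficients are the published calibrated values. The
full min/max ranges were published only in an appendix that is not
packaged here; the table ships the two published range anchors (wetlands
0.02–0.15, applied to all slope rows of the slope-invariant wetland
category; grasslands on steep slopes 0.08–0.15) and **synthetic** ranges
min = median/1.5, max = median×1.5 elsewhere (zero-median categories keep
0/0), so sensitivity mode runs out of the box. Users with the real ranges
can drop in their own CSV via the `export_coefficients` config key.
Categories printed with a single coefficient (Water 0.135, Wetland 0.085,
Cliffs 0.045) are slope-invariant. Zero-coefficient categories are retained
so area accounting stays complete; parcels are allowed to cover less than
the catchment area and the unmapped remainder contributes no load.

## The lake model and its inversion

TP_in = L/Q × 10⁶ µg P/l (1 kg per 10³ m³ = 1000 µg/l), X = TP_in/(1+√τ),
TP_lake = a·X^b, τ = V/Q with V = surface area × mean depth when no
measured volume is supplied. The "a" coefficient is a multiplier in this
standard form. The relation is exactly invertible
(X = (TP_lake/a)^(1/b)), which the headroom and back-calculation functions
use; the round trip is tested to 1e-10 relative. At fixed hydrology the
model implies C = C₀·(L/L₀)^b, exposed as `scale_concentration` for quick
what-if arithmetic from a calibrated pair.

Numerical choices and degenerate inputs:

* mean depth exactly at the threshold takes the **shallow** preset;
* zero outflow is a distinguished no-flushing error for concentration
  requests (and an infinite residence-time sentinel in the hydrology
  layer); zero-volume lakes are rejected outright;
* the empirical relation with a > 1 can predict TP_lake > TP_in at very
  low inflow concentrations; predictions are reported unclipped and the
  retention fraction R = 1 − TP_lake/TP_in may then be negative;
* class boundaries are inclusive upward (a concentration exactly on a
  boundary keeps the better class); the same convention places trophic
  boundaries 10 and 20 µg/l in the mesotrophic class and makes a
  concentration exactly on the traffic-light target boundary amber.

## Routing and retention

Upstream load arrives as a single "upstream" apportionment component; the
local breakdown (land/urban/septic/extras) is kept per catchment. Default
`retention_mode="all_lakes"` applies the lake model at every standing
water, so upstream lakes trap P before passing load on
(exported = TP_lake × Q); `terminal_only` treats upstream lakes as
pass-through, in which case the outlet load is exactly the sum of all
local loads (tested as a mass-balance invariant, and against a brute-force
upstream-enumeration oracle on 200 random networks). No in-stream
attenuation is applied between catchments. A `wwtw_override` extra source
replaces the per-capita urban term, supporting catchments where the true
effluent routing is known (e.g. sewage pumped out of the catchment:
override 0).

## Synthetic data

`generate_network` emulates the range of catchment typologies the model is
used on: upland profiles (coarse grassland/bog/heather mixes, steep
slopes, ~2000 mm rainfall, sparse population), lowland agricultural
profiles (arable/improved grassland, gentle slopes, ~800 mm), urban
profiles (inflated populations), and a mixed blend. Networks are random
trees toward a single outlet; the outlet always carries a lake and a
configurable fraction of other nodes do too, with mean depths spanning the
3.0 m preset threshold. Generation is deterministic for a given
(n_nodes, seed, profile).

What the generator does **not** emulate: spatial structure (no geometry,
no autocorrelation between neighbouring catchments), measurement error in
climate or land cover, seasonal dynamics, internal/sediment P loading, and
realistic national frequency distributions of lake size. Passing property
tests on these networks therefore demonstrates the arithmetic and
invariants of the implementation, not predictive skill on real
catchments.

### Case-study fixtures

Six one-node fixtures encode documented worked examples (Heldale Water,
Loch of Skene, Loch Leven, Lake of Menteith, Strathclyde Loch, Milton
Loch). The published material prints each site's baseline load and/or
modelled concentration but not its hydrology, so each fixture back-solves
the unique outflow Q at which the lake model maps the printed load to the
printed concentration (Brent root-finding on a strictly monotone
function), then derives a consistent precipitation from Q and a fixed
PET of 450 mm/yr. Load compositions not printed (Skene's spurious sewage
term, Strathclyde's corrected treatment-works discharge, Milton's septic
term, Leven's source mix) are back-solved from the printed before/after
concentration pairs under the site's preset exponent. Lake morphometries
use plausible real-world values with mean depths on the correct side of
the 3.0 m threshold. Breakpoint ladders are synthetic, chosen so the
printed concentrations fall in their printed status classes. All of this
is deterministic and labelled synthetic in the fixture notes.

## Sensitivity procedures

Three one-at-a-time drivers re-run the full pipeline: (1) the three
export-coefficient columns, summarised as lowest/mean/highest lake
concentration per setting and each setting's percentage ratio to the
median run; (2) discharge scaled by ±10% in 5% steps (concentration is
monotonically non-increasing in the discharge multiplier); (3) a generic
grid driver that perturbs one named parameter at a time and ranks
parameters by the largest absolute relative change in mean concentration.
Summary statistics fix the percentile estimator (linear interpolation
between order statistics), SD with the n−1 denominator, SE = SD/√n.
National-scale summary values require the national catchment dataset,
which is external; the package reproduces the procedure and report layout
and verifies them on synthetic networks. Problem sizes used in the test
suite and the acceptance script (networks of ≤ 20 nodes, 200 random
routing trials, the six one-node fixtures) were chosen as the smallest
sizes that exercise every code path.

## Known limitations

* Annual resolution only: no seasonality, storm events, or travel-time
  dynamics.
* No internal loading: lakes with significant sediment P release (as
  discussed for under-predicted sites) will be under-predicted; the model
  has no mechanism for it.
* Livestock are folded into the improved-grassland coefficient rather than
  modelled by headcount.
* P-stripping at treatment works is not represented except via an explicit
  `wwtw_override` load.
* The synthetic min/max coefficient ranges make sensitivity magnitudes
  indicative, not calibrated, until real ranges are supplied.
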