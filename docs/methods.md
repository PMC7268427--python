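# Methods

## The scenario model

Each dispatched suspected-stroke mission is evaluated under four mutually
exclusive transport strategies. All four share the measured first-ambulance
response time `r` (call handling to first unit on scene) and a fixed on-scene
interval; they differ in the transport leg and destination tier.

**Ground scenarios (S1, S2).**

    t = r + t_scene + (1 − ρ) · t_drive + t_unload

`t_drive` is the shortest normal driving time on the road network from the
scene's nearest node to the hospital's nearest node; ρ is the lights-and-siren
reduction. The destination is the hospital of the required tier (thrombolysis
for S1, thrombectomy for S2) with the minimal siren-adjusted drive; capability
tiers are nested, so every thrombectomy centre is also an eligible S1
destination — which guarantees `t1 ≤ t2` mission by mission.

**Helicopter scenarios (S3, S4).**

    t = max( r + t_scene , t_dispatch + t_enroute + t_fly(base→scene) )
        + t_fly(scene→dest) + t_unload

The `max` encodes the overlap assumption: the on-scene interval is the
patient's single scene phase (packaging, assessment), shared by ambulance and
helicopter, not additive per vehicle. Whichever of "patient ready" and
"helicopter on scene" happens later gates departure. S3 dispatches the
helicopter with the ambulance (`t_dispatch = 0`); S4 only after the crew's
primary evaluation (`t_dispatch = r + t_eval`). Because the S4 offset is
non-negative, `t3 ≤ t4` holds identically. The helicopter destination is the
thrombectomy centre nearest by great-circle flight time (which may differ from
the S2 road-nearest centre); the serving base is the nearest by great circle.

**Derived comparisons.** Per routable mission: `delay_increase = t2 − t1`,
`saved_s3 = t2 − t3`, `saved_s4 = t2 − t4`, and a fastest-method label per
dispatch mode; a strictly positive saving classifies the helicopter as
fastest, ties count as ground (conservative toward the cheaper modality).
When the helicopter is not the binding constraint the comparison collapses to
the closed form *helicopter fastest ⇔ ground leg > flight leg*, which the
break-even tests exploit.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `flight_speed_kmh` | 220 | km/h | cruise speed for all flight legs |
| `heli_dispatch_to_enroute_min` | 6 | min | crew alert to lift-off |
| `on_scene_min` | 26 | min | shared scene interval |
| `unload_min` | 10 | min | hospital door/helipad unload target |
| `siren_reduction` | 0.20 | — | emergency-driving time reduction |
| `include_unload` | true | — | charge unload in all four scenarios |
| `heli_base_leg` | true | — | charge the base→scene positioning flight |
| `s4_eval_min` | 10 | min | on-scene evaluation before the S4 dispatch |

Three of these are explicit modelling choices rather than measured
quantities, surfaced as toggles:

* **Base leg** (`heli_base_leg`): whether the helicopter must first fly from
  its base to the scene. The default charges it, with the nearest base by
  great circle; setting it false reproduces the minimal reading in which only
  the scene→hospital flight (plus the 6-min en-route delay) counts. Both
  readings are unit-tested.
* **S4 dispatch instant** (`s4_eval_min`): "after primary evaluation" is not
  a measured duration; 10 min after ambulance arrival is an assumption, kept
  configurable and recorded in the resolved run config.
* **Unload** (`include_unload`): unload time varies by hospital and helipad
  layout and good data are scarce. It is charged symmetrically in all four
  scenarios, so every between-scenario comparison (savings, fastest labels,
  break-even) is invariant to the toggle; only absolute totals move.

The siren reduction is applied to the whole door-to-door drive time rather
than per-edge speed inflation — numerically identical for a fixed path and
stated here for clarity.

## Routing and geodesy

The road network is an undirected weighted graph (edge weight
`length/speed·60` minutes); shortest paths use Dijkstra (networkx), with one
single-source pass per hospital cached and reused across missions, so 20k
missions evaluate in seconds. Unreachable scene–hospital pairs mark the
mission unroutable; unroutable missions are excluded from every summary and
counted in the inclusion log (`n_total = n_included + n_excluded`). Scenes
and hospitals snap to their nearest node by great-circle distance (ties to
the smallest node id; snaps beyond 2 km are logged); off-network access time
is taken as zero.

Great-circle distances use the haversine with the IUGG mean Earth radius
6371.0088 km; at the model's resolution (minutes at 220 km/h) the spherical
approximation is far below other uncertainties. Catchments are convex hulls
of the mission locations whose fastest road destination is the same hospital,
computed after an equirectangular projection centred on each point set —
membership is projection-invariant at national scale, and the projection is
recorded in the GeoJSON properties. Hulls with fewer than three distinct or
non-collinear points are flagged degenerate and skipped on export rather than
emitted as zero-area rings. No administrative clipping is applied.

## Statistics

"Median (95% CI)" columns are the 2.5th/97.5th percentiles of the per-mission
time distribution (type-7 linear-interpolation quantiles). Intervals that
wide over ~20k missions describe between-mission spread — reference
intervals — not the sampling uncertainty of a median, which would be
sub-minute at that n; a percentile-bootstrap CI of the median is available
behind `interval="bootstrap"` for the literal reading. "Helicopter faster"
means strictly positive saving. The break-even threshold is the midpoint of
the first ground-leg bin (default width 10 min) whose helicopter-fastest
fraction exceeds 0.5 with all later occupied bins at least 0.5; the plateau
rule prevents sparse noisy bins from producing a spurious early crossing.
The Total row is always recomputed from the pooled missions, never summed
from stratum rows.

## Synthetic region

The generator emulates one year of nationwide stroke-suspected dispatches in
a Nordic-scale country: a ~350,000 km² extent, 30 urban centres with
Zipf-like size weights, 20 thrombolysis hospitals of which the 5 largest
centres offer thrombectomy, 6 HEMS bases placed 8–20 km from the largest
centres, and 20,000 missions, 75 % drawn from truncated-Gaussian clusters
(σ = 5 km, capped at 2.5σ) at the centres and the rest uniform. The road
network is a spanning tree over centres (100 km/h trunk, winding factor 1.3)
plus 2-nearest-neighbour links, short 40 km/h urban spurs, and a coarse
80 km/h rural lattice — connected by construction. Response times are
log-normal per area class with medians ≈ 7/9/14/20 min from core urban to
other rural and heavier rural tails; the class-specific parameters are spec
inputs, re-estimable from generated data to within sampling error.

Area classes are assigned from the local mission density: a k-nearest-
neighbour density estimate (k = 10) relative to the uniform mean density
`n/area`, cut at fixed ratios 80 / 10 / 0.8. Fixed relative cuts (rather
than per-sample quantiles) make the classification meaningful for degenerate
mixtures — a fully clustered mission set contains no rural labels — and the
estimate is reliable only when clusters hold appreciably more than k
missions. Real classifications supplied in input files pass through
untouched.

What a green test on synthetic data establishes: the engine's arithmetic,
orderings and accounting, and the qualitative urban–rural gradients (rural
strata have longer ground times to thrombectomy and larger helicopter
benefit). What it does not: any country's actual magnitudes. In particular,
the synthetic world is kinder to the helicopter than a real one — bases sit
close to the largest centres, flight is never weather-limited, and urban
driving is slow relative to real arterial roads — so helicopter-fastest
fractions run higher than registry-based studies report. Not modelled:
turn restrictions and traffic, helicopter availability/queueing across
concurrent missions, rendezvous strategies, and secondary (drip-and-ship)
transfers.

## Numerical and reproducibility notes

* All randomness flows from the single `RegionSpec.seed` (region layout and
  missions use derived, independent streams); identical seed and config give
  byte-identical CSV/GeoJSON outputs.
* Ties — equidistant snap nodes, equal-time hospitals, equal base distances —
  break on the lexicographically smallest id, so runs are order-independent.
* Disconnected routing returns infinity (flagged) instead of raising; NaN
  time fields mark unroutable missions in the per-mission table.
* The vectorised batch evaluator is asserted against the scalar per-mission
  path in the test suite; both share the same tie-break rules.
* Degenerate inputs: empty mission lists yield empty tables; empty strata
  emit rows with `n = 0` and absent statistics; a break-even curve that never
  crosses 0.5 reports an absent threshold rather than extrapolating.
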