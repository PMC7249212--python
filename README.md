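# firevac

Fire-spread simulation coupled to fire-safe evacuation routing for animal
rescue, plus buffer-zone exposure analysis of farm registries. Everything
runs on synthetic, seeded landscapes — no external data downloads.

The pipeline has three computational stages:

1. **Fire spread** (`firevac.fire`) — a discrete-time Huygens-style
   perimeter propagation: front vertices advance along their outward
   normals at `ROS_max(fuel, humidity) × wind_factor × slope_factor`
   (both factors in [0, 1]), with polygon repair, ring merging and
   densification each step. Outputs perimeter snapshots (GeoJSON) and a
   per-cell fire arrival-time raster (ESRI ASCII grid).
2. **Evacuation routing** (`firevac.routing`) — a multi-criteria
   label-setting search on an oriented, traffic-weighted road graph under
   a time-dependent binary node-availability function derived from the
   arrival raster. The objective is the **fewest junctions visited**, with
   travel time and then accumulated traffic intensity as tie-breakers; a
   brute-force path enumerator provides independent reference semantics on
   small graphs. Infeasibility is a result, not an error.
3. **Exposure analysis** (`firevac.exposure`) — farms classified as
   directly involved (≤ 1 km of a fire footprint), indirectly involved
   (≤ 7 km, the maximum flight range of a bee swarm) or outside.

Supporting modules: `firevac.raster` (ESRI ASCII grid / GeoJSON / CSV I/O
with metric-CRS and alignment enforcement), `firevac.roads` (road graph,
traffic-speed statistics: time-mean, space-mean, 85th-percentile and modal
speed, and the traffic-intensity → travel-time mapping) and
`firevac.fixtures` (seeded synthetic landscapes, road graphs, farms and a
packaged end-to-end demo scenario).

## CLI

```sh
# generate a synthetic scenario directory
firevac gen-fixtures --seed 0 --out-dir fx

# fire simulation: perimeters.geojson + arrival.asc
firevac simulate --dem fx/dem.asc --fuel fx/fuel.asc --humidity fx/humidity.asc \
    --ignition fx/ignition.csv --dt 1 --horizon 60 --snapshot-every 5 --out-dir out

# fire-safe minimum-node evacuation plan
firevac route --graph fx/roads.geojson --arrival out/arrival.asc \
    --source g0_0 --sink g3_3 --horizon 60 --out-dir out

# farm exposure classification
firevac expose --farms fx/farms.csv --footprints out/perimeters.geojson --out-dir out

# the packaged end-to-end scenario (simulate -> route -> expose)
firevac demo --seed 0 --out-dir demo_out
```

Options can also be given in a YAML config (`--config run.yaml`); CLI
flags override config values. Outputs are never overwritten without
`--force`. Exit codes: 0 success (including an infeasible route), 2
configuration error, 3 data error.

## Conventions

- All coordinates are metres in one shared projected CRS; degree-unit
  grids are rejected. Rasters use the ESRI ASCII grid convention
  (row 0 = northernmost row; cell (row, col) maps to its centre).
- Wind directions are meteorological (degrees the wind blows FROM);
  speeds are m/h; times are minutes since ignition.
- The road graph is directed; two-way roads are two opposite edges.
- Distances exactly equal to an exposure radius classify inward (≤).
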