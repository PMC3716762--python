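# stemheat

A two-dimensional, physically based simulator of tree-stem heating and
tissue injury under fire. A horizontal stem slice is discretized on a polar
finite-volume grid (uniform angular wedges × uniform radial nodes) and the
heat-conduction equation is integrated with a Crank–Nicolson scheme, with:

- moisture-, density- and temperature-dependent thermophysical properties
  of wood and bark,
- prescribed fire heat-flux forcing per wedge plus net black-body radiant
  exchange with ambient air at the bark surface, periodic circumferential
  coupling and a no-flux center,
- Arrhenius desiccation (latent-heat sink) and bark charring (char front
  advancing at most one node per wedge per step),
- rate-process tissue viability integrated over each node's temperature
  history, yielding per-wedge necrotic depth and the surviving
  cross-sectional area fraction,
- a species-level calibration of the water-loss-rate parameter against
  reference probe-temperature/necrotic-depth observations, and
- virtual-experiment runners for circumferential heat redistribution
  (five cases × stem diameters) and slice height above ground
  (exponential flux–height profile, surface- and crown-fire styles).

A per-section species parameter table (eight eastern North American
species) ships as a fixture (`stemheat/data/species_params.csv`).

## CLI

```sh
# one simulation from a config file
stemheat simulate config.yaml --out run_output/

# circumferential redistribution experiment (cases 1-5 x diameters)
stemheat experiment --kind circumferential_case --species "Pinus strobus" \
    --case 1 --case 2 --out cases.csv

# height sweep (surface or crown fire profile)
stemheat experiment --kind height_profile --fire surface --out heights.csv

# water-loss-rate calibration against observations
stemheat calibrate obs.csv --metadata meta.json --species "Quercus rubra" \
    --forcing-csv forcing.csv --out fit.json
```

A minimal simulate config:

```yaml
geometry: {diameter: 0.14, outer_bark_thickness: 0.001,
           inner_bark_thickness: 0.002, n_wedges: 16, radial_spacing: 0.001}
species: {table_key: "Pinus strobus"}
run: {dt: 1.0, total_time: 960.0, output_every: 10.0}
forcing:
  synthetic_pulse: {peak_flux: 3.0e4, ramp_s: 60, hold_s: 300, cool_s: 600}
  # or: csv: forcing.csv   (columns time_s, T_ambient_K, flux_W_m2[_j])
  # optional circumferential redistribution: case: 3
```

Outputs: `trajectory.csv` (full field at the output cadence), `probes.csv`
(surface / sub-surface / cambium temperature series), `injury.csv`
(per-wedge necrotic depth) and `summary.json` (live-area percentage,
girdling flag, energy-balance residual). Runs are deterministic; the
energy-balance residual of every run is logged.

## Layout

| module                  | contents                                             |
|-------------------------|------------------------------------------------------|
| `stemheat.grid`         | polar finite-volume grid, wedge/bearing mapping      |
| `stemheat.properties`   | wood/bark thermophysics, species parameter table     |
| `stemheat.forcing`      | forcing series, generators, circumferential cases, height profile, CSV/XLSX I/O |
| `stemheat.sinks`        | desiccation and charring kinetics, char front        |
| `stemheat.solver`       | Crank–Nicolson stepping, boundary handling, runs     |
| `stemheat.injury`       | viability kinetics, necrotic depth, live area        |
| `stemheat.calibration`  | species error objective, water-loss-rate search      |
| `stemheat.experiments`  | virtual-experiment runners                           |
| `stemheat.verification` | explicit-Euler oracle, analytic benchmarks           |
| `stemheat.cli`          | `stemheat` command-line interface                    |
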