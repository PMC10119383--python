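# polychamber

Individual-based reaction–diffusion model of bacterial growth on a
polysaccharide in a flow-flushed microfluidic chamber, together with the
single-cell and batch statistical analyses that accompany such
experiments, and a synthetic-data layer that generates every input with
known ground truth.

The chamber is a 2D lattice (default 50×50 µm at 1 µm spacing). Three
concentration fields live on it — polymer `P`, secreted enzyme `E`, and
oligomer breakdown product `O` — with fixed concentrations at the flushed
boundary (polymer 0.1 mg/L, enzyme and oligomer 0). Cells occupy single
lattice sites, secrete enzyme in proportion to their biomass, and grow on
the local oligomer with Monod kinetics. Diffusion is advanced with an
unconditionally stable backward-Euler sparse solve; reactions are
explicit (operator splitting).

## Layout

| module | contents |
|---|---|
| `polychamber.lattice` | lattice/field types, implicit diffusion step, depolymerization step, dense steady-state oracle |
| `polychamber.agents` | cell placement, enzyme secretion, Monod uptake and growth |
| `polychamber.simulate` | chamber time loop, density×activity sweep, hindered-diffusivity sweep, reference configurations |
| `polychamber.chamber_stats` | tracked-cell filtering, 2-h birth binning, density-response fit (`μ(N)=aN/(K_N+N+N²/K_I)`) with half-max cell number, logistic count fits, lineage aggregate metric, exact Mann–Whitney + Hodges–Lehmann |
| `polychamber.batch_assays` | plate-reader growth metrics (max OD, time to exponential), lag reduction under enzyme supplementation, halo-diameter correlation (OLS + exact Spearman) |
| `polychamber.synthetic` | ground-truth generators for tracked-cell tables (division-clock birth–dispersal process) and OD curve panels |
| `polychamber.io` | CSV/JSON snapshot and table writers, run manifests |
| `polychamber.cli` | `polychamber` command-line interface |

## CLI

```sh
# synthetic tracked-cell data for 7 chambers, with its truth record
polychamber generate --kind tracks --profile low-secretor --seed 1 --out out/tracks

# plate-reader OD panel for 12 pseudo-strains
polychamber generate --kind od --seed 1 --out out/od

# one chamber simulation from a YAML config
polychamber simulate --config examples/chamber.yaml --out out/sim

# parameter sweeps (density × enzymatic activity, or relative diffusivity)
polychamber sweep --config examples/chamber.yaml --kind density-activity --out out/sweepA
polychamber sweep --config examples/chamber.yaml --kind diffusivity --plot --out out/sweepD

# the single-cell pipeline: filter, bin, fit, aggregate
polychamber analyze-chambers out/tracks/tracks.csv --out out/analysis

# batch growth metrics, lag reduction, secretion correlation
polychamber analyze-batch out/od/od_curves.csv --assays out/od/assays.csv --out out/batch

# two-group Mann–Whitney comparison with Hodges–Lehmann difference
polychamber compare values.csv --group-col strain --value-col n_half --out cmp.csv
```

Every run writes a `manifest.json` (seed, versions, output list) before
any other output. All outputs are plain CSV/JSON; identical seeds give
byte-identical files.

## Notes on parameters

The upstream model's exact rate law and parameter table are not public;
the defaults in `DepolymerizationParams`/`KineticParams` and the tuned
reference configurations in `polychamber.simulate`
(`default_chamber_config`, `diffusivity_sweep_config`) are
reconstructions calibrated to reproduce the reported qualitative
behaviour, and are documented as such in their docstrings. Quantities are
model-relative, not physical measurements.
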