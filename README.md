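# colonyfate

A computational pipeline for morphogen-driven fate patterning in circular
micropatterned stem-cell colonies: a reaction–diffusion (RD) signalling
simulator, a positional-information fate model, synthetic data generators
with ground truth, and the quantification/statistics tools to analyse both
synthetic and real colony data.

## Modules

| Module | What it does |
| --- | --- |
| `colonyfate.rd_model` | Activator/pooled-inhibitor RD simulator (saturating Gierer–Meinhardt kinetics with bath exchange and an optional secondary-signal field) on radial-1D and grid-2D disk domains; linear stability analysis; radial readout profiles; interior-maxima detection. |
| `colonyfate.fate_patterning` | Cumulative-exposure positional-information fate rule: integrates the signalling readout over time and assigns SOX2 / none / GATA3 (or BRA when the secondary signal is on) by exposure thresholds. |
| `colonyfate.synthetic_colonies` | Seeded generators: multi-colony plates with per-cell intensities and a ground-truth sidecar, reference point patterns (uniform-random, jittered-hex, RD maxima), and qPCR Ct tables with planted fold changes. |
| `colonyfate.colony_quant` | DBSCAN colony assignment (plus a brute-force reference implementation), QC filtering, radial profiles with SD and 95% t-CIs, hexagonal-bin maps, and percent-positive via fixed / Otsu / Gaussian-mixture thresholds. |
| `colonyfate.peak_stats` | Foci detection from thresholded cells, nearest-neighbour distance histograms, Shannon entropy, base-2 Jensen–Shannon divergence, and Monte-Carlo non-randomness tests against uniform / jittered-hex / RD-derived nulls. |
| `colonyfate.expression_analysis` | ΔΔCt log₂ fold changes (reference gene + baseline day) and k = 3 K-means clustering of lines into Strong / Intermediate / Weak responders. |

## Command line

The `colonyfate` entry point exposes the pipeline as subcommands; all
stochastic commands take `--seed`:

```sh
colonyfate simulate config.yaml outdir --seed 1      # RD run -> NPZ + radial CSV
colonyfate stability config.yaml dispersion.csv      # linear-stability table
colonyfate fatemap config.yaml outdir --seed 1       # exposure -> fate table
colonyfate generate-plate plate.yaml outdir --seed 1 # synthetic cells + truth
colonyfate generate-pattern pat.yaml pts.csv         # reference point pattern
colonyfate generate-qpcr q.yaml ct.csv               # synthetic Ct table
colonyfate quantify cells.csv outdir                 # colonies, profiles, hex map
colonyfate peaks cells.csv foci.csv --channel m      # foci per colony
colonyfate nnstat pts.csv report.json --radius 600   # NN stats + MC test
colonyfate ddct ct.csv fc.csv                        # log2 fold changes
colonyfate cluster fc.csv labels.csv --gene GENE1    # responder labels
```

Simulation YAML keys: `regime` (`sb` | `nodal` | `turing`), `params`
(overrides of `RDParams` fields), `domain` (`kind`, `R_colony`,
`R_domain`, `h`), `nodal` (`A`, `r_peak_frac`, `w`, `tau_ramp`), `T`,
`save_every`, `n_bins`.

## Testing and acceptance

```sh
pytest -q                                   # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`scripts/acceptance.py` runs the whole pipeline (gradient formation,
knockout, dose/size ladders, secondary-signal reshaping, Turing foci,
fate-fraction monotonicity, quantification recovery, DBSCAN oracle,
NN-statistic calibration, expression round-trip) and writes the headline
quantities as JSON.

See `docs/methods.md` for the model equations, parameter presets and the
rationale behind the main design choices.
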