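# phylorates

Diversification-rate analysis of time-calibrated phylogenies, built around
the kind of question asked for language families: how fast do lineages
multiply, does the rate change through time, and does it depend on how many
lineages already exist?

The package provides, end to end:

- **`phylorates.tree_io`** — reading/writing dated Newick trees (branch
  lengths in years, ages in years before present), node ages, and pruning to
  extant tips.
- **`phylorates.ltt`** — lineages-through-time step functions per tree,
  summation of many trees on an absolute time axis, millennial binning, and
  the overall semi-log diversification rate of a curve.
- **`phylorates.rates`** — the overall rate estimator `r = ln(N_max)/T`,
  doubling times `ln(2)/r`, replication of a published 18-family summary
  table (packaged as `phylorates/data/table1.tsv`), normalization of LTT
  curves to unit depth/size, interval rates over ten normalized-time bins,
  and a bootstrapped mean rate across families.
- **`phylorates.density`** — OLS regression layer: rate-vs-time and
  rate-vs-diversity quadratic fits (with vertex/peak extraction), the
  across-family exponential trend of rates against root age, and a
  three-way density-dependence classification (negative / positive /
  constant-rate) of a family's binned rates.
- **`phylorates.simulate`** — an exact event-driven birth-death simulator
  (constant, exponentially time-varying via thinning, or density-dependent
  speciation; constant extinction) that produces dated crown trees, event
  logs, and whole synthetic family tables, so every analysis stage is
  testable without the original consensus-tree files.
- **`phylorates.cli`** — a `phylorates` command with `rates`, `ltt`,
  `binned`, `density`, `simulate`, and `pipeline` subcommands; plain TSV
  outputs, YAML config, explicit seeds, deterministic reruns.

## Command-line usage

```sh
# per-family rates + bootstrapped mean from the packaged family table
phylorates rates --seed 1 --out out/

# simulate a synthetic study (trees, event logs, family table), then analyze it
phylorates simulate --seed 7 --families 18 --out study/
phylorates ltt study/trees.nwk --out study/
phylorates binned study/trees.nwk --out study/
phylorates density study/trees.nwk --table study/family_table.tsv --out study/

# or all of the above in one go
phylorates pipeline --seed 7 --families 18 --out study/
```

All commands are idempotent for a fixed config and seed (byte-identical
outputs). Exit codes: 0 success, 2 input error, 3 numerical failure.

## Conventions

- Time is measured in years before present (BP); the present is 0 and the
  root age is positive. Natural logarithms throughout.
- Binned interval rates are reported in yr⁻¹ even though bins live on
  normalized time, so they are comparable across families.
- Tabulated doubling times follow the published convention: the rate is
  rounded to 5 decimal places first, then `ln 2 / r` is rounded to whole
  years (configurable via `rate_decimals`).
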