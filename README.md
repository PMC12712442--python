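# frostdrought

Tools for analysing the global trade-off between drought resistance and
frost resistance in woody plants.

Trees and shrubs survive drought by resisting xylem embolism — summarized
by **P50**, the xylem pressure (MPa, negative) at which half of hydraulic
conductance is lost — and survive winter by tolerating freezing, summarized
by **LT50**, the temperature (°C) at which half of cell lysis occurs (or
**LT0**, the coldest temperature without visible damage). Whether species
can be good at both is a long-standing question, and it is confounded by
phylogeny: closely related species resemble each other in both traits, so a
cross-species correlation may reflect shared history rather than a
functional constraint. This package implements the complete comparative
workflow for that question, for ecophysiologists and comparative
biologists:

- **Curation** of heterogeneous literature measurements into one value per
  species: midwinter filtering, freezing/thawing-rate screening, LT50
  estimation from raw electrolyte-leakage curves via a 4-parameter
  logistic, a 6-level organ x method priority (EL-branch > EL-bud >
  VS-branch > VS-bud > EL-leaf > VS-leaf), vulnerability-curve shape
  filtering, a 4-tier technique priority for P50, and a turgor-loss-point
  consistency check.
- **Phylogenetics**: Newick I/O, random grafting of unplaced species into
  their genera, pruning, the Brownian covariance matrix C, Blomberg's K
  with permutation tests, Pagel's λ by profile maximum likelihood with
  likelihood-ratio tests, and Brownian ancestral states.
- **Bayesian mixed-effects quantile regression** of LT50 on P50 at
  τ = 0.1 / 0.5 / 0.9 with group-specific intercepts and slopes
  (deciduous angiosperms, evergreen angiosperms, gymnosperms), an optional
  phylogenetic random effect u ~ MVN(0, σ_p² C), an asymmetric-Laplace
  likelihood (so the fitted line is the conditional τ-quantile), and
  HDI-vs-ROPE inference: a slope is practically nonzero when its 95%
  highest-density interval falls outside ±0.1·SD(y).
- **Climate ranges**: occurrence thinning (≤ 15,000 points, ≥ 10 km
  spacing), nearest-cell raster extraction, and range-edge percentiles
  (5th percentile of the aridity index and of daily minimum temperature).
- **A synthetic-data generator** producing every input with known ground
  truth, so each stage — and the full pipeline — is testable end to end.

See `docs/methods.md` for the model details and design choices.

## Worked example

Run the whole analysis on a simulated 60-species study (traits evolve on a
pure-birth tree; LT50 responds to P50 along known group-specific quantile
lines) and render the verdict table:

```python
from frostdrought.pipeline import PipelineConfig, run_pipeline, render_report

cfg = PipelineConfig(outdir="demo", seed=11, simulate={"n_species": 60},
                     chains=2, iterations=2000, warmup=500, n_perm=199)
bundle = run_pipeline(cfg)
print(render_report("demo"))
```

which prints (abridged):

```
frostdrought v0.1.0 run (seed 11, config 09556b5c8e405305)

Slope HDI vs ROPE (quantile x group x phylogeny):
  tau=0.1  non-phylo gymnosperm             beta=+4.914 HDI=[+0.757, +7.137] -> overlapping
  tau=0.5  non-phylo deciduous_angiosperm   beta=+2.977 HDI=[+1.306, +4.574] -> overlapping
  tau=0.9  non-phylo evergreen_angiosperm   beta=+4.071 HDI=[+2.193, +6.105] -> outside_rope
  tau=0.5  phylo     deciduous_angiosperm   beta=+2.667 HDI=[+0.653, +4.379] -> overlapping
  tau=0.9  phylo     evergreen_angiosperm   beta=+4.322 HDI=[+1.573, +7.120] -> outside_rope
  ...

Phylogenetic signal:
  p50    K       0.661 p_vs_0=0.005 (n=60)
  p50    lambda  1.000 p_vs_0=2.28e-11 p_vs_1=1 (n=60)
  lt50   K       0.147 p_vs_0=0.295 (n=60)
  lt50   lambda  0.313 p_vs_0=0.000876 p_vs_1=6.12e-14 (n=60)
```

Reading it: each row compares a posterior slope (β, in °C per MPa) of the
LT50~P50 quantile regression against the region of practical equivalence.
`outside_rope` means the whole 95% HDI clears ±0.1·SD(LT50) — a
practically nonzero trade-off slope in that group, at that quantile, under
that model. The signal table gives Blomberg's K and Pagel's λ per trait
with tests against no signal (`p_vs_0`) and against pure Brownian motion
(`p_vs_1`). In this simulation both traits evolve on the tree (P50 as pure
Brownian motion, hence λ = 1), and the LT50 response carries substantial
non-phylogenetic quantile noise, so its signal is weaker — the same
qualitative pattern the real databases show.

The same run is available from the shell:

```bash
tradeoff run --config config.yaml         # full pipeline from YAML
tradeoff simulate --outdir sim --seed 3   # synthetic input bundle + truth
tradeoff report --bundle demo             # plain-text verdict table
tradeoff curate frost --in raw.csv --out curated.csv --report report.json
tradeoff physig --tree tree.nwk --traits traits.csv --stat lambda
tradeoff qreg --data merged.csv --tree tree.nwk --phylo on --tau 0.1,0.5,0.9
tradeoff climate --occ occ.csv --grid ai=grids/ai.grid --thin 15000,10
```

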