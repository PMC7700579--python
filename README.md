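# agglomnet

Spatial-correlation network analysis of regional resource-agglomeration
capacity. The package implements a complete, reusable pipeline:

1. **Entropy-weight scoring** (`agglomnet.entropy_scoring`) — min-max
   standardization, per-indicator information entropy, objective weights,
   and composite capacity scores per region.
2. **Modified gravity network** (`agglomnet.gravity_network`) — a directed
   interaction matrix from population, GDP, capacity shares, per-capita-GDP
   gaps and geographic distance, thresholded at row/column/grand mean
   critical points into a directed binary network.
3. **Network metrics** (`agglomnet.network_metrics`) — density, level
   (share of unreciprocated pairs), efficiency, and degree / betweenness /
   closeness centralities with raw and normalized variants.
4. **CONCOR blockmodel** (`agglomnet.block_model`) — convergence of
   iterated correlations with configurable depth and tolerance, block tie
   tabulation (expected vs. actual internal-correlation proportions), and a
   four-role spillover typology (net spillover / bidirectional spillover /
   mediator / net beneficial).
5. **QAP correlation** (`agglomnet.qap_analysis`) — permutation inference
   of the network against covariate absolute-difference matrices, with
   exhaustive enumeration available at small n.
6. **Synthetic data** (`agglomnet.synthetic_data`) — fully seeded generator
   of regions, indicator panels, Euclidean distances and covariates with an
   east-to-west capacity gradient, plantable block structure, and
   plantable covariate-network effects.
7. **Pipeline + CLI** (`agglomnet.pipeline`, `agglomnet.cli`) — one-command
   orchestration with a JSON+CSV report bundle.

## CLI

```bash
# generate synthetic inputs (CSV panel, regions, distances, covariates)
agglomnet simulate --seed 1 --out data/

# validate any input file against its invariants
agglomnet validate --panel data/panel_2018.csv --dist data/distances.csv

# stage by stage
agglomnet score   --panel data/panel_2018.csv --out capacity.json
agglomnet network --regions data/regions.csv --capacity capacity.json \
                  --dist data/distances.csv --rule row_mean --out net.csv
agglomnet metrics --net net.csv --out metrics.json
agglomnet blocks  --net net.csv --depth 2 --tol 0.2 --out blocks.json
agglomnet qap     --net net.csv --covariates data/covariates.csv \
                  --nperm 8000 --seed 1 --out qap.json

# or everything at once
agglomnet run --data data/ --out results/run1/
```

`agglomnet run` accepts a YAML config (`--config`) with fields of
`RunConfig`: `years`, `binarize_rule`, `concor_depth`, `concor_tolerance`,
`role_margin`, `qap_permutations`, `weight_mode` (`per_year` or `pooled`),
`log_covariates`, `seed`, `output_dir`.

## Conventions worth knowing

- Density and efficiency count *unordered connected pairs* (a reciprocated
  pair counts once) against the `t(t-1)/2` denominator; the directed tie
  count is reported separately.
- Binarization compares each gravity cell to the mean of its row's
  off-diagonal cells by default (`row_mean`); `col_mean` and `grand_mean`
  are available for sensitivity analysis. Ties (`>=`) become 1; zero cells
  never do.
- Betweenness is computed on the directed graph (ordered-pair sum, halved
  for the raw score); closeness on the symmetrized graph with unreachable
  distances capped at the node count.
- CONCOR convergence: iterate until every off-diagonal correlation is
  within the tolerance of +/-1 (cap 100 iterations); isolates are attached
  to the block they share most ties with.
- A block is "internally dense" for role classification when its actual
  internal proportion is at least `role_margin` (default 1.5) times the
  expected proportion.
- QAP p-values use the add-one estimator; one- and two-tailed are both
  reported.
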