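# hubnet

Perturbed-subnetwork and hub-network analysis of two-group expression data
on a protein-interaction network.

Given an undirected interactome and a case/control expression matrix, the
pipeline:

1. cleans the network (self-loop removal, restriction to measured genes,
   largest connected component) and preprocesses expression data
   (detection-call filtering, probe collapse, k-NN imputation);
2. computes empirical-Bayes moderated t-statistics and two-sided p-values
   per gene;
3. fits a beta-uniform mixture (BUM) to the p-value collection, scans an
   FDR grid for the threshold whose positively scored fraction is closest
   to a target (default 10% of network nodes), and converts p-values into
   additive node scores that change sign at the threshold;
4. searches for the maximal-scoring connected subnetwork — exhaustively on
   small graphs, with an MST-contraction heuristic on large ones;
5. extracts degree-quantile hubs (default 90% quantile) per condition,
   assembles the cross-condition hub network, and quantifies its
   perturbation (mean |moderated t| with a permutation null), pairwise
   subnetwork overlaps (Fisher exact), gene-set over-representation
   (hypergeometric, GMT input), enrichment maps (overlap coefficient) and
   severity-score correlations.

A `simulate` module generates scale-free networks with planted, connected,
differentially expressed modules plus BUM p-value collections and severity
scores, so every stage is testable offline against known ground truth.

## CLI

```sh
# write a synthetic dataset (network.tsv, expression.tsv, design.tsv, truth.json)
hubnet simulate --outdir demo --n-genes 500 --module-size 20 --seed 42

# full pipeline from a config file
hubnet run-all config.yaml
```

Minimal `config.yaml`:

```yaml
network: demo/network.tsv
conditions:
  - name: cond1
    expression: demo/expression.tsv
    design: demo/design.tsv
outdir: demo/out
seed: 42
# optional: gene_sets: sets.gmt, severity: {mmse: mmse.tsv, nft: nft.tsv},
# target_fraction, hub_quantile, n_perm, fdr_grid, min_overlap, alpha
```

Artifacts per run: per-condition `de.tsv`, `scores.tsv` (with a JSON header
carrying the fitted `lam`, `a`, chosen `fdr` and `tau`),
`subnetwork_nodes.tsv`/`subnetwork_edges.tsv`; cross-condition
`hub_nodes.tsv`/`hub_edges.tsv` (edge provenance lists the conditions),
`enrichment.tsv`, `correlation.tsv`; and `report.json` plus the resolved
config. Outputs are byte-reproducible for a fixed config and seed (wall
time lives in a separate `timing.log`).

Individual stages are also exposed: `hubnet de`, `fit-bum`, `score`,
`search`, `hubs`, `perturb`, `enrich`, `correlate`. Exit codes: 0 success,
2 config error, 3 data error, 4 numerical failure.

## File formats

- Networks: two-column TSV or SIF edge lists.
- Expression: TSV, first column gene/probe id, header row of sample ids;
  `NA`/empty cells are missing.
- Design and severity scores: two-column TSV (sample, value).
- Gene sets: GMT.
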