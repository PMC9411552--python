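# funcpred

Balanced-ensemble gene function prediction with orthogonal network
validation.

Given a binary gene × attribute matrix, a list of positive genes and a
weighted protein–protein interaction network, `funcpred`:

1. splits the positive class 80/20 (stratified, floor rounding on the test
   side) and partitions the training negatives into disjoint blocks equal in
   size to the positive training set, yielding one balanced training set per
   block;
2. filters features per training set (zero-fraction and variance rules) and
   merges the per-set survivor lists;
3. trains an ensemble of classifiers per model type (LR, GNB, SVM, RF, GB)
   with optional grid/randomized hyperparameter search and 10-fold CV;
4. scores every gene with every ensemble member, averages the Class-1
   probabilities, calls the top 1% high-confidence set per model type, and
   intersects calls across types (≥ 3 of 5 by default);
5. evaluates the selected ensemble on balanced hold-out test sets and on the
   pooled hold-out (FPR at 0.5, FDR/FPR at top-k);
6. validates predictions against the PPI network: personalized PageRank
   from the known positives, preranked GSEA of the predictions on the
   PageRank ranking, Louvain community detection on the known+predicted
   subnetwork, and hypergeometric over-representation of communities
   against GMT gene sets.

A synthetic-data module generates feature matrices with planted
class-conditional signal and stochastic-block-model PPI networks, so the
full pipeline is exercisable (and tested) without any downloads.

## CLI

The `funcpred` entry point exposes one subcommand per stage plus `run`:

```bash
# full synthetic run with package defaults
funcpred run --outdir out --seed 7

# or stage by stage (later stages read earlier artifacts from --outdir)
funcpred simulate -o out --seed 7
funcpred split -o out --seed 7
funcpred filter -o out --seed 7
funcpred train -o out --seed 7
funcpred predict -o out --seed 7
funcpred evaluate -o out --seed 7
funcpred ppi-validate -o out --seed 7
funcpred communities -o out --seed 7
```

A YAML config (`-c config.yaml`) overrides any default; to run on real data
instead of the simulator, point `inputs:` at your files:

```yaml
seed: 1
inputs:
  feature_matrix: matrix.tsv        # genes x features, 0/1 cells
  feature_families: families.tsv    # feature_id <tab> family
  positives: positives.txt          # one gene id per line
  ppi_edges: edges.tsv              # node <tab> node <tab> score (0-1000)
  gene_sets: sets.gmt
ppi_min_score: 400
models:
  types: [LR, GNB, SVM, RF, GB]
  tuning: paper       # grid/randomized search; "none" = library defaults
  run_cv: true
selected_ensemble: GB
```

Every run writes a `manifest.json` recording the config hash and per-stage
outputs; stages refuse to mix artifacts produced under different configs.
Identical config + seed reproduces byte-identical TSV outputs.

## Layout

```
src/funcpred/
  types.py        shared domain types (matrix, labels, metrics, graph, gene sets)
  io.py           TSV/GMT readers and writers (lossless round trips)
  synthetic.py    planted-signal matrix + SBM network generators
  design.py       stratified split and balanced negative-block partitioning
  filters.py      zero-fraction and variance feature filters + merge
  models.py       the five classifier types, tuning, CV, metrics, importances
  predict.py      genome-wide aggregation, top-1% calling, consensus
  holdout.py      balanced test-set evaluation, pooled FPR, top-k FDR/FPR
  network.py      personalized PageRank and preranked GSEA
  communities.py  Louvain, modularity, hypergeometric enrichment, BH
  pipeline.py     stage orchestration, config, manifest
  cli.py          click CLI
  benchmark.py    desk-scale parameter-recovery experiment
```
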