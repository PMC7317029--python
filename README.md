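# clonescreen

Analysis pipeline for an in-vivo RNAi tumor-progression screen. The package
re-implements the screen's computational stages as reusable, tested code:

- **score_db** — data model, validation, I/O and aggregation for the
  per-animal, dual-scorer ordinal phenotype score database (default 33
  categories on a −2…+2 scale; lethal lines tracked separately).
- **qc** — qualitative-vs-quantitative Spearman correlation, between-scorer
  agreement, and permutation-tested concordance of independent RNAi line
  pairs targeting the same gene.
- **hit_calling** — per-category median ± IQR hit rule (strict bounds,
  type-7 quantiles by default), directional calls, and cross-category hit
  union with category membership retained.
- **clustering** — row scaling, model-based choice of K (BIC over
  shared-variance spherical mixtures), Euclidean agglomerative clustering,
  and resampling consensus clustering with CDF-delta-area model selection.
- **enrichment** — exact hypergeometric over-representation with
  Benjamini–Hochberg adjustment (terms are opaque labels).
- **network** — hit/lethal/linker interaction-graph construction from typed
  edge tables and a from-scratch molecular-complex-detection algorithm
  (neighborhood k-core vertex weighting, greedy seed-and-grow, haircut,
  fluff), plus hub ranking and bipartite interaction counting.
- **tracks** — 3-D single-cell trajectory metrics (path length,
  displacement, speed, straightness), group directionality verdicts, and the
  polarized-actin vs invasion Spearman correlation.
- **expression** — knockdown-vs-pooled-control Welch t per gene on log2
  intensities, signed linear fold change on anti-logged means, and the
  p < 0.01, |FC| ≥ 1.5 pass filter.
- **synthetic** — seeded generators for every input (score database with
  planted effects, persistent-random-walk tracks, interactomes with planted
  complexes, expression matrices with planted fold changes), each returning
  ground truth for recovery testing.
- **pipeline** — YAML-configured end-to-end driver with per-stage seeds and
  a hash manifest that reproduces exactly on rerun.

## CLI

All stages are exposed under a single entry point:

```sh
clonescreen simulate scores --n-genes 497 --frac-two-lines 0.515 --seed 7 --out scores.tsv
clonescreen aggregate --scores scores.tsv --out matrix.tsv
clonescreen qc pairs --scores scores.tsv --n-perm 10000 --seed 7 --out concordance.tsv
clonescreen hits --matrix matrix.tsv --map lines.tsv --out hits.tsv
clonescreen cluster lines --matrix matrix.tsv --kmin 2 --kmax 15 --seed 7 --out clusters.tsv
clonescreen cluster categories --matrix matrix.tsv --out category_clusters.tsv
clonescreen network --hits hits.tsv --edges interactions.tsv --out network.tsv
clonescreen enrich --set hits.txt --universe universe.txt --annot go.tsv --out enr.tsv
clonescreen tracks --in tracks.csv --group genotype --out stats.tsv
clonescreen de --expr expr.tsv --samples samples.tsv --out de.tsv
clonescreen pipeline --config run.yaml
```

`clonescreen pipeline` runs aggregate → qc → hits → clustering → network
(+MCODE-style complexes, optional enrichment) → tracks → de from one YAML
config and writes a `manifest.json` of output hashes.

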