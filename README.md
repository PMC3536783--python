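# phosphowrangle

Cluster wrangling for extremely sparse phosphoproteomic count matrices.

Shotgun tyrosine-phosphoproteomics yields a gene × sample table of
phosphopeptide spectral counts in which the vast majority of cells —
routinely ~95% — contain no measurement at all. Mass spectrometers have a
very low false-positive rate but a high false-negative rate, so an empty
cell means "not detected", never "zero". Treating those cells as zeros
makes every unmeasured protein correlate with every other and collapses
all statistical structure. `phosphowrangle` is a library + CLI for
analysts who want to resolve, score, filter, and externally validate
clusters of co-phosphorylated proteins in such matrices, keeping missing
data missing at every step.

## Method

For genes *x*, *y* measured over samples:

* **Correlation distance** `d = 1 − |r|`, with *r* the Pearson or (by
  default) Spearman correlation over the *pairwise-complete* samples —
  the samples observed in both genes. Pairs with overlap < 2 samples, or
  no variance on the overlap, have **no defined distance**.
* **Euclidean distance** over co-observed samples, with the partial sum of
  squares rescaled to the full sample count:
  `d = sqrt((p/m) · Σ_co-observed (x_i − y_i)²)` for *m* of *p* samples
  co-observed.
* Undefined distances mean "no statistical relationship" and are set far
  beyond any real distance: **100 × the maximum real distance** of each
  matrix.
* The **Spearman–Euclidean Dissimilarity (SED)** divides each filled
  matrix by its own maximum real distance (real distances land in [0, 1])
  and averages the two entrywise.
* Each gene's row of the filled dissimilarity matrix is treated as its
  **feature vector** (a dissimilarity representation — no attempt to
  preserve the distances), embedded in 2–3 dimensions by **t-SNE**
  (perplexity 30) or classical MDS, and clusters are read off the map by
  **minimum-spanning-tree single linkage**: cut every MST edge longer
  than a radius, or the k−1 longest edges for exactly k groups. k-means
  and fuzzy-membership selection are provided for comparison.
* Clusters are scored from the primary data by the **Index**

  ```
  intensity   = total_signal − total_signal · %NA/100
  cleargenes  = n_genes − genes culled by slope
  realsamples = n_samples − n_samples · %single-gene-samples/100
  Index       = intensity · (1 + realsamples) · (1 + cleargenes) / (1 + %NA)
  ```

  where a gene is *culled by slope* when, with the cluster's samples
  sorted by decreasing total signal, the regression slope of its values
  (missing as 0) on sample position is positive — it peaks where the
  cluster is weak.
* **Wrangling** merges clusters found under different dissimilarities and
  filters them to a fixed point (anchor kinase, minimum occurrence,
  single-sample genes, single-gene samples, slope conformity).
* **External evaluation** merges interaction-database evidence into
  weighted networks (directed kinase–substrate edges at a fixed 0.25
  weight), compares clusters to random gene-set backgrounds
  (edges/node, weight/node), computes expected induced edges under
  density or configuration nulls, and tests GO term over-representation
  with the hypergeometric tail (terms need p < 0.01 and ≥ 2 genes).

## Worked example

Simulate a 300 × 60 matrix with 10 planted 12-gene clusters at ~95%
missingness, run the full pipeline, and score the clusters:

```python
import phosphowrangle as pw

matrix, truth = pw.simulate_phospho_matrix(pw.SimulationConfig(seed=0))
print(matrix.summary())
# {'n_genes': 300, 'n_samples': 60, 'percent_missing': 94.07, 'total_signal': 5468.0}

D = pw.sed(matrix)                                   # filled SED matrix
emb = pw.tsne_embed(D, pw.EmbeddingConfig(seed=0, whiten=False))
clusters = pw.mst_cluster(emb, "radius", radius=2.0)
table, summary = pw.rank_clusters(matrix, clusters)
print(clusters.n_clusters)                           # 43
print(table.head(3).round(1).to_string(index=False))
```

```
 group  rank  n_genes  percent_single_sample_genes  n_samples  percent_single_gene_samples  total_signal  percent_na  n_culled  index
    14     1       12                          0.0         10                         20.0         408.0        31.7         1  921.7
     8     2       12                          0.0         11                         27.3         394.0        35.6         0  810.9
     7     3       13                          0.0         11                         27.3         468.0        42.7         0  774.5
```

The top-ranked groups are exactly the planted 12-gene clusters (the
surplus groups are background-gene singletons and fragments, which the
Index ranks far below). Against the planted labels this run scores an
adjusted Rand index of 0.96. The Index orders clusters by data density:
group 14 wins because nearly 70% of its cells are observed and only one
gene defies its expression pattern.

The same pipeline is available from the shell:

```bash
phosphowrangle simulate matrix --seed 0 --out matrix.tsv --truth truth.tsv
phosphowrangle dissim --matrix matrix.tsv --method sed --out D.tsv
phosphowrangle embed --dissim D.tsv --method tsne --seed 0 --out E.tsv
phosphowrangle cluster --embedding E.tsv --method mst --radius 2.0 --out C.tsv
phosphowrangle evaluate --matrix matrix.tsv --clusters C.tsv --out eval.tsv
```

or as one configured run: `phosphowrangle run --config pipeline.yaml
--outdir out/` (every stage writes a provenance JSON with its parameters
and derived seed; reruns are bit-identical).

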