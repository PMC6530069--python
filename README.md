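# limbatlas

Construction of single-cell transcriptomic atlases from UMI count
matrices, built for developmental samples such as the embryonic limb
autopod: quality control, normalization, cell-cycle scoring, clustering
with differential-expression-based cluster collapse, and gene
co-expression module discovery — with a planted-truth simulator so that
every stage has a recovery-based test.

## Who this is for

Computational biologists who want the atlas-construction workflow of
droplet scRNA-seq studies as a tested, scriptable Python library: each
stage is exposed both as a plain function over typed containers and as a
scikit-learn-style estimator (`fit` / `transform`, `get_params`,
fitted attributes with trailing underscores) that composes with sklearn
pipelines.

## The methods at the core

* **QC filtering** — remove cells with UMI total > 4 × sample mean or
  < 20% of the sample median, or with mitochondrial or ribosomal UMI
  fraction > 10% (statistics computed once, on the unfiltered sample).
* **Log-normalization** — `log(1 + c·s/t)` per entry, cell total `t`,
  scale factor `s = 10⁴`.
* **Cell-cycle scores** — per phase, the fraction of marker gene pairs
  `(g_hi, g_lo)` with `expr(g_hi) > expr(g_lo)` among informative pairs;
  the covariate δG2M/S = s(G2M) − s(S) is regressed out downstream.
* **Marchenko–Pastur PCA** — keep principal components whose
  sample-covariance eigenvalue exceeds the MP upper edge
  `λ₊ = (1 + √(p/n))²` expected for i.i.d. unit-variance noise.
* **SNN/Louvain clustering** — Jaccard-weighted shared-nearest-neighbor
  graph (k = 20) on the significant-PC scores; Louvain modularity with
  Reichardt–Bornholdt resolution at a broad (0.4–0.5) and a fine
  (1.1–1.4) tier on the same graph.
* **Negative-binomial DE** — per gene, NB2 GLM with a group indicator,
  the δG2M/S covariate and a log-total-UMI offset; likelihood-ratio test,
  15% expression gate, Bonferroni adjustment. Sibling cluster pairs with
  fewer than 15 signature-grade DE genes (pct ≥ 25%, logFC > 0.5,
  adj. p < 0.05) are collapsed recursively.
* **Iterative signed WGCNA** — adjacency `((1 + cor)/2)⁸`, topological
  overlap, average-linkage tree of 1 − TOM cut at height 0.9957 with
  minimum module size 15; module eigengenes (sign-oriented first PC),
  membership kME with Student-t p-values; genes not significant
  (p > 0.01) for any eigengene are discarded and the chain repeats until
  stable. Module activity (mean member-gene expression per cell) tracks
  modules across developmental stages.

See `docs/methods.md` for assumptions, parameter defaults, tie-breaking
and degenerate-input rules.

## Worked example

```python
import numpy as np
import limbatlas as la

# simulate a 600-cell atlas with 3 planted populations
cm, truth = la.simulate_atlas(la.preset("three_pops"))

# QC: metrics + filtering
qc = la.compute_qc_metrics(cm, truth.gene_classes)
kept, qc = la.filter_cells(qc, la.QCThresholds())
cm = cm.subset_cells(qc["keep"].to_numpy())

# normalize, select variable genes, scale, cluster
nm = la.lognormalize(cm)
hvg = la.select_variable_genes(nm)
nm_hvg = nm.subset_genes([i for i, g in enumerate(nm.gene_ids) if g in set(hvg)])
import pandas as pd
cov = pd.DataFrame({"umi_total": cm.cell_totals().astype(float)},
                   index=pd.Index(cm.barcodes))
sm = la.regress_and_scale(nm_hvg, cov)
labels = la.cluster_two_tier(sm, seed=0)

from sklearn.metrics import adjusted_rand_score
keep = qc["keep"].to_numpy()
print(len(hvg), "variable genes,", labels.n_significant, "significant PCs")
print(len(set(labels.labels_broad)), "broad clusters, ARI",
      round(adjusted_rand_score(truth.population_label[keep],
                                labels.labels_broad), 3))
```

prints

```
239 variable genes, 5 significant PCs
3 broad clusters, ARI 1.0
```

— the two population-discriminant directions and the three planted
co-expression programs all clear the Marchenko–Pastur edge, the broad
Louvain tier returns one cluster per planted population, and the
adjusted Rand index of 1.0 means the recovered labels match the planted
ones exactly (up to renaming).

The same workflow is available from the shell:

```sh
limbatlas simulate --preset three_pops --out sim/
limbatlas load --matrix sim/matrix.mtx --genes sim/genes.tsv --barcodes sim/barcodes.tsv
limbatlas run-all --config config.yaml
```

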