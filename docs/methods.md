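# Methods

This note describes the models and procedures implemented in `limbatlas`,
the choices made where the design was genuinely open, and what the
synthetic fixtures do and do not establish about real data.

## Scope and data model

The package re-implements a single-cell UMI atlas-construction workflow:
per-cell quality control, log-normalization, marker-pair cell-cycle
scoring, PCA with random-matrix component selection, shared-nearest-
neighbor Louvain clustering at two resolutions with recursive DE-based
cluster collapse, negative-binomial differential expression, and iterative
signed-TOM co-expression module discovery. The substrate is a sparse
genes × cells matrix of deduplicated transcript (UMI) counts read from
10X-style Matrix Market triplets; both id-only and id+name gene-table
dialects are accepted, and duplicate gene identifiers are suffixed
(`.1`, `.2`, in file order) rather than summed, which keeps the mapping
reversible.

## Quality control

Per cell we compute the UMI total, genes detected, and the fraction of
UMIs on mitochondrial and on ribosomal genes (a gene-class lookup;
unlisted genes count as "other"). Cells are removed when the UMI total
exceeds `upper_mean_mult` (default 4) times the sample mean, falls below
`lower_median_frac` (default 0.20) of the sample median, or when an
organelle fraction exceeds `organelle_frac_max` (default 0.10). Open
choices, resolved as follows:

* the mean and median are computed once, on the unfiltered barcode set, so
  the rule is a pure function of the input (and idempotent on its own
  output);
* "mitochondrial or ribosomal contribution above 10%" is read as
  either-class-exceeds, each fraction capped at 0.10 separately; the
  combined-sum reading is available via `QCThresholds(combined_organelle=True)`.

## Normalization, variable genes, scaling

Counts are log-normalized: entry `log(1 + c * s / t)` with per-cell total
`t` and scale factor `s` (default 10,000; natural log throughout).
Variable genes are selected by dispersion (variance/mean of the
back-transformed expression), z-scored within 20 equal-frequency mean
bins, keeping genes with standardized dispersion strictly above 0.5.
Scaling residualizes each gene by OLS on an intercept plus nuisance
covariates (library size, mitochondrial fraction, and — for the
clustering input only — the cell-cycle score difference δG2M/S), then
z-scores the residuals; rank-deficient designs fall back to the
pseudo-inverse solution, and constant genes map to zero rows.

## Cell-cycle scoring

Each phase (G1, S, G2/M) has a catalogue of ordered gene pairs
`(g_hi, g_lo)`; the per-cell phase score is the fraction of informative
pairs (members not tied within the cell) with `expr(g_hi) > expr(g_lo)`.
Cells with no informative pairs score 0.5. This pair-voting score is a
deliberate simplification of the published random-projection classifier
built on the same rank-pair logic: it is rank-based (invariant under any
monotone per-cell transformation), exactly testable, and sufficient to
produce the nuisance covariate δG2M/S = s(G2M) − s(S). Exact arg-max ties
resolve with priority G1 > S > G2M. δG2M/S is used only as a regression
covariate, never as a filter. Pair catalogues from another species pass
through an ortholog table first; pairs with an unmapped member are
dropped and counted.

## Dimensionality reduction and clustering

PCA is an exact SVD of the per-gene z-scored matrix with cells as
observations; eigenvalues are sample-covariance eigenvalues (divisor
n−1). Under the null of i.i.d. unit-variance entries the eigenvalues lie
inside the Marchenko–Pastur bulk, so components with eigenvalue above the
upper edge `(1 + sqrt(p/n))²` (σ² = 1 because the data are z-scored) are
retained. If none passes, the top 2 are used with a warning.

The SNN graph connects cells by the Jaccard overlap of their k-nearest-
neighbor sets (k = 20, Euclidean, self included; stable index-order
tie-breaking on duplicate coordinates); edges with weight ≤ 1/15 are
pruned (configurable — the value is the convention of the workflow's
toolchain, which does not publish it). Louvain greedy modularity
optimization with the Reichardt–Bornholdt resolution scaling of the
configuration-model null term yields communities; labels are ranked by
decreasing size. Broad (default 0.4; 0.5 appropriate for less complex
samples) and fine (1.1–1.4) resolutions run on the *same* graph — the
fine tier is an independent clustering, not a split of the broad one. A
t-SNE embedding is provided for visualization only; nothing downstream
reads its coordinates.

## Differential expression and cluster collapse

Per gene, counts are modelled as NB2 (variance = μ + μ²·α) with log link:
intercept + group indicator + δG2M/S, with a log-total-UMI offset. The
dispersion α is gene-wise, estimated by profile maximum likelihood
alternating with IRLS for the coefficients; the group effect is assessed
by a likelihood-ratio χ²(1) test. A gene whose NB fit diverges falls back
to a Poisson fit (flagged); a gene failing both reports p = 1 (flagged).
Genes enter testing only if expressed in ≥ 15% of either compared group;
adjustment is Bonferroni over tested genes (Benjamini–Hochberg via
`DEThresholds(adjust="bh")`). `avg_logFC` is the difference of mean
log-normalized expression (natural log), matching the reported column of
the source workflow. The fitter was written in-house because the
collapse loop fits two models per gene for every sibling cluster pair in
every round; the identical statsmodels model serves as the independent
oracle in the test suite.

Marker signatures keep genes with focus-cluster expression fraction
≥ 25%, logFC > 0.5 and adjusted p < 0.05, sorted by logFC. Cluster
collapse builds an average-linkage tree of cluster centroids in
significant-PC space, tests every sibling leaf pair, and merges — 
simultaneously, lowest label surviving — every pair separated by fewer
than 15 signature-grade genes, counting the union of both directions
(the LRT is direction-free, so one fit serves both). The loop repeats
until stable, bounded by the initial cluster count. Whether the "<15
differentially expressed genes" rule uses the signature thresholds or the
looser testing gate is not decidable from the source; the signature
thresholds were chosen and are configurable.

## Co-expression modules

On the log-normalized expression of the variable genes (the
covariate-regressed matrix is an alternative substrate; the source is
ambiguous, and log-normalized was chosen because variable-gene selection
feeds the network step directly):

1. signed adjacency `a_ij = ((1 + cor(x_i, x_j))/2)^β`, Pearson, β = 8;
2. topological overlap
   `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`;
3. average-linkage tree of 1 − TOM, cut at fixed height 0.9957; branches
   of ≥ 15 genes become modules (size-ranked color-style labels), the
   rest "unassigned";
4. eigengenes: sign-oriented, unit-variance first principal component of
   each module's standardized member genes (orientation: non-negative
   correlation with the module's mean profile);
5. membership: kME = Pearson correlation of every gene with every
   eigengene, two-sided Student t p-value with t = r·√((n−2)/(1−r²));
6. genes whose p-value exceeds 0.01 for *every* eigengene are discarded
   (unassigned genes that pass for some eigengene are retained), and the
   chain re-runs on the survivors until no gene is discarded.

On re-runs the minimum module size is relaxed downward from 15 only as
far as needed to keep at least as many modules as the first pass
produced (the largest size in [2, 15] meeting the count; if even 2 cannot,
15 is reused). Taking the *smallest* size meeting the count would
degenerate to 2 by monotonicity — the module count is non-increasing in
the minimum size — and fragment the network.

The fixed cut height is a data-calibrated constant of the source
workflow: on other data, branches whose merge height straddles it can
fuse or split, which is visible on some simulation seeds and is the
expected behavior of a static cut.

Module activity is the per-cell mean log-normalized expression over
member genes; cross-stage comparison discovers modules on one reference
stage (the most complex sample), scores them on every stage, and
averages per (stage, sub-cluster) group with average-linkage ordering of
both heatmap axes. Graph export emits node tables (size ∝ kME, min–max
rescaled within the module) and edge tables (pairwise adjacency, likewise
rescaled) with a visibility threshold set to the largest value that
leaves every node at least one visible edge.

## Synthetic atlases

The generator draws NB2 counts (gene-wise dispersion φ ~ Gamma(2, 0.15);
variance μ + μ²φ, matching the DE model so recovery tests are coherent)
around lognormal base abundances, with: population marker fold-changes
applied multiplicatively; latent per-cell module factors ~ N(0, sd)
acting on the log-mean (loading × factor), so Pearson correlation of
log-normalized expression carries the planted signal the network stage
assumes; phase-dependent symmetric shifts on (up, down) pair genes;
lognormal library sizes (mean log 2000, sd 0.25 on the log scale); and
planted outliers — high-UMI cells pinned at a multiple of the expected
library size, and high-mitochondrial cells with the organelle share
pinned at a target level. Zero inflation arises only from NB sampling;
there is no extra dropout layer.

Preset fixtures (sizes chosen as small but adequately powered recovery
problems): `qc_outliers` (600 cells, 20 cells at 6× library, 20 at 25%
mito), `three_pops` (600 cells, 1000 genes, 3 populations with 40
four-fold markers each, plus three 30-gene latent programs — real
samples always carry continuous within-population variation, and without
it the significant-PC space degenerates to the two discriminant
directions, a geometry in which modularity clustering splits blobs),
`overclustered` (the same populations *without* latent programs, so that
fine-resolution splits are spurious by construction and collapse must
undo them), `planted_modules` (3 × 30-gene modules, loading 0.8, + 200
unstructured genes, 500 cells), `cellcycle` (40 pairs per phase,
three-fold pair effect), and `two_stage_shared_module` (a module tied to
a population recurring in two independently simulated stages).

What passing these fixtures does *not* show: robustness to batch and
chemistry effects across platforms, ambient RNA, doublets, dropout
beyond NB sampling, or spatial structure — none of which the generator
emulates.

## Numerical and reproducibility notes

* All stochastic stages take explicit seeds; Louvain is seeded through
  the igraph RNG, t-SNE through sklearn's `random_state`. Two runs with
  the same configuration and seed produce byte-identical tables, and
  every output table carries a configuration hash (analysis parameters
  only, not the output path) plus the seed.
* Tie-breaks: k-NN ties by stable index order; arg-max phase ties by
  G1 > S > G2M; equal-size module labels by first gene index; cluster
  merges keep the lowest label.
* Degenerate inputs: zero-UMI cells are flagged at QC and rejected by
  normalization; constant genes are dropped (network) or zeroed
  (scaling); TOM denominators ≤ 0 map to 0 with a log entry; an
  eigengene of a constant module is zero.
* The NB fitter clips linear predictors to ±30 and solves with a 1e-10
  ridge, which stabilizes separation cases; profile dispersion is
  optimized on the log scale in [e⁻¹², e⁶].
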