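# Methods

## Blood vs. tissue-resident classification

### Model

Immune cells captured from blood vessels inside a tissue sample and
tissue-resident cells of the same type are transcriptionally close; the
classifier therefore works geometrically rather than with marker genes.
Per immune cell type:

1. **Normalization.** Counts-per-10,000 followed by log1p, the community
   standard. Cells with zero total counts are an error (quality control is
   the caller's job).
2. **Shared features.** Genes present in both query and reference, ranked
   by dispersion (variance/mean) on the concatenated normalized matrix;
   top `n_hvg` (default 2000) kept.
3. **Joint embedding.** Query and reference cells are concatenated,
   features z-scaled on the concatenation, and a `latent_dim`-dimensional
   (default 10) PCA computed. With `embed_method="umap"` the PCA
   coordinates are further embedded into UMAP of the same dimension
   (n_neighbors=30, min_dist=0.3, fixed seed). Passing both matrices
   through one transform is what makes query–reference distances
   meaningful; per-dataset reductions would put the two sets in
   incomparable coordinates.
4. **Distance profiles.** Each query cell's feature vector for clustering
   is its full vector of Euclidean distances to every reference cell.
   Clustering the full profile preserves the geometry of *where* a cell
   sits relative to the reference; clustering the scalar mean distance is
   available as `profile_summary="mean"`.
5. **k-means, k=2** on the profiles, then the cluster with the smaller
   average per-cell mean reference distance is labeled blood, the other
   tissue. An exact tie labels cluster 0 blood with a warning.

### Numerical choices

- PCA components have their sign fixed (largest-magnitude loading
  positive) so output is bit-reproducible.
- k-means is initialized deterministically from the data geometry: initial
  centers are the profile rows at the quantiles of mean reference
  distance. Seeded k-means++ initialization depends on row order, which
  would break the guarantee that calls are invariant to cell order and
  barcode renaming; quantile initialization does not. The degenerate case
  of fewer distinct profiles than clusters falls back to seeded k-means.
- Cell types with fewer than `min_cells` (default 20) query cells are left
  unassigned with a warning — clustering a handful of points produces
  labels with no support. Reference cells of the matching annotated type
  are used when reference annotations are supplied and the type exists
  there; otherwise the whole reference is used, with a warning.
- One top-level seed fans out to per-cell-type seeds through a stable
  string hash, so adding or removing one type does not reshuffle the
  others.
- `embed_method` defaults to `umap` for analysis use; the test and
  acceptance runs use `pca`, which is deterministic to the bit, an order of
  magnitude faster, and recovers the planted structure equally well on the
  synthetic mixtures.

## Genotype demultiplexing

### Model

Cells pooled from *N* individuals are a finite mixture. Each origin *k*
has a diploid alternate-allele dosage $d_{kv} \in \{0, 0.5, 1\}$ per
variant *v*; a read at *v* from a cell of origin *k* is alternate with
probability $p_{kv} = d_{kv}(1-\varepsilon) + (1-d_{kv})\varepsilon$. A
cell's log-likelihood is the binomial sum over variants; variants without
coverage contribute nothing.

- **SNP filter**: population MAF strictly greater than `max_maf` percent
  (default 10) is excluded — the boundary value is retained — as are
  variants with zero total coverage. Common variants are likely shared
  between individuals and dilute the signal.
- **EM**: E-step computes responsibilities from current dosages and
  mixing weights; M-step picks, per origin and variant, the dosage level
  in {0, 0.5, 1} maximizing the responsibility-weighted log-likelihood
  (a 3-way argmax, exact), then updates mixing weights. Initialization is
  k-means on per-cell alt-fraction vectors with zero-coverage entries
  imputed at the population MAF. The observed-data log-likelihood is
  checked non-decreasing (tolerance 1e-9) at every iteration and the loop
  stops when the improvement falls below `tol` (1e-6) or at `max_iter`
  (100), in which case the model is returned flagged unconverged with a
  warning.
- **Doublets**: a mosaic doublet is one barcode containing a 50/50
  genetic mixture of two individuals, so its dosage profile is the
  average $(d_j + d_k)/2$ of two origins. The posterior is computed over
  N singlet categories (prior $(1-\pi_d)$ split by mixing weights) and
  ${N \choose 2}$ pair categories (prior $\pi_d$ split evenly,
  $\pi_d = 0.05$ default). Calls below the confidence threshold (default
  0.8) are ambiguous; a cell with no reads keeps the prior and is
  therefore ambiguous.
- **Origin labels**: with two origins, the index holding the majority of
  a known-origin anchor type's singlet cells (e.g., trophoblast → fetal)
  receives the biological label. An exact 50/50 split is an error
  requiring manual assignment, never a silent coin flip.

### Design choices

- Dosages are restricted to the three diploid values rather than a
  continuous allele fraction: at the coverage typical of scRNA-seq
  (a few reads per variant) continuous dosages are not identifiable.
- The error rate $\varepsilon$ (default 0.01) is fixed, not estimated —
  low-coverage data cannot separate $\varepsilon$ from heterozygous
  dosages reliably. It is configurable.
- Doublet composition is fixed at 50/50; unequal mixtures are out of
  scope.
- The mixture model is freemuxlet-like in task and interface (reference
  free, `--nsample N`), not byte-compatible with any external tool.

## Synthetic data

### Expression mixtures

Each cell type has a baseline log-expression program (Gaussian over
genes). Cells carry a latent state in `n_programs` (default 10)
dimensions, drawn with per-axis SD `within_sd` around the compartment
mean; the state maps to gene space through type-specific orthonormal
loadings scaled by `program_scale` (default 8). Tissue-resident cells'
latent mean is displaced by `latent_shift` along a random latent
direction fixed per type, so the planted blood–tissue separation is
`latent_shift / within_sd` in latent units — the quantity the embedding
step is meant to recover. Counts are multinomial draws of `library_size`
(default 2000) reads over the softmax of the resulting log-expression.
The reference consists of additional, independently drawn blood cells of
every type.

Defaults (4 types, 250 cells per type per compartment, 500 genes,
shift = 5, within_sd = 1) give a clearly but not trivially separated
mixture: the classifier reaches AUC ≈ 0.98, not 1.0, and a shift of 0
yields AUC ≈ 0.5. The generator deliberately omits dropout, ambient RNA
and batch effects; passing tests therefore demonstrates the geometry of
the method, not robustness to every real-data artifact.

### Allele counts

Population MAFs are Beta(1.5, 20) (mostly rare, matching a pool after
upstream frequency filtering), folded into (0, 0.5]. Per-origin dosages
follow Hardy–Weinberg proportions at each MAF; cells draw an origin (or
an origin pair, at `doublet_rate` = 0.05); depth is Poisson(`coverage`,
default 2) per cell and variant and alt reads binomial under the same
error model the demultiplexer assumes. Doublets are genetic only — their
expression is not simulated — matching the mosaic-doublet definition.

Both generators are bit-deterministic under a fixed seed.

## Evaluation

AUC is the rank-based (Mann–Whitney) statistic with midranks for ties;
AUCPR is the step-summation (average-precision) form, since trapezoidal
interpolation on precision–recall curves is biased upward; F1 is
2PR/(P+R) with the 0-when-undefined convention (warned). `benchmark`
repeats a pipeline over independently seeded replicates and tabulates
per-replicate and mean metrics.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
the expression benchmark uses the generator defaults (2000 query cells,
1000 reference cells, 5 replicates), the demultiplexing benchmark 200
cells x 500 SNPs x 5 replicates, both with PCA embeddings. All randomness
flows from explicit seeds; reruns of the same configuration are
byte-identical, including the pipeline's output files (the manifest
records the configuration and seed needed to reproduce a run).

## Known limitations

- The blood/tissue step assumes the whole-blood reference is itself free
  of tissue-resident contamination and that each processed cell type
  genuinely contains both compartments; a type that is entirely blood or
  entirely tissue will still be split in two (k-means with k=2 always
  produces two clusters when it can).
- The latent-distance criterion measures "distal from the blood
  reference", which is evidence of tissue residency, not proof.
- Demultiplexing accuracy degrades with coverage and with the number of
  discriminating variants; N > 2 origins are supported by index only
  (anchor-based biological labeling is defined for N = 2).
- The expression generator's low-rank latent model is a simplification;
  see above for what passing tests does and does not show.
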