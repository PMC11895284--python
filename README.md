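# scorigin

Separate barcoded single cells from scRNA-seq of heterogeneous tissues along
two axes of origin:

1. **Blood vs. expected tissue-resident context.** Solid tissues contain
   blood vessels, so dissociated samples carry blood immune cells alongside
   genuinely tissue-resident cells of the same types (T-cells, NK cells,
   macrophages, ...). Their expression profiles are highly similar, which
   biases differential expression, enrichment and cell–cell-communication
   analyses when the compartments are mixed.
2. **Genetic origin.** Some tissues pool cells from more than one
   individual — maternal and fetal cells in placenta being the canonical
   case — and the individuals can be separated from the allele content of
   the reads alone, without external genotypes.

## Methods in brief

**Blood/tissue classifier.** For each immune cell type, query cells and a
whole-blood scRNA-seq reference are normalized (counts-per-10k, log1p),
restricted to shared highly variable genes and embedded jointly into a
*d*-dimensional latent space (*d* = 10: z-scaled PCA, optionally followed by
UMAP). Each query cell *i* is summarized by its **distance profile**
$D_{ij} = \lVert x_i - r_j \rVert_2$, its Euclidean distances to every
reference cell *j*. k-means with *k* = 2 on the profile rows splits the
cells; the cluster with the smaller mean reference distance is called
**blood**, the other **expected tissue-resident**.

**Genotype demultiplexer.** Variants with population minor allele frequency
above a threshold (default 10%) are removed, since rare variants carry the
identity signal. Reads are modeled per variant as Bernoulli draws with
alternate-allele probability $p_v = d_v(1-\varepsilon) + (1-d_v)\varepsilon$,
where $d_v \in \{0, \tfrac12, 1\}$ is the diploid dosage and
$\varepsilon$ the error rate. An EM algorithm fits an *N*-origin mixture
(default *N* = 2) over per-origin dosage vectors and mixing weights;
**mosaic doublets** (one barcode with a ~50/50 genetic mixture of two
individuals) are then scored against pairwise-averaged dosage profiles and
called by posterior probability. With two origins, a cell type of known
origin (e.g., trophoblasts are fetal) anchors the biological labels.

A synthetic-data module generates expression mixtures and allele-count
datasets with planted ground truth, and an evaluation module provides
rank-based AUC, F-score, step-summation AUCPR and a replication harness, so
the whole pipeline is testable offline.

## Worked example

```sh
python examples/blood_tissue_separation.py
```

```
query: 2000 cells, reference: 1000 cells
type0: AUC vs planted truth = 0.979
type1: AUC vs planted truth = 0.986
type2: AUC vs planted truth = 0.989
type3: AUC vs planted truth = 0.984
macro-F1 over blood/tissue = 0.964
mean AUC = 0.985
```

Four immune cell types, 250 cells per type per compartment, tissue cells
shifted five within-population SDs from blood cells in latent space. The
per-type AUC ranks cells by mean distance to the whole-blood reference
against the planted compartment: values near 1 mean tissue-resident cells
sit almost perfectly farther from the reference than blood cells, and the
macro-F1 scores the final hard blood/tissue calls.

`examples/genotype_demultiplexing.py` does the same for the genetic axis
(singlet accuracy 1.000, doublet recall 1.000 on the default two-origin
pool), and `examples/full_pipeline_cli.py` drives both stages through the
file-based interface.

From a shell, the same stages are available as subcommands:

```sh
scorigin simulate expression --seed 1 --out data/
scorigin bloodtissue --query data/query --annotations data/truth.tsv \
    --reference data/reference --out calls.tsv
scorigin demux --counts counts.tsv --nsample 2 --max-maf 10 --out demux.tsv
scorigin run --config run.yaml
```

## Layout

- `src/scorigin/io.py` — Cell Ranger v3 matrix directories, annotation and
  allele-count TSVs
- `src/scorigin/preprocess.py` — normalization, HVG selection, joint
  PCA/UMAP embedding
- `src/scorigin/blood_tissue.py` — distance profiles, profile clustering,
  compartment labeling
- `src/scorigin/demux.py` — SNP filtering, genotype-mixture EM, doublet
  and origin calling
- `src/scorigin/synthetic.py` — ground-truth generators
- `src/scorigin/metrics.py` — AUC / F-score / AUCPR and the benchmark
  harness
- `src/scorigin/pipeline.py`, `src/scorigin/cli.py` — orchestration and
  the `scorigin` command

See `docs/methods.md` for model details, parameter defaults and known
limitations.
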