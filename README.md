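# asvembed

Embedding transformation matrices for 16S rRNA (V4) gut-microbiome
count tables.

## The problem

Microbiome survey studies pair small sample sizes with enormous,
sparse feature spaces: tens of thousands of amplicon sequence variants
(ASVs) observed across a few hundred stool samples. Classifiers
trained on one study's ASV counts routinely fail on another study's —
the two studies literally observe different feature sets, and models
latch onto study-specific taxa. `asvembed` addresses this by learning
a **features × dimensions transformation matrix** from a large
reference survey and projecting *any* V4 count table into that shared
low-dimensional space, so that models can learn community-level
patterns that transfer across cohorts.

Two kinds of matrices are supported:

* **GloVe** — each sample is treated as a "sentence" whose tokens are
  the ASVs present in it; a global ASV×ASV co-occurrence matrix
  `X` is factorized by minimizing the weighted least-squares objective

  ```
  J = Σ_{ij : X_ij > 0}  f(X_ij) · (w_i·w̃_j + b_i + b̃_j − ln X_ij)²,
  f(x) = (x/x_max)^α  for x < x_max, else 1
  ```

  with seeded AdaGrad updates; the final ASV vector is `w + w̃`.
* **PCA** — each ASV count vector is standardized (mean 0, variance 1)
  and the top-k right singular vectors `V` of the sample×ASV matrix
  form the matrix columns; the per-ASV center/scale is stored so
  queries are standardized identically at projection time.

Projecting a new study (the transform every external cohort goes
through): align its ASV sequences against the reference set, keep per
query only the best hit(s) — lowest E-value, then highest percent
identity, then longest alignment, subject to `E ≤ 1e-40` and a
percent-identity floor (97 by default) — relabel query features with
their hit IDs splitting counts evenly among ties (queries with no hit
or with more than 100 exactly tied hits are dropped), prune unused
matrix rows, asinh-normalize (`asinh x = ln(x + √(x²+1))`, a log-like
transform needing no pseudocount), and matrix-multiply.

Downstream, `asvembed` reproduces the cross-study benchmark design
(random forest, 100 trees, depth capped at ⌈√p⌉, classes weighted
inversely to their training priors `w_c = N/N_c`, train on one cohort
/ test on another, precision–recall–F1 reporting) and the
pathway-interpretation step (pathway×gene · gene×ASV → ASV×pathway,
Spearman-correlated against the matrix columns).

## Worked example

Everything below runs on synthetic data generated by the package
itself (no downloads):

```bash
asvembed make-fixtures --out fixtures/ --seed 3 --preset tiny
asvembed fit-pca   --counts fixtures/reference_counts.tsv --dim 5 --out pca.tsv
asvembed fit-glove --counts fixtures/reference_counts.tsv --dim 5 --epochs 10 \
                   --seed 1 --out glove.tsv
asvembed embed --queries fixtures/queries.fasta \
               --counts fixtures/cohort_a_query_counts.tsv \
               --matrix pca.tsv --reference fixtures/reference.fasta \
               --out embedded.tsv --report report.json
```

The `embed` step prints

```
aligned 10/10 queries (100.0%) -> embedded.tsv
```

meaning every query ASV (a 1%-mutated variant of a reference ASV)
cleared the E ≤ 1e-40 / identity ≥ 97% best-hit filter and was
relabeled onto its source; `embedded.tsv` holds the 40 samples × 5
dimensions coordinates and `report.json` the per-cohort alignment
statistics (alignment rate, mean/median tied subjects per query, max
accepted E-value, min accepted alignment length).

From Python, the same pipeline is three calls:

```python
from asvembed import read_count_table, fit_pca, embed_dataset, read_fasta

table = read_count_table("fixtures/reference_counts.tsv")
matrix = fit_pca(table, dim=5)
embedded, report = embed_dataset(
    read_fasta("fixtures/queries.fasta"),
    read_count_table("fixtures/cohort_a_query_counts.tsv"),
    read_fasta("fixtures/reference.fasta"),
    matrix,
)
```

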