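# Methods

## Embedding construction

### Prevalence and blocklist filtering

`filter_prevalence(table, min_samples=10)` keeps a feature only if it
has a nonzero count in *strictly more than* `min_samples` samples, so
the default removes ASVs detected in 10 or fewer samples. Blocklist
removal drops features whose nucleotide sequence exactly matches a
supplied set (e.g. known bloom sequences); the two filters commute and
their order is the caller's choice.

### Co-occurrence corpus and GloVe

The corpus has one line per sample listing the IDs of the features
with nonzero counts — presence, not abundance, defines membership,
because token order within a sample is arbitrary. All-zero samples
keep their (empty) lines so the line count always equals the sample
count. Co-occurrence counting defaults to a whole-line window:
`X_ij` (i ≠ j) is the number of samples containing both features.
A finite window with 1/distance weighting is available for
compatibility with text-style corpora but is meaningless for samples,
where position carries no information; the diagonal is always
excluded.

GloVe minimizes

    J = Σ_{ij: X_ij>0} f(X_ij) (w_i·w̃_j + b_i + b̃_j − ln X_ij)²

with f(x) = (x/x_max)^α capped at 1, by AdaGrad stochastic updates
over all ordered nonzero pairs (symmetric treatment of the main and
context roles), shuffled each epoch by the seeded generator.
Defaults follow the reference GloVe implementation: `x_max=100`,
`α=0.75`, initial learning rate 0.05, 50 epochs, uniform
(−0.5, 0.5)/(dim+1) initialization, AdaGrad accumulators started at 1.
`loss_history[0]` is the objective at initialization and entry *e* the
objective after epoch *e*, evaluated exactly (vectorized over the
nonzero pairs) rather than accumulated during updates. The exported
per-feature vector is `w + w̃`, the summed-representation convention.
The fit is deterministic to the last bit for a fixed seed.

### PCA

Counts are standardized per feature (mean 0, variance 1, `ddof=1`) and
the top-k right singular vectors of the standardized sample×feature
matrix become the matrix columns, ordered by nonincreasing singular
value. A zero-variance feature is an error naming the feature, not a
silent drop. The per-feature center and scale are stored in the
matrix metadata so query tables can be standardized identically before
projection. `pre_asinh=True` applies the asinh transform before
standardization; this is the recommended setting whenever the
downstream projection normalizes counts, since it keeps the stored
center/scale on the same scale as the values they are subtracted from.

Sign ambiguity of singular vectors is resolved by making each column's
largest-magnitude entry nonnegative (idempotent, applied to all PCA
output), so results are reproducible across linear-algebra backends.

## Query transform

The best-hit filter applies the E-value ceiling (default 1e-40) and
percent-identity floor (default 97) *before* ranking, then keeps the
set of hits exactly tied on the lexicographic key (E-value ascending,
percent identity descending, alignment length descending). Exact
equality defines a tie — no tolerance — for reproducibility. A query
with more than `max_ties` (default 100, strict) tied best subjects is
dropped, as is a query with no surviving hit. Counts of an assigned
query are split evenly (weight 1/k among k tied subjects); relabeled
columns accumulate over queries; matrix rows never used as a top hit
are pruned. With normalization on, asinh is applied to the relabeled
counts before the matrix product, keeping embedded features on the
scale the matrices were learned from (a `--no-normalize-pre` escape
hatch exists).

### Alignment engines

`engine="external_blast"` shells out to `makeblastdb`/`blastn`
(`-outfmt 6 -dust no`). `engine="builtin"` performs exact local
alignment (Biopython's `PairwiseAligner`: match +1, mismatch −2, gap
open −2, gap extend −1) restricted to sequence pairs sharing at least
one 11-mer, reporting percent identity = identities / alignment
columns × 100 and a Karlin–Altschul E-value surrogate
`E = K·m·n·e^(−λS)` with fixed constants λ = 1.28, K = 0.46 (m = query
length, n = total reference length). The two engines satisfy the same
downstream contract — threshold filtering, tie structure, relabeling —
but are not numerically identical; BLAST+ is the fidelity path for
real data, the builtin engine removes the external dependency for
desk-scale work. Local alignment trims terminal mismatches (as BLAST
does), so a mutation in the first or last base raises reported
identity slightly; identity thresholds are interpreted on the aligned
region.

## Benchmarking

Features are asinh-normalized; the forest uses 100 trees, per-tree
depth capped at ⌈√p⌉ (ceiling avoids a zero cap at p = 1; whether the
original rule floored or ceiled is not determinable, and the
difference is one level), class weights `N/N_c` for both classes (a
`neg_weight_one` flag pins the negative class at exactly 1, matching
the convention of quoting only the positive upweighting), scikit-learn
defaults for bootstrap and feature subsampling (recorded choice), and
hard labels at the 0.5 vote threshold. Precision, recall and F1 are
computed from the confusion counts by their defining formulas with the
0/0 case mapped to 0. Train and test cohorts must have disjoint
sample IDs (leakage guard); no test information reaches the fit.

## Pathway interpretation

`pathway_abundance` computes C = (pathway×gene · gene×ASV)ᵀ after an
inner join on genes, so C[asv, pathway] sums the predicted copy
numbers of the pathway's genes in that ASV. `correlate_dimensions`
Spearman-correlates C's pathway columns with the embedding matrix
columns over the shared ASVs (inner join, ≥ 3 required), with average
ranks for ties. Constant columns yield NaN and are reported, never
silently dropped. No multiple-testing correction is applied — the
output is an interpretation aid, not a hypothesis test.

## Synthetic data generators

`CommunityModel` draws block-structured communities: each sample
activates each block independently (probability 0.5), members of an
active block are present with probability 0.9, others 0.05, and
present taxa get log-normal abundances (μ = 2, σ = 1 on the log scale,
right-skewed like amplicon counts). Sequences are uniform random
253-mers — the merged V4 amplicon length — which keeps unrelated pairs
far below any identity threshold; queries are derived by i.i.d.
per-base substitution at a configurable rate, with the query→source
truth table returned so alignment recall is measurable.

`make_phenotype_cohorts` generates the cross-study setting: case
probability is logistic (slope 2.5) in the standardized asinh-total
abundance of one *effect block*, so the phenotype signal is spread
across a co-occurring group rather than carried by a single taxon.
Batch structure then differs between cohorts in two ways. First,
per-taxon *detection efficiencies* are drawn once per cohort from a
Beta distribution with mean 0.8 (concentration 10) and each nonzero
count survives detection with its taxon's efficiency — the mean
mirrors the 80–90% cross-study alignment rates typical of V4 data,
and the smooth thinning is closer to real primer/extraction batch
effects than all-or-nothing censoring. Second, four always-detected
nuisance taxa (one from each of four non-effect blocks, the same taxa
in both cohorts) receive a label-linked multiplicative shift
`e^(±1.5)` whose direction is opposite in the two cohorts, so their
apparent phenotype association anti-transfers: a per-taxon classifier
that learns them in one cohort is actively misled in the other.
Pathway tables plant dedicated gene sets for chosen pathways with
elevated copy numbers in one block's taxa over a Poisson background.

What these generators do *not* emulate: phylogenetic sequence
similarity (mutated queries aside, taxa are unrelated), compositional
(closed-sum) effects, overdispersed sequencing depth per sample,
chimeras and contaminants. Passing tests therefore demonstrate that
the algorithms recover the structures they target under a clean
generative model, not performance on real amplicon data.

## The generalization study

The replicate study behind the headline comparison uses 16 blocks × 8
taxa (128 features) so the 50-dimension matrices are a genuine ~2.5×
compression — with features ≈ dimensions, a PCA loading matrix is
nearly a rotation and cannot dilute single-taxon nuisance signal,
which misrepresents the intended regime (tens of thousands of ASVs
into 50 dimensions). Per replicate: 300 reference samples, GloVe
(dim 50, 50 epochs) and PCA (dim 50, asinh-first) matrices refit from
scratch, two cohorts of 120 samples, the embedding paths run through
the full align→filter→relabel→prune→project pipeline at the default
97% filter, and the matched-count path relabels both cohorts at 100%
identity and keeps features observed in both. All three
representations share one forest seed per replicate. These sizes keep
a 10-replicate study around two minutes on one CPU while preserving
the feature-to-sample-size imbalance that drives the phenomenon.

Under these conditions the matched-count model's test F1 typically
lands below 0.2 — it learns the anti-transferring nuisance taxa, which
are the cleanest per-feature predictors in the training cohort — while
the 50-dimension models, whose representations dilute single-taxon
signal across block-level dimensions, typically reach 0.3–0.7 and beat
the matched-count model in at least 8 of 10 replicates for both GloVe
and PCA.

## Numerical choices and degenerate inputs

* Missing cells in tables are errors, never zeros; comma-separated
  files are rejected; negative counts and duplicate IDs are rejected
  at parse time.
* Embedding-matrix round trips are exact to 1e-12 (17-significant-
  digit TSV output).
* Ties in sign canonicalization resolve to the first index of the
  maximum absolute value.
* An all-zero co-occurrence matrix, a single-class label vector, an
  empty reference set, and a < 3-feature correlation overlap are all
  explicit errors.
* Seeds: every stochastic component (GloVe updates, generators,
  forests) takes an explicit seed and is bit-reproducible given it.

## Known limitations

* The builtin aligner is exact but quadratic per candidate pair; it is
  intended for reference sets up to a few thousand sequences. Use
  BLAST+ beyond that.
* GloVe training is a per-pair Python loop — fine for the corpus sizes
  here (≤ a few thousand features), not for 50k-feature surveys.
* The package consumes pathway×gene and gene×ASV tables as files; it
  does not query KEGG or run PICRUSt.
* Embedding matrices learned on one community/primer regime do not
  transfer to others; nothing in the code guards against projecting
  incompatible data beyond the alignment-rate report.
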