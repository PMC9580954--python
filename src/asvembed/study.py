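"""Desk-scale cross-cohort generalization study.

Orchestrates the full pipeline on synthetic cohorts: build GloVe and
PCA transformation matrices from a block-structured reference
community, project two phenotype cohorts (which share biology but
differ in taxon detection and batch-associated nuisance taxa) into
each embedding space, run the matched-count ("full") representation
alongside, and compare cross-cohort test F1 across replicate seeds.

The study conditions: 16 blocks of 8 taxa (so the 50-dim matrices are
a genuine compression of the 128-taxon feature space), 300 reference
samples, two cohorts of 120 samples, the default best-hit filter
(E <= 1e-40, identity >= 97, <= 100 ties) for the embedding paths and
a 100%-identity match for the full-count path.  The PCA matrix is fit
on asinh-transformed counts so its stored center/scale is on the same
scale as the normalized counts it is applied to at projection time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import CommunityModel, make_phenotype_cohorts, make_reference
from .io_formats import CountTable
from .ml_benchmark import (
    LabeledDataset,
    ModelConfig,
    asinh_normalize,
    benchmark_suite,
)
from .reference_builder import (
    GloveConfig,
    build_corpus,
    count_cooccurrences,
    fit_glove,
    fit_pca,
    glove_embedding,
)
from .transform import (
    BestHitFilterConfig,
    align_queries,
    embed_dataset,
    filter_best_hits,
    relabel_counts,
)

__all__ = ["GeneralizationStudyResult", "run_generalization_study"]


@dataclass
class GeneralizationStudyResult:
    """Per-seed test F1 per representation, plus win counts of the
    50-dim embedded models over the matched-count model."""

    f1: pd.DataFrame  # rows = replicate seeds, columns = representations
    wins: dict[str, int] = field(default_factory=dict)
    n_seeds: int = 0

    def win_fraction(self, name: str) -> float:
        return self.wins[name] / self.n_seeds


def _matched_count_features(cohort: LabeledDataset, hits) -> pd.DataFrame:
    """Relabel a cohort's counts onto reference IDs at 100% identity
    (best hits only, even splitting), mimicking the feature matching
    used for the non-embedded model."""
    cfg = BestHitFilterConfig(min_percent_identity=100.0)
    assignments = filter_best_hits(hits, cfg)
    counts = CountTable(cohort.features)
    relabeled = relabel_counts(counts, assignments)
    return relabeled.data


def run_generalization_study(
    seed: int,
    n_seeds: int = 10,
    dim: int = 50,
    model_template: CommunityModel | None = None,
    n_reference_samples: int = 300,
    n_per_cohort: int = 120,
    glove_epochs: int = 50,
) -> GeneralizationStudyResult:
    """Run the replicate-seed study comparing full vs 50-dim models.

    Each replicate regenerates the reference community, refits both
    transformation matrices, regenerates both cohorts, and trains on
    cohort A / tests on cohort B with the benchmark forest at an equal
    seed for every representation.
    """
    rows = []
    for rep in range(n_seeds):
        base = (seed * 1009 + rep * 131) % (2**31 - 1)
        model = (
            CommunityModel(
                n_blocks=16,
                taxa_per_block=8,
                seed=base,
            )
            if model_template is None
            else CommunityModel(
                n_blocks=model_template.n_blocks,
                taxa_per_block=model_template.taxa_per_block,
                within_block_presence_prob=model_template.within_block_presence_prob,
                between_block_presence_prob=model_template.between_block_presence_prob,
                block_on_prob=model_template.block_on_prob,
                abundance_scale=model_template.abundance_scale,
                seed=base,
            )
        )
        ref_seqs, ref_counts = make_reference(model, n_samples=n_reference_samples)

        corpus = build_corpus(ref_counts)
        X = count_cooccurrences(corpus, ref_counts.feature_ids)
        glove = glove_embedding(
            fit_glove(X, GloveConfig(dim=dim, epochs=glove_epochs, seed=base))
        )
        pca = fit_pca(ref_counts, dim=dim, pre_asinh=True)

        cohort_a, cohort_b = make_phenotype_cohorts(
            model, seeds=(base + 7, base + 8)
        )

        # Cohort taxa are the reference taxa; align once per study seed.
        hits = align_queries(ref_seqs, ref_seqs, engine="builtin")

        pairs = {}
        for name, matrix in (("glove_50", glove), ("pca_50", pca)):
            reps = []
            for cohort in (cohort_a, cohort_b):
                embedded, _ = embed_dataset(
                    ref_seqs,
                    CountTable(cohort.features),
                    ref_seqs,
                    matrix,
                    hits=hits,
                )
                reps.append(LabeledDataset(embedded.data, cohort.labels))
            pairs[name] = (reps[0], reps[1])

        fa = _matched_count_features(cohort_a, hits)
        fb = _matched_count_features(cohort_b, hits)
        # Keep only features observed in both cohorts, as matched-count
        # models require a shared feature space.
        shared = [
            c
            for c in fa.columns
            if c in set(fb.columns) and fa[c].sum() > 0 and fb[c].sum() > 0
        ]
        pairs["full"] = (
            LabeledDataset(
                pd.DataFrame(
                    asinh_normalize(fa[shared]), index=fa.index, columns=shared
                ),
                cohort_a.labels,
            ),
            LabeledDataset(
                pd.DataFrame(
                    asinh_normalize(fb[shared]), index=fb.index, columns=shared
                ),
                cohort_b.labels,
            ),
        )

        reports = benchmark_suite(pairs, ModelConfig(seed=base))
        rows.append({name: rep_pair["test"].f1 for name, rep_pair in reports.items()})

    f1 = pd.DataFrame(rows)
    wins = {
        name: int((f1[name] > f1["full"]).sum())
        for name in f1.columns
        if name != "full"
    }
    return GeneralizationStudyResult(f1=f1, wins=wins, n_seeds=n_seeds)
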