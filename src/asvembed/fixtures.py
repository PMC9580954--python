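"""Seeded synthetic-data generators with planted, recoverable structure.

These generators stand in for a large reference survey and its external
query cohorts: a block-structured community (groups of taxa that tend
to occur together), query ASVs that are point-mutated variants of
reference ASVs, phenotype cohorts whose label depends on a co-occurring
block's aggregate abundance while cohort-specific technical structure
(incomplete taxon detection, batch-associated nuisance taxa) differs
between cohorts, and pathway/gene tables with pathway signal planted in
a chosen block.  Every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountTable, SequenceSet, ValidationError
from .ml_benchmark import LabeledDataset

__all__ = [
    "CommunityModel",
    "QueryDerivation",
    "make_reference",
    "make_queries",
    "make_phenotype_cohorts",
    "make_pathway_tables",
]

_BASES = np.array(list("ACGT"))
_SEQ_LENGTH = 253  # merged V4 amplicon length


@dataclass
class CommunityModel:
    """Block co-occurrence community.

    Each sample activates each block independently with probability
    ``block_on_prob``; a taxon is then present with probability
    ``within_block_presence_prob`` if its block is active, else
    ``between_block_presence_prob``.  Present taxa receive log-normal
    abundances (mu=2, sigma=1 on the log scale, right-skewed like
    amplicon counts) times ``abundance_scale``.
    """

    n_blocks: int = 4
    taxa_per_block: int = 5
    within_block_presence_prob: float = 0.9
    between_block_presence_prob: float = 0.05
    block_on_prob: float = 0.5
    abundance_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.taxa_per_block < 1:
            raise ValidationError("block counts must be positive")
        for p in (
            self.within_block_presence_prob,
            self.between_block_presence_prob,
            self.block_on_prob,
        ):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.abundance_scale <= 0:
            raise ValidationError("abundance_scale must be positive")

    @property
    def n_taxa(self) -> int:
        return self.n_blocks * self.taxa_per_block

    def taxon_ids(self) -> list[str]:
        return [f"t{i:03d}" for i in range(self.n_taxa)]

    def block_of(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_blocks), self.taxa_per_block)


@dataclass
class QueryDerivation:
    """How query ASVs derive from reference ASVs: one source per query,
    i.i.d. per-base substitutions at ``mutation_rate``."""

    source_ids: list[str]
    mutation_rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 0.5:
            raise ValidationError("mutation_rate must lie in [0, 0.5)")


def _random_sequences(rng: np.random.Generator, ids: list[str]) -> SequenceSet:
    seqs = {
        sid: "".join(rng.choice(_BASES, size=_SEQ_LENGTH)) for sid in ids
    }
    return SequenceSet(seqs)


def _draw_counts(
    model: CommunityModel, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    block_of = model.block_of()
    counts = np.zeros((n_samples, model.n_taxa))
    for s in range(n_samples):
        block_on = rng.random(model.n_blocks) < model.block_on_prob
        p_present = np.where(
            block_on[block_of],
            model.within_block_presence_prob,
            model.between_block_presence_prob,
        )
        present = rng.random(model.n_taxa) < p_present
        abundance = np.rint(
            np.exp(rng.normal(2.0, 1.0, model.n_taxa)) * model.abundance_scale
        )
        counts[s] = present * np.maximum(abundance, 1)
    return counts


def make_reference(
    model: CommunityModel, n_samples: int = 300
) -> tuple[SequenceSet, CountTable]:
    """Reference community: random 253-bp ASV sequences (pairwise far
    below any alignment threshold) and a block-structured count table."""
    rng = np.random.default_rng(model.seed)
    ids = model.taxon_ids()
    seqs = _random_sequences(rng, ids)
    counts = _draw_counts(model, n_samples, rng)
    table = CountTable(
        pd.DataFrame(
            counts, index=[f"ref_s{i:04d}" for i in range(n_samples)], columns=ids
        )
    )
    return seqs, table


def make_queries(
    reference: SequenceSet, deriv: QueryDerivation
) -> tuple[SequenceSet, dict[str, str]]:
    """Point-mutated query variants plus the query -> source truth table."""
    rng = np.random.default_rng(deriv.seed)
    queries: dict[str, str] = {}
    truth: dict[str, str] = {}
    for k, src in enumerate(deriv.source_ids):
        if src not in reference:
            raise ValidationError(f"unknown source reference ID {src!r}")
        seq = np.array(list(reference[src]))
        if deriv.mutation_rate > 0:
            mutate = rng.random(seq.size) < deriv.mutation_rate
            for pos in np.where(mutate)[0]:
                choices = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = choices[rng.integers(3)]
        qid = f"q{k:03d}"
        queries[qid] = "".join(seq)
        truth[qid] = src
    return SequenceSet(queries), truth


def make_phenotype_cohorts(
    model: CommunityModel,
    effect_block: int = 0,
    n_per_cohort: int = 120,
    nuisance_strength: float = 1.5,
    seeds: tuple[int, int] = (1, 2),
    effect_size: float = 2.5,
    detection_prob: float = 0.8,
    detection_concentration: float = 10.0,
    n_nuisance: int = 4,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Two cohorts sharing biology but not technical structure.

    Case probability is logistic in the standardized asinh-total
    abundance of the effect block, so the signal is spread across a
    co-occurring group of taxa rather than carried by any single one.
    Each cohort then gets its own batch structure:

    * per-taxon *detection efficiencies* drawn once per cohort from a
      Beta distribution with mean ``detection_prob`` and concentration
      ``detection_concentration``; each nonzero count survives with its
      taxon's efficiency, so the two cohorts observe systematically
      different slices of the same community (the mean mirrors typical
      cross-study alignment rates of roughly 80%);
    * ``n_nuisance`` always-detected nuisance taxa (one from each of
      ``n_nuisance`` non-effect blocks, the same taxa in both cohorts)
      receive a label-linked multiplicative shift ``exp(±strength)``
      whose direction is *opposite* in the two cohorts, so their
      apparent phenotype association anti-transfers — the batch-effect
      mechanism that defeats per-taxon classifiers.

    With ``nuisance_strength=0`` and ``detection_prob=1`` the cohorts
    are exchangeable draws from the same generative model.
    """
    if not 0 <= effect_block < model.n_blocks:
        raise ValidationError(f"effect block {effect_block} does not exist")
    block_of = model.block_of()

    # Batch design shared by the cohort pair: which taxa are nuisance
    # and which direction cohort A shifts them (cohort B flips).
    shared_rng = np.random.default_rng((seeds[0] * 31 + seeds[1]) % (2**31 - 1))
    other_blocks = [b for b in range(model.n_blocks) if b != effect_block]
    nuisance_blocks = shared_rng.choice(
        other_blocks, size=min(n_nuisance, len(other_blocks)), replace=False
    )
    nuisance_cols = [
        int(shared_rng.choice(np.where(block_of == b)[0])) for b in nuisance_blocks
    ]
    base_signs = shared_rng.choice([-1.0, 1.0], size=len(nuisance_cols))

    datasets = []
    for cohort_index, (name, seed) in enumerate(zip(("A", "B"), seeds)):
        rng = np.random.default_rng(seed)
        counts = _draw_counts(model, n_per_cohort, rng)

        effect_cols = np.where(block_of == effect_block)[0]
        z = np.arcsinh(counts[:, effect_cols].sum(axis=1))
        z = (z - z.mean()) / (z.std() or 1.0)
        p_case = 1.0 / (1.0 + np.exp(-effect_size * z))
        labels = (rng.random(n_per_cohort) < p_case).astype(int)

        signs = base_signs if cohort_index == 0 else -base_signs
        for col, sign in zip(nuisance_cols, signs):
            absent = counts[:, col] == 0
            counts[absent, col] = np.maximum(
                np.rint(np.exp(rng.normal(2.0, 1.0, int(absent.sum())))), 1
            )
            shift = np.exp(sign * nuisance_strength * (2 * labels - 1))
            counts[:, col] = np.rint(counts[:, col] * shift)

        # Incomplete, cohort-specific detection of everything else:
        # thin each taxon's nonzero counts at its cohort efficiency.
        if detection_prob < 1.0:
            efficiency = rng.beta(
                detection_prob * detection_concentration,
                (1.0 - detection_prob) * detection_concentration,
                model.n_taxa,
            )
        else:
            efficiency = np.ones(model.n_taxa)
        efficiency[nuisance_cols] = 1.0
        detected = rng.random(counts.shape) < efficiency[None, :]
        counts = counts * detected

        index = pd.Index([f"{name}_s{i:04d}" for i in range(n_per_cohort)])
        features = pd.DataFrame(counts, index=index, columns=model.taxon_ids())
        datasets.append(LabeledDataset(features, pd.Series(labels, index=index)))
    return datasets[0], datasets[1]


def make_pathway_tables(
    taxon_ids: list[str],
    model: CommunityModel,
    planted: dict[str, int],
    n_genes: int = 40,
    n_background_pathways: int = 8,
    genes_per_planted: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary pathway x gene and nonnegative gene x ASV tables.

    Each planted pathway gets a dedicated disjoint gene set whose
    predicted copy numbers are concentrated in its mapped block's taxa;
    background pathways draw random gene memberships and background
    genes carry low uniform copy numbers everywhere.
    """
    for pathway, block in planted.items():
        if not 0 <= block < model.n_blocks:
            raise ValidationError(f"planted pathway {pathway!r} maps to missing block")
    needed = len(planted) * genes_per_planted
    if needed > n_genes:
        raise ValidationError("not enough genes for the planted pathways")
    rng = np.random.default_rng(seed)
    genes = [f"K{g:05d}" for g in range(n_genes)]
    pathways = list(planted) + [f"ko_bg{i:02d}" for i in range(n_background_pathways)]

    pg = np.zeros((len(pathways), n_genes), dtype=int)
    planted_gene_idx: dict[str, np.ndarray] = {}
    cursor = 0
    for p, pathway in enumerate(planted):
        idx = np.arange(cursor, cursor + genes_per_planted)
        planted_gene_idx[pathway] = idx
        pg[p, idx] = 1
        cursor += genes_per_planted
    for p in range(len(planted), len(pathways)):
        membership = rng.random(n_genes - needed) < 0.3
        pg[p, needed:] = membership.astype(int)

    block_of = model.block_of()
    ga = rng.poisson(1.0, size=(n_genes, len(taxon_ids))).astype(float)
    for pathway, block in planted.items():
        in_block = np.where(block_of == block)[0]
        for g in planted_gene_idx[pathway]:
            ga[g, in_block] += rng.poisson(8.0, size=in_block.size) + 5.0

    pg_df = pd.DataFrame(pg, index=pathways, columns=genes)
    ga_df = pd.DataFrame(ga, index=genes, columns=list(taxon_ids))
    return pg_df, ga_df
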