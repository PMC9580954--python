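"""Project a query ASV count table into an embedding space.

The pipeline mirrors the transform applied to every external cohort:

1. align query ASV sequences against the reference ASVs behind the
   embedding matrix (external BLAST+ or the builtin aligner);
2. keep, per query, only the best hit(s) — lowest E-value, then highest
   percent identity, then longest alignment — after discarding hits
   above the E-value ceiling or below the identity floor;
3. relabel query features with their hit IDs, splitting a query's
   counts evenly among tied best hits; queries with no surviving hits,
   or more than ``max_ties`` exactly tied hits, contribute nothing;
4. prune embedding-matrix rows never used as a top hit;
5. multiply the relabeled (optionally asinh-normalized) count table by
   the embedding matrix.

The builtin aligner performs exact local alignment (match +1, mismatch
-2, gap open -2, gap extend -1) restricted to sequence pairs sharing at
least one 11-mer, and reports a Karlin-Altschul E-value surrogate
E = K * m * n * exp(-lambda * S) with fixed constants lambda = 1.28 and
K = 0.46.  It satisfies the same downstream contract as BLAST without
being numerically identical to it.
"""

from __future__ import annotations

import math
import shutil
import statistics
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import (
    AlignmentHit,
    CountTable,
    EmbeddingMatrix,
    SequenceSet,
    ValidationError,
    read_alignment_tabular,
    write_fasta,
)

__all__ = [
    "BestHitFilterConfig",
    "HitAssignment",
    "EmbeddedTable",
    "align_queries",
    "filter_best_hits",
    "relabel_counts",
    "prune_embedding",
    "project",
    "embed_dataset",
]

# Builtin-aligner constants (documented, fixed).
_LAMBDA = 1.28
_K = 0.46
_WORD_SIZE = 11


@dataclass
class BestHitFilterConfig:
    """Thresholds for best-hit selection.

    ``max_evalue`` and ``min_percent_identity`` are applied before the
    per-query best-hit ranking; a query whose tied best set exceeds
    ``max_ties`` hits is dropped entirely (specificity guard).
    """

    max_evalue: float = 1e-40
    min_percent_identity: float = 97.0
    max_ties: int = 100

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValidationError("max_evalue must be positive")
        if not 0 <= self.min_percent_identity <= 100:
            raise ValidationError("min_percent_identity outside [0, 100]")
        if self.max_ties < 1:
            raise ValidationError("max_ties must be at least 1")


@dataclass(frozen=True)
class HitAssignment:
    """The tied best reference subjects for one query, equally weighted."""

    query_id: str
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.subject_ids:
            raise ValidationError("assignment must have at least one subject")

    @property
    def weight(self) -> float:
        return 1.0 / len(self.subject_ids)


@dataclass
class EmbeddedTable:
    """Samples x embedding-dimensions coordinates, with provenance."""

    data: pd.DataFrame
    provenance: dict

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def dims(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _builtin_align(queries: SequenceSet, reference: SequenceSet) -> list[AlignmentHit]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1

    index: dict[str, set[str]] = {}
    for rid, rseq in reference.items():
        for kmer in _kmers(rseq, _WORD_SIZE):
            index.setdefault(kmer, set()).add(rid)

    total_ref_length = sum(len(s) for s in reference.sequences.values())
    hits: list[AlignmentHit] = []
    for qid, qseq in queries.items():
        candidates: set[str] = set()
        for kmer in _kmers(qseq, _WORD_SIZE):
            candidates.update(index.get(kmer, ()))
        for rid in sorted(candidates):
            alignments = aligner.align(qseq, reference[rid])
            best = alignments[0]
            if best.score <= 0:
                continue
            c = best.counts()
            length = c.identities + c.mismatches + c.gaps
            if length == 0:
                continue
            evalue = _K * len(qseq) * total_ref_length * math.exp(-_LAMBDA * best.score)
            bitscore = (_LAMBDA * best.score - math.log(_K)) / math.log(2.0)
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=rid,
                    percent_identity=100.0 * c.identities / length,
                    alignment_length=int(length),
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


def _external_blast(queries: SequenceSet, reference: SequenceSet) -> list[AlignmentHit]:
    if shutil.which("makeblastdb") is None or shutil.which("blastn") is None:
        raise FileNotFoundError(
            "BLAST+ binaries (makeblastdb/blastn) not found on PATH; "
            "use engine='builtin' instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp)
        ref_fa = write_fasta(reference, tmp_path / "reference.fasta")
        qry_fa = write_fasta(queries, tmp_path / "queries.fasta")
        db = tmp_path / "refdb"
        subprocess.run(
            ["makeblastdb", "-in", str(ref_fa), "-dbtype", "nucl", "-out", str(db)],
            check=True,
            capture_output=True,
        )
        out = tmp_path / "hits.tsv"
        subprocess.run(
            [
                "blastn",
                "-query",
                str(qry_fa),
                "-db",
                str(db),
                "-outfmt",
                "6",
                "-dust",
                "no",
                "-out",
                str(out),
            ],
            check=True,
            capture_output=True,
        )
        return read_alignment_tabular(out)


def align_queries(
    queries: SequenceSet,
    reference: SequenceSet,
    engine: str = "builtin",
) -> list[AlignmentHit]:
    """All alignment hits of each query against the reference set.

    ``engine='external_blast'`` shells out to makeblastdb/blastn;
    ``engine='builtin'`` uses the documented exact local aligner.  The
    two engines satisfy the same downstream contract but do not produce
    identical numbers.
    """
    if len(reference) == 0:
        raise ValidationError("reference sequence set is empty")
    if engine == "builtin":
        return _builtin_align(queries, reference)
    if engine in ("external_blast", "blast"):
        return _external_blast(queries, reference)
    raise ValueError(f"unknown alignment engine {engine!r}")


# ---------------------------------------------------------------------------
# Best-hit filtering
# ---------------------------------------------------------------------------


def filter_best_hits(
    hits: Sequence[AlignmentHit], cfg: BestHitFilterConfig | None = None
) -> list[HitAssignment]:
    """Per query, keep the set of hits exactly tied on the best
    (E-value asc, percent identity desc, alignment length desc) key.

    Hits above ``max_evalue`` or below ``min_percent_identity`` are
    discarded first.  Queries with no surviving hit, or with strictly
    more than ``max_ties`` tied best hits, yield no assignment.  Exact
    equality, not a tolerance, defines a tie.
    """
    cfg = cfg or BestHitFilterConfig()
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)

    assignments: list[HitAssignment] = []
    for qid, qhits in by_query.items():
        survivors = [
            h
            for h in qhits
            if h.evalue <= cfg.max_evalue
            and h.percent_identity >= cfg.min_percent_identity
        ]
        if not survivors:
            continue
        best_key = min(
            (h.evalue, -h.percent_identity, -h.alignment_length) for h in survivors
        )
        tied = [
            h
            for h in survivors
            if (h.evalue, -h.percent_identity, -h.alignment_length) == best_key
        ]
        # A subject may appear in several tied HSPs; count it once.
        subjects: list[str] = []
        for h in tied:
            if h.subject_id not in subjects:
                subjects.append(h.subject_id)
        if len(subjects) > cfg.max_ties:
            continue
        assignments.append(HitAssignment(qid, tuple(subjects)))
    return assignments


# ---------------------------------------------------------------------------
# Relabeling, pruning, projection
# ---------------------------------------------------------------------------


def relabel_counts(
    table: CountTable, assignments: Sequence[HitAssignment]
) -> CountTable:
    """Relabel query features with their reference hit IDs.

    Each assigned query's counts are split evenly among its tied
    subjects; multiple queries mapping to the same subject accumulate.
    Unassigned queries contribute nothing.  Output feature order is the
    order in which subjects first appear across assignments.
    """
    missing = [a.query_id for a in assignments if a.query_id not in table.data.columns]
    if missing:
        raise ValidationError(f"assignments reference unknown query IDs: {missing[:5]}")
    subject_order: list[str] = []
    for a in assignments:
        for sid in a.subject_ids:
            if sid not in subject_order:
                subject_order.append(sid)
    out = np.zeros((table.shape[0], len(subject_order)))
    col = {sid: k for k, sid in enumerate(subject_order)}
    for a in assignments:
        counts = table.data[a.query_id].to_numpy(dtype=float)
        for sid in a.subject_ids:
            out[:, col[sid]] += counts * a.weight
    return CountTable(
        pd.DataFrame(out, index=table.data.index, columns=subject_order)
    )


def prune_embedding(
    matrix: EmbeddingMatrix, used_ids: Sequence[str]
) -> EmbeddingMatrix:
    """Restrict matrix rows to ``used_ids``, in that order."""
    missing = [u for u in used_ids if u not in matrix.data.index]
    if missing:
        raise ValidationError(
            f"IDs absent from embedding matrix: {missing[:5]}"
        )
    used = list(used_ids)
    return EmbeddingMatrix(
        matrix.data.loc[used],
        matrix.method,
        matrix.center.loc[used] if matrix.center is not None else None,
        matrix.scale.loc[used] if matrix.scale is not None else None,
    )


def project(
    table: CountTable, matrix: EmbeddingMatrix, normalize: bool = True
) -> EmbeddedTable:
    """Dot product of the (optionally asinh-normalized) count table with
    the embedding matrix.

    For PCA matrices the stored per-feature center/scale is applied
    after normalization so queries are standardized exactly as the
    reference was at fit time.  Feature order must already match.
    """
    if table.feature_ids != matrix.feature_ids:
        extra = set(table.feature_ids) ^ set(matrix.feature_ids)
        raise ValidationError(
            "count-table and embedding-matrix feature spaces differ "
            f"(unmatched or misordered IDs, e.g. {sorted(extra)[:5]})"
        )
    values = table.values()
    if normalize:
        values = np.arcsinh(values)
    if matrix.method == "pca":
        values = (values - matrix.center.to_numpy()) / matrix.scale.to_numpy()
    out = values @ matrix.values()
    return EmbeddedTable(
        pd.DataFrame(out, index=table.data.index, columns=matrix.dims),
        provenance={
            "method": matrix.method,
            "dim": matrix.dim,
            "normalize": normalize,
            "n_features": len(matrix.feature_ids),
        },
    )


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------


def embed_dataset(
    queries: SequenceSet,
    table: CountTable,
    reference: SequenceSet,
    matrix: EmbeddingMatrix,
    cfg: BestHitFilterConfig | None = None,
    engine: str = "builtin",
    normalize: bool = True,
    hits: Sequence[AlignmentHit] | None = None,
) -> tuple[EmbeddedTable, dict]:
    """Full query transform: align, filter, relabel, prune, project.

    A pre-computed hit list (outfmt-6 dialect) can be supplied to skip
    alignment.  Returns the embedded table and a report with the
    alignment statistics commonly summarized per cohort: query counts,
    alignment rate, mean/median tied subjects per aligned query, and
    the maximum E-value / minimum alignment length among accepted hits.
    """
    cfg = cfg or BestHitFilterConfig()
    if hits is None:
        hits = align_queries(queries, reference, engine=engine)
    assignments = filter_best_hits(hits, cfg)
    relabeled = relabel_counts(table, assignments)
    pruned = prune_embedding(matrix, relabeled.feature_ids)
    embedded = project(relabeled, pruned, normalize=normalize)
    embedded.provenance["filter"] = {
        "max_evalue": cfg.max_evalue,
        "min_percent_identity": cfg.min_percent_identity,
        "max_ties": cfg.max_ties,
    }

    assigned = {a.query_id for a in assignments}
    accepted = [
        h
        for h in hits
        if h.query_id in assigned
        and h.evalue <= cfg.max_evalue
        and h.percent_identity >= cfg.min_percent_identity
    ]
    subjects_per_query = [len(a.subject_ids) for a in assignments]
    report = {
        "n_queries": len(queries),
        "n_aligned": len(assignments),
        "alignment_rate": len(assignments) / len(queries) if len(queries) else 0.0,
        "mean_subjects_per_query": (
            float(np.mean(subjects_per_query)) if subjects_per_query else 0.0
        ),
        "median_subjects_per_query": (
            float(statistics.median(subjects_per_query)) if subjects_per_query else 0.0
        ),
        "max_evalue_accepted": max((h.evalue for h in accepted), default=None),
        "min_alignment_length_accepted": min(
            (h.alignment_length for h in accepted), default=None
        ),
        "n_reference_used": len(relabeled.feature_ids),
    }
    return embedded, report
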