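"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular artifacts are tab-separated with a header row and an ID
column; comma-separated files are rejected outright so that round trips
stay predictable.  Missing cells are errors, never silently zero-filled.

Feature identifiers may be the raw ASV nucleotide sequences themselves
(the convention used when building co-occurrence corpora) or opaque
short IDs resolvable through a companion FASTA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A file could not be parsed into the expected schema."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


_NUCLEOTIDES = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# Sequence sets (FASTA)
# ---------------------------------------------------------------------------


@dataclass
class SequenceSet:
    """An ordered mapping of unique IDs to uppercase A/C/G/T/N sequences."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"sequence {sid!r} is empty")
            bad = set(seq) - _NUCLEOTIDES
            if bad:
                raise ValidationError(
                    f"sequence {sid!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def items(self):
        return self.sequences.items()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self.sequences == other.sequences


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file, uppercasing sequences and checking uniqueness."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValidationError(f"duplicate FASTA id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(
                f"{path}: record {record.id!r} is a header without a sequence"
            )
        sequences[record.id] = seq
    return SequenceSet(sequences)


def write_fasta(seqs: SequenceSet, path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """A samples x features table of nonnegative real abundances.

    Counts may be fractional: downstream relabeling splits query counts
    evenly among tied reference hits.
    """

    data: pd.DataFrame  # index = sample IDs, columns = feature IDs

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dupes}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table contains non-numeric entries")
        if np.isnan(values).any():
            raise ValidationError("count table contains missing cells")
        if values.size and values.min() < 0:
            raise ValidationError("count table contains negative entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def _read_tsv_frame(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    if "\t" not in header and "," in header:
        raise ParseError(
            f"{path}: comma-separated input; only tab-separated tables are accepted"
        )
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_count_table(
    path: str | Path, orientation: str = "samples_in_rows"
) -> CountTable:
    """Read a TSV count table; the result is always samples x features.

    ``orientation`` declares the on-disk layout: ``samples_in_rows`` or
    ``features_in_rows`` (the latter is transposed on read).
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = _read_tsv_frame(path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r}, "
                f"row {df.index[bad.argmax()]!r}"
            )
        df[col] = coerced
    if orientation == "features_in_rows":
        df = df.T
    return CountTable(df.astype(float))


def write_count_table(
    table: CountTable, path: str | Path, orientation: str = "samples_in_rows"
) -> Path:
    path = Path(path)
    df = table.data if orientation == "samples_in_rows" else table.data.T
    df.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# Alignment hits (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    """One query-subject alignment with the fields the filter needs."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length <= 0:
            raise ValidationError("alignment length must be positive")
        if self.evalue < 0:
            raise ValidationError("E-value must be nonnegative")


_OUTFMT6_COLUMNS = 12


def read_alignment_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tab-separated alignment file (outfmt 6 order:
    qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
    sstart, send, evalue, bitscore).  Columns beyond the retained fields
    are ignored."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_OUTFMT6_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_alignment_tabular(hits: Sequence[AlignmentHit], path: str | Path) -> Path:
    """Write hits in the 12-column dialect.  Fields the hit does not carry
    (mismatch, gapopen, coordinates) are written as zeros."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            bitscore = 0.0 if h.bitscore is None else h.bitscore
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.3f}",
                        str(h.alignment_length),
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        f"{h.evalue:.3g}",
                        f"{bitscore:.1f}",
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Embedding transformation matrices
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingMatrix:
    """A reference-features x dimensions transformation matrix.

    ``method`` records how it was learned ("glove" or "pca").  PCA
    matrices carry the per-feature centering and scaling parameters used
    at fit time so that queries can be standardized identically before
    projection.
    """

    data: pd.DataFrame  # index = feature IDs, columns = dimension labels
    method: str
    center: pd.Series | None = None
    scale: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.method not in ("glove", "pca"):
            raise ValidationError(f"unknown embedding method {self.method!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate feature IDs in embedding matrix")
        if self.method == "pca":
            if self.center is None or self.scale is None:
                raise ValidationError(
                    "PCA embedding matrices require center and scale vectors"
                )
            if not self.center.index.equals(self.data.index) or not (
                self.scale.index.equals(self.data.index)
            ):
                raise ValidationError(
                    "center/scale index does not match matrix feature IDs"
                )
            if (self.scale.to_numpy() <= 0).any():
                raise ValidationError("PCA scale vector must be strictly positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def dims(self) -> list[str]:
        return list(self.data.columns)

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def write_embedding_matrix(
    matrix: EmbeddingMatrix, path: str | Path, meta_path: str | Path | None = None
) -> Path:
    """Write the matrix as TSV plus a YAML sidecar with method/center/scale.

    The sidecar defaults to ``<path>.meta.yaml``.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(path.suffix + ".meta.yaml")
    matrix.data.to_csv(path, sep="\t", float_format="%.17g")
    meta: dict = {"method": matrix.method, "dim": matrix.dim}
    if matrix.center is not None:
        meta["center"] = {k: float(v) for k, v in matrix.center.items()}
    if matrix.scale is not None:
        meta["scale"] = {k: float(v) for k, v in matrix.scale.items()}
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_embedding_matrix(
    path: str | Path, meta_path: str | Path | None = None
) -> EmbeddingMatrix:
    """Read a TSV embedding matrix and its YAML metadata sidecar.

    Without a sidecar the matrix loads as a bare GloVe-style matrix with
    no centering/scaling; a matrix claiming ``method: pca`` must supply
    both vectors.
    """
    path = Path(path)
    candidate = (
        Path(meta_path) if meta_path else path.with_suffix(path.suffix + ".meta.yaml")
    )
    df = _read_tsv_frame(path).astype(float)
    method = "glove"
    center = scale = None
    if candidate.exists():
        with open(candidate) as fh:
            meta = yaml.safe_load(fh) or {}
        method = meta.get("method", "glove")
        if "center" in meta:
            center = pd.Series(meta["center"], dtype=float).reindex(df.index)
            if center.isna().any():
                raise ValidationError(f"{candidate}: center vector missing features")
        if "scale" in meta:
            scale = pd.Series(meta["scale"], dtype=float).reindex(df.index)
            if scale.isna().any():
                raise ValidationError(f"{candidate}: scale vector missing features")
    elif meta_path is not None:
        raise FileNotFoundError(f"metadata sidecar {candidate} not found")
    return EmbeddingMatrix(df, method=method, center=center, scale=scale)
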