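"""Interpret embedding dimensions via metabolic-pathway potential.

A binary pathway x gene membership table multiplied by a gene x ASV
predicted-copy-number table yields an ASV x pathway "genetic potential"
matrix; Spearman-correlating its pathway columns against the embedding
matrix columns gives a pathway x dimension correlation matrix that maps
mathematically defined dimensions onto biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import EmbeddingMatrix, ValidationError

__all__ = ["pathway_abundance", "correlate_dimensions"]


def pathway_abundance(pg: pd.DataFrame, ga: pd.DataFrame) -> pd.DataFrame:
    """ASV x pathway genetic-potential matrix C = (pg . ga)^T.

    ``pg`` is a binary pathway x gene table; ``ga`` a nonnegative
    gene x ASV copy-number table.  Genes are reconciled by inner join;
    unmatched genes are dropped.  C[asv, pathway] sums the copy numbers
    of the pathway's genes in that ASV — higher values suggest higher
    presence of the pathway in the organism.
    """
    bad = set(np.unique(pg.to_numpy())) - {0, 1}
    if bad:
        raise ValidationError(f"pathway-gene table must be binary, found {sorted(bad)}")
    if ga.to_numpy().size and ga.to_numpy().min() < 0:
        raise ValidationError("gene-ASV table contains negative copy numbers")
    shared = [g for g in pg.columns if g in set(ga.index)]
    if not shared:
        raise ValidationError("no genes shared between pathway-gene and gene-ASV tables")
    return (pg[shared] @ ga.loc[shared]).T


def correlate_dimensions(
    C: pd.DataFrame, matrix: EmbeddingMatrix
) -> pd.DataFrame:
    """Pathway x dimension Spearman correlations over shared ASVs.

    Features are reconciled by inner join (at least 3 shared required).
    Ties receive average ranks; a constant column yields NaN for its
    pathway/dimension rather than being dropped.
    """
    shared = [f for f in C.index if f in set(matrix.data.index)]
    if len(shared) < 3:
        raise ValidationError(
            f"need at least 3 shared features for correlation, got {len(shared)}"
        )
    A = C.loc[shared].to_numpy(dtype=float)  # features x pathways
    B = matrix.data.loc[shared].to_numpy(dtype=float)  # features x dims

    def ranked(M: np.ndarray) -> np.ndarray:
        return np.apply_along_axis(rankdata, 0, M)

    Ra, Rb = ranked(A), ranked(B)
    Ra = Ra - Ra.mean(axis=0)
    Rb = Rb - Rb.mean(axis=0)
    sa = np.sqrt((Ra**2).sum(axis=0))
    sb = np.sqrt((Rb**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Ra.T @ Rb) / np.outer(sa, sb)
    return pd.DataFrame(rho, index=C.columns, columns=matrix.dims)
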