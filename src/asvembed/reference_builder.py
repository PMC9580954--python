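"""Build embedding transformation matrices from a reference count table.

Two routes produce a features x dimensions matrix from a large
sample x ASV count table:

* **GloVe** — treat each sample as a "sentence" whose tokens are the
  ASVs present in it, accumulate a global ASV-ASV co-occurrence matrix,
  and factorize it with the GloVe weighted least-squares objective

      J = sum_{ij : X_ij > 0} f(X_ij) (w_i . w~_j + b_i + b~_j - ln X_ij)^2

  with the capped weighting f(x) = (x / x_max)^alpha for x < x_max and
  1 otherwise, minimized by seeded AdaGrad stochastic updates.

* **PCA** — standardize each ASV count vector (mean 0, variance 1) and
  take the top right singular vectors of the sample x ASV matrix.

Both are preceded by prevalence filtering (drop ASVs detected in too
few samples) and optional blocklist removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CountTable,
    EmbeddingMatrix,
    SequenceSet,
    ValidationError,
)

__all__ = [
    "CooccurrenceMatrix",
    "GloveConfig",
    "GloveModel",
    "filter_prevalence",
    "remove_blocklist",
    "build_corpus",
    "count_cooccurrences",
    "fit_glove",
    "glove_loss",
    "glove_embedding",
    "fit_pca",
    "sign_canonicalize",
]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_prevalence(table: CountTable, min_samples: int = 10) -> CountTable:
    """Drop features detected in ``min_samples`` or fewer samples.

    A feature is retained only if it has a nonzero count in strictly
    more than ``min_samples`` samples.  The sample set is unchanged; the
    result may have zero features.
    """
    prevalence = (table.data.to_numpy() > 0).sum(axis=0)
    keep = prevalence > min_samples
    return CountTable(table.data.loc[:, table.data.columns[keep]])


def remove_blocklist(
    table: CountTable,
    blocklist: SequenceSet,
    sequences: SequenceSet | None = None,
) -> CountTable:
    """Drop features whose nucleotide sequence exactly matches a blocklist
    entry (e.g. known bloom sequences).

    When feature IDs are not themselves sequences, ``sequences`` maps
    feature IDs to their sequences.
    """
    blocked = set(blocklist.sequences.values())
    if not blocked:
        return table

    def resolve(fid: str) -> str:
        if sequences is not None and fid in sequences:
            return sequences[fid]
        return fid

    keep = [fid for fid in table.feature_ids if resolve(fid) not in blocked]
    return CountTable(table.data.loc[:, keep])


# ---------------------------------------------------------------------------
# Co-occurrence corpus
# ---------------------------------------------------------------------------


def build_corpus(table: CountTable) -> list[list[str]]:
    """One token line per sample, in sample order.

    A feature's ID appears on a sample's line iff its count is strictly
    positive; token order follows the table's column order.  All-zero
    samples yield empty lines, kept so the line count always equals the
    sample count.
    """
    features = np.asarray(table.feature_ids, dtype=object)
    present = table.data.to_numpy() > 0
    return [list(features[row]) for row in present]


def corpus_to_text(corpus: list[list[str]]) -> str:
    """Serialize a corpus as one space-separated line per sample."""
    return "\n".join(" ".join(line) for line in corpus) + "\n"


@dataclass
class CooccurrenceMatrix:
    """Symmetric nonnegative feature-feature co-occurrence weights."""

    feature_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        if self.X.shape != (n, n):
            raise ValidationError("co-occurrence matrix shape mismatch")
        if not np.allclose(self.X, self.X.T):
            raise ValidationError("co-occurrence matrix must be symmetric")
        if self.X.size and self.X.min() < 0:
            raise ValidationError("co-occurrence weights must be nonnegative")


def count_cooccurrences(
    corpus: list[list[str]],
    feature_ids: list[str],
    window: int | None = None,
) -> CooccurrenceMatrix:
    """Accumulate co-occurrence weights over a corpus.

    With ``window=None`` (whole-line, the default) X_ij for i != j is
    the number of lines on which features i and j both appear; token
    order within a line carries no information.  With a finite window,
    each ordered token pair within ``window`` positions contributes
    1/distance, the weighting convention of the GloVe software.  The
    diagonal is always zero.
    """
    index = {fid: k for k, fid in enumerate(feature_ids)}
    n = len(feature_ids)
    X = np.zeros((n, n))
    for line in corpus:
        try:
            idx = [index[tok] for tok in line]
        except KeyError as exc:
            raise ValidationError(f"corpus token {exc.args[0]!r} not in feature set")
        if window is None:
            uniq = sorted(set(idx))
            for a_pos, a in enumerate(uniq):
                for b in uniq[a_pos + 1 :]:
                    X[a, b] += 1.0
                    X[b, a] += 1.0
        else:
            for p, a in enumerate(idx):
                for q in range(p + 1, min(p + 1 + window, len(idx))):
                    b = idx[q]
                    if a == b:
                        continue
                    w = 1.0 / (q - p)
                    X[a, b] += w
                    X[b, a] += w
    return CooccurrenceMatrix(list(feature_ids), X)


# ---------------------------------------------------------------------------
# GloVe
# ---------------------------------------------------------------------------


@dataclass
class GloveConfig:
    """GloVe hyperparameters.

    Defaults follow the GloVe reference implementation: weighting cap
    ``x_max=100``, exponent ``alpha=0.75``, AdaGrad with initial
    learning rate 0.05.
    """

    dim: int
    x_max: float = 100.0
    alpha: float = 0.75
    learning_rate: float = 0.05
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValidationError("embedding dimension must be positive")
        if self.x_max <= 0 or self.learning_rate <= 0 or self.epochs <= 0:
            raise ValidationError("x_max, learning_rate and epochs must be positive")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must lie in (0, 1]")


@dataclass
class GloveModel:
    """Fitted GloVe factors: main and context vectors plus biases.

    ``loss_history[0]`` is the objective at initialization; entry e is
    the objective after epoch e.
    """

    feature_ids: list[str]
    w: np.ndarray
    w_tilde: np.ndarray
    b: np.ndarray
    b_tilde: np.ndarray
    loss_history: list[float] = field(default_factory=list)


def _glove_weights(x: np.ndarray, x_max: float, alpha: float) -> np.ndarray:
    return np.where(x < x_max, (x / x_max) ** alpha, 1.0)


def glove_loss(
    X: CooccurrenceMatrix,
    w: np.ndarray,
    w_tilde: np.ndarray,
    b: np.ndarray,
    b_tilde: np.ndarray,
    x_max: float = 100.0,
    alpha: float = 0.75,
) -> float:
    """Evaluate the full GloVe objective over all ordered nonzero pairs."""
    ii, jj = np.nonzero(X.X)
    mask = ii != jj
    ii, jj = ii[mask], jj[mask]
    x = X.X[ii, jj]
    diff = np.einsum("ij,ij->i", w[ii], w_tilde[jj]) + b[ii] + b_tilde[jj] - np.log(x)
    return float(np.sum(_glove_weights(x, x_max, alpha) * diff**2))


def fit_glove(X: CooccurrenceMatrix, cfg: GloveConfig) -> GloveModel:
    """Fit GloVe factors to a co-occurrence matrix by AdaGrad SGD.

    Both orderings (i, j) and (j, i) of each nonzero off-diagonal entry
    are visited, mirroring the symmetric treatment of main and context
    roles.  Deterministic for a fixed ``cfg.seed``.
    """
    ii, jj = np.nonzero(X.X)
    mask = ii != jj
    ii, jj = ii[mask], jj[mask]
    if ii.size == 0:
        raise ValidationError("co-occurrence matrix has no nonzero off-diagonal entries")
    n = len(X.feature_ids)
    d = cfg.dim
    logx = np.log(X.X[ii, jj])
    fwt = _glove_weights(X.X[ii, jj], cfg.x_max, cfg.alpha)

    rng = np.random.default_rng(cfg.seed)
    # Reference-style init: uniform in (-0.5, 0.5) scaled by (dim + 1).
    w = (rng.random((n, d)) - 0.5) / (d + 1)
    wt = (rng.random((n, d)) - 0.5) / (d + 1)
    b = (rng.random(n) - 0.5) / (d + 1)
    bt = (rng.random(n) - 0.5) / (d + 1)
    gw = np.ones((n, d))
    gwt = np.ones((n, d))
    gb = np.ones(n)
    gbt = np.ones(n)

    lr = cfg.learning_rate
    history = [glove_loss(X, w, wt, b, bt, cfg.x_max, cfg.alpha)]
    order = np.arange(ii.size)
    for _ in range(cfg.epochs):
        rng.shuffle(order)
        for k in order:
            i, j = ii[k], jj[k]
            diff = w[i] @ wt[j] + b[i] + bt[j] - logx[k]
            fdiff = fwt[k] * diff
            grad_wi = fdiff * wt[j]
            grad_wtj = fdiff * w[i]
            w[i] -= lr * grad_wi / np.sqrt(gw[i])
            wt[j] -= lr * grad_wtj / np.sqrt(gwt[j])
            gw[i] += grad_wi**2
            gwt[j] += grad_wtj**2
            b[i] -= lr * fdiff / math.sqrt(gb[i])
            bt[j] -= lr * fdiff / math.sqrt(gbt[j])
            gb[i] += fdiff**2
            gbt[j] += fdiff**2
        history.append(glove_loss(X, w, wt, b, bt, cfg.x_max, cfg.alpha))
    return GloveModel(list(X.feature_ids), w, wt, b, bt, history)


def glove_embedding(model: GloveModel) -> EmbeddingMatrix:
    """Final per-feature representation: w + w~ (the GloVe summed
    convention), tagged method="glove"."""
    vectors = model.w + model.w_tilde
    df = pd.DataFrame(
        vectors,
        index=pd.Index(model.feature_ids),
        columns=[f"dim_{k}" for k in range(vectors.shape[1])],
    )
    return EmbeddingMatrix(df, method="glove")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _canonicalize_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is nonnegative."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def sign_canonicalize(matrix: EmbeddingMatrix) -> EmbeddingMatrix:
    """Resolve SVD sign ambiguity: each column's largest-magnitude entry
    is made nonnegative.  Idempotent."""
    df = pd.DataFrame(
        _canonicalize_signs(matrix.values()),
        index=matrix.data.index,
        columns=matrix.data.columns,
    )
    return EmbeddingMatrix(df, matrix.method, matrix.center, matrix.scale)


def fit_pca(table: CountTable, dim: int, pre_asinh: bool = False) -> EmbeddingMatrix:
    """PCA transformation matrix via SVD of the standardized count table.

    Each feature's count vector is mean-centered and scaled to unit
    variance (guarding against heteroskedasticity across taxa of very
    different typical abundance), then the top ``dim`` right singular
    vectors form the matrix columns, ordered by nonincreasing singular
    value and sign-canonicalized.  The per-feature mean and standard
    deviation are stored so queries can be standardized identically.

    ``pre_asinh`` applies the inverse-hyperbolic-sine transform to the
    counts before standardization.
    """
    n_samples, n_features = table.shape
    if dim > min(n_samples, n_features):
        raise ValidationError(
            f"dim={dim} exceeds min(#samples, #features)="
            f"{min(n_samples, n_features)}"
        )
    values = table.values()
    if pre_asinh:
        values = np.arcsinh(values)
    center = values.mean(axis=0)
    scale = values.std(axis=0, ddof=1)
    zero_var = np.where(scale == 0)[0]
    if zero_var.size:
        names = [table.feature_ids[i] for i in zero_var[:5]]
        raise ValidationError(f"zero-variance features cannot be scaled: {names}")
    Z = (values - center) / scale
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    V = _canonicalize_signs(Vt[:dim].T)
    index = pd.Index(table.feature_ids)
    df = pd.DataFrame(V, index=index, columns=[f"dim_{k}" for k in range(dim)])
    return EmbeddingMatrix(
        df,
        method="pca",
        center=pd.Series(center, index=index),
        scale=pd.Series(scale, index=index),
    )
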