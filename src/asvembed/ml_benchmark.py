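"""Cross-study phenotype classification benchmark.

Features (embedded coordinates or matched counts) are asinh-normalized,
a random forest is trained on one cohort with inverse-prior class
weights, and evaluated on an independent cohort.  The forest follows
the benchmark configuration: 100 trees, per-tree depth capped at the
square root of the number of input features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io_formats import ValidationError

__all__ = [
    "LabeledDataset",
    "ModelConfig",
    "EvalReport",
    "asinh_normalize",
    "class_weights",
    "train_classifier",
    "evaluate",
    "benchmark_pair",
    "benchmark_suite",
]


@dataclass
class LabeledDataset:
    """A samples x p feature matrix with binary labels (1 = case)."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValidationError("features and labels index mismatch")
        bad = set(self.labels.unique()) - {0, 1}
        if bad:
            raise ValidationError(f"labels must be binary 0/1, found {sorted(bad)}")
        if self.labels.isna().any():
            raise ValidationError("every sample must carry a label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class ModelConfig:
    n_trees: int = 100
    max_depth_rule: str = "sqrt_features"
    seed: int = 0
    neg_weight_one: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be at least 1")
        if self.max_depth_rule != "sqrt_features":
            raise ValidationError(f"unknown depth rule {self.max_depth_rule!r}")


@dataclass
class EvalReport:
    """Confusion counts and the derived precision/recall/F1.

    precision = tp / (tp + fp), recall = tp / (tp + fn),
    F1 = 2 * precision * recall / (precision + recall);
    a zero denominator yields 0 by convention.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    split: str

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "split": self.split,
        }


def asinh_normalize(x: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Elementwise inverse hyperbolic sine, log(x + sqrt(x^2 + 1)).

    A log-like transform for count data that needs no pseudocount:
    asinh(0) = 0 and asinh(x) tracks log(2x) closely for large x.
    """
    return np.arcsinh(np.asarray(x, dtype=float))


def class_weights(labels: pd.Series | np.ndarray, neg_weight_one: bool = False) -> dict:
    """Inverse-prior weights: class c gets N / N_c.

    With 5% positives the positive class is weighted 20.  With
    ``neg_weight_one`` the negative class weight is pinned at exactly 1
    (the convention of quoting only the positive-class upweighting).
    """
    labels = np.asarray(labels)
    n = labels.size
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute weights")
    weights = {0: n / n_neg, 1: n / n_pos}
    if neg_weight_one:
        weights[0] = 1.0
    return weights


def max_tree_depth(n_features: int) -> int:
    """Depth cap: ceiling of the square root of the feature count."""
    return max(1, math.ceil(math.sqrt(n_features)))


def train_classifier(
    train: LabeledDataset, cfg: ModelConfig | None = None
) -> RandomForestClassifier:
    """Fit the benchmark random forest, deterministic under cfg.seed."""
    cfg = cfg or ModelConfig()
    X = train.features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("features contain NaN or infinite values")
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=max_tree_depth(train.n_features),
        class_weight=class_weights(train.labels, cfg.neg_weight_one),
        random_state=cfg.seed,
    )
    model.fit(X, train.labels.to_numpy(dtype=int))
    return model


def _report_from_counts(tp: int, fp: int, fn: int, tn: int, split: str) -> EvalReport:
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return EvalReport(tp, fp, fn, tn, precision, recall, f1, split)


def evaluate(
    model: RandomForestClassifier, data: LabeledDataset, split: str = "test"
) -> EvalReport:
    """Hard-label evaluation at the 0.5 vote threshold."""
    if data.n_features != model.n_features_in_:
        raise ValidationError(
            f"feature-space mismatch: model expects {model.n_features_in_} "
            f"features, data has {data.n_features}"
        )
    pred = model.predict(data.features.to_numpy(dtype=float))
    truth = data.labels.to_numpy(dtype=int)
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    return _report_from_counts(tp, fp, fn, tn, split)


def benchmark_pair(
    train: LabeledDataset, test: LabeledDataset, cfg: ModelConfig | None = None
) -> dict[str, EvalReport]:
    """Train entirely on one cohort, test on an independent one.

    Overlapping sample IDs between the cohorts are rejected as a
    leakage guard; no test-set information reaches the fit.
    """
    overlap = set(train.sample_ids) & set(test.sample_ids)
    if overlap:
        raise ValidationError(
            f"train/test cohorts share sample IDs: {sorted(overlap)[:5]}"
        )
    model = train_classifier(train, cfg)
    return {
        "train": evaluate(model, train, split="train"),
        "test": evaluate(model, test, split="test"),
    }


def benchmark_suite(
    pairs: dict[str, tuple[LabeledDataset, LabeledDataset]],
    cfg: ModelConfig | None = None,
) -> dict[str, dict[str, EvalReport]]:
    """Run benchmark_pair for each named feature representation.

    The canonical benchmark compares seven representations per cohort
    pair: matched counts ("full") plus GloVe and PCA embeddings at 50,
    100 and 250 dimensions.
    """
    return {name: benchmark_pair(tr, te, cfg) for name, (tr, te) in pairs.items()}
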