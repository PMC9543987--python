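"""Example-based multilabel evaluation metrics.

For truth label sets Y_i and predicted sets Z_i over label space L:

* Hamming loss      = (1/|D|) sum_i |Y_i delta Z_i| / |L|
* subset accuracy   = (1/|D|) sum_i [[Y_i = Z_i]]
* accuracy          = (1/|D|) sum_i |Y_i n Z_i| / |Y_i u Z_i|   (Jaccard)
* precision         = (1/|D|) sum_i |Y_i n Z_i| / |Y_i|
* recall            = (1/|D|) sum_i |Y_i n Z_i| / |Z_i|
* F-measure         = 2 P R / (P + R) on the dataset-level averages

Note on precision/recall denominators: the convention followed here divides
precision by |Y_i| (truly relevant labels) and recall by |Z_i| (predicted
labels).  This is swapped relative to the usual information-retrieval
convention; the F-measure, being symmetric in the pair, is unaffected.

Zero-denominator convention: an instance where both Y_i and Z_i are empty
contributes 1 to the Jaccard, precision and recall terms; an instance where
only the denominator set is empty contributes 0.  This keeps every metric
total and bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .data import PredictionMatrix

__all__ = [
    "MetricReport",
    "hamming_loss",
    "subset_accuracy",
    "example_accuracy",
    "precision_recall_f",
    "compute_metrics",
]


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, PredictionMatrix):
        return x.predicted.astype(np.int8)
    arr = np.asarray(x)
    if hasattr(x, "to_numpy"):
        arr = x.to_numpy()
    return arr.astype(np.int8)


def _check(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t, p = _as_matrix(truth), _as_matrix(pred)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs prediction {p.shape}")
    if t.ndim != 2:
        raise ValueError("expected 2-d (instances x labels) matrices")
    return t, p


def hamming_loss(truth, pred) -> float:
    """Fraction of instance-label cells in the symmetric difference."""
    t, p = _check(truth, pred)
    return float((t != p).mean())


def subset_accuracy(truth, pred) -> float:
    """Fraction of instances whose predicted label set matches exactly."""
    t, p = _check(truth, pred)
    return float((t == p).all(axis=1).mean())


def example_accuracy(truth, pred) -> float:
    """Instance-averaged Jaccard similarity |Y n Z| / |Y u Z|."""
    t, p = _check(truth, pred)
    inter = (t & p).sum(axis=1)
    union = (t | p).sum(axis=1)
    terms = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return float(terms.mean())


def precision_recall_f(truth, pred) -> tuple[float, float, float]:
    """Instance-averaged precision and recall, and their harmonic mean.

    Returns ``(precision, recall, f_measure)``; F is computed from the two
    dataset-level averages and defined as 0 when both are 0.
    """
    t, p = _check(truth, pred)
    inter = (t & p).sum(axis=1).astype(float)
    ny = t.sum(axis=1)
    nz = p.sum(axis=1)
    both_empty = (ny == 0) & (nz == 0)
    prec_terms = np.where(ny > 0, inter / np.maximum(ny, 1), np.where(both_empty, 1.0, 0.0))
    rec_terms = np.where(nz > 0, inter / np.maximum(nz, 1), np.where(both_empty, 1.0, 0.0))
    precision = float(prec_terms.mean())
    recall = float(rec_terms.mean())
    denom = precision + recall
    f = 2 * precision * recall / denom if denom > 0 else 0.0
    return precision, recall, f


@dataclass
class MetricReport:
    """Bundle of the six example-based metrics for one evaluation."""

    hamming_loss: float
    subset_accuracy: float
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    n_evaluated: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(truth, pred) -> MetricReport:
    """Evaluate a prediction matrix against the true label matrix."""
    t, p = _check(truth, pred)
    prec, rec, f = precision_recall_f(t, p)
    return MetricReport(
        hamming_loss=hamming_loss(t, p),
        subset_accuracy=subset_accuracy(t, p),
        accuracy=example_accuracy(t, p),
        precision=prec,
        recall=rec,
        f_measure=f,
        n_evaluated=t.shape[0],
    )
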