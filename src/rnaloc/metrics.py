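"""Multi-label evaluation metrics and per-label accuracy/MCC.

Six example/ranking-based metrics summarize multi-label performance over n
samples with 6 labels:

* **Acc_exam** — mean Jaccard index |Y ∩ Z| / |Y ∪ Z| between true and
  binarized predicted label sets (1 for a sample where both sets are empty);
* **hamming loss** — mean fraction of label slots where Z disagrees with Y;
* **one-error** — fraction of samples whose top-ranked label is not true;
* **coverage** — mean over samples of (max 1-based rank among true labels)
  minus 1, ranking labels by descending probability;
* **ranking loss** — mean fraction of (true, false) label pairs ordered
  wrongly by probability; exact probability ties count 1/2;
* **average precision** — mean over samples of the mean, over true labels, of
  precision at that label's rank.

Samples with zero true labels are excluded from the four ranking metrics
(with a warning) and kept in Acc_exam and hamming loss. Rank ties are broken
by ascending label index so results are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .records import LABEL_NAMES, N_LABELS

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    acc_exam: float
    average_precision: float
    coverage: float
    one_error: float
    ranking_loss: float
    hamming_loss: float
    #: per label: {"accuracy": ..., "mcc": ...}, keyed by compartment name
    per_label: dict[str, dict[str, float]]
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "acc_exam": self.acc_exam,
            "average_precision": self.average_precision,
            "coverage": self.coverage,
            "one_error": self.one_error,
            "ranking_loss": self.ranking_loss,
            "hamming_loss": self.hamming_loss,
            "per_label": self.per_label,
            "n_samples": self.n_samples,
        }


def binarize(P: np.ndarray, threshold: float | np.ndarray = 0.5) -> np.ndarray:
    """Threshold probabilities into 0/1 labels; p >= threshold maps to 1.

    `threshold` may be a scalar or a length-6 per-label vector.
    """
    P = np.asarray(P, dtype=float)
    return (P >= np.asarray(threshold)).astype(np.int64)


def _ranks_desc(p: np.ndarray) -> np.ndarray:
    """1-based rank of each label when sorted by descending probability,
    ties broken by ascending label index."""
    order = np.lexsort((np.arange(p.size), -p))
    ranks = np.empty(p.size, dtype=np.int64)
    ranks[order] = np.arange(1, p.size + 1)
    return ranks


def multilabel_metrics(
    Y: np.ndarray, P: np.ndarray, threshold: float | np.ndarray = 0.5
) -> MetricsReport:
    """Compute the six multi-label metrics plus per-label accuracy/MCC."""
    Y = np.asarray(Y, dtype=np.int64)
    P = np.asarray(P, dtype=float)
    if Y.ndim != 2 or Y.shape != P.shape or Y.shape[1] != N_LABELS:
        raise DataError(
            f"expected matching (n, {N_LABELS}) label and probability arrays, "
            f"got {Y.shape} and {P.shape}"
        )
    n = Y.shape[0]
    if n < 1:
        raise DataError("need at least one sample")
    Z = binarize(P, threshold)

    inter = (Y & Z).sum(axis=1)
    union = (Y | Z).sum(axis=1)
    jaccard = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    acc_exam = float(jaccard.mean())
    hamming = float((Y != Z).mean())

    has_positive = Y.any(axis=1)
    n_ranked = int(has_positive.sum())
    if n_ranked < n:
        logger.warning(
            "%d of %d samples have no true label; excluded from ranking metrics",
            n - n_ranked, n,
        )
    one_error_terms, coverage_terms, rloss_terms, ap_terms = [], [], [], []
    for i in np.flatnonzero(has_positive):
        y, p = Y[i], P[i]
        ranks = _ranks_desc(p)
        true_idx = np.flatnonzero(y == 1)
        false_idx = np.flatnonzero(y == 0)
        top = int(np.argmin(ranks))
        one_error_terms.append(0.0 if y[top] == 1 else 1.0)
        coverage_terms.append(float(ranks[true_idx].max() - 1))
        if false_idx.size:
            pt = p[true_idx][:, None]
            pf = p[false_idx][None, :]
            wrong = (pt < pf).sum() + 0.5 * (pt == pf).sum()
            rloss_terms.append(wrong / (true_idx.size * false_idx.size))
        else:
            rloss_terms.append(0.0)
        true_ranks = np.sort(ranks[true_idx])
        precisions = [
            (true_ranks <= r).sum() / r for r in ranks[true_idx]
        ]
        ap_terms.append(float(np.mean(precisions)))

    def _mean(terms):
        return float(np.mean(terms)) if terms else float("nan")

    return MetricsReport(
        acc_exam=acc_exam,
        average_precision=_mean(ap_terms),
        coverage=_mean(coverage_terms),
        one_error=_mean(one_error_terms),
        ranking_loss=_mean(rloss_terms),
        hamming_loss=hamming,
        per_label=per_label_metrics(Y, Z),
        n_samples=n,
    )


def per_label_metrics(Y: np.ndarray, Z: np.ndarray) -> dict[str, dict[str, float]]:
    """Accuracy and MCC per compartment from binarized predictions.

    MCC is defined as 0 when any confusion-matrix marginal is zero.
    """
    Y = np.asarray(Y, dtype=np.int64)
    Z = np.asarray(Z, dtype=np.int64)
    if Y.shape != Z.shape:
        raise DataError("shape mismatch between truth and predictions")
    out = {}
    for j, name in enumerate(LABEL_NAMES):
        y, z = Y[:, j], Z[:, j]
        tp = int(((y == 1) & (z == 1)).sum())
        tn = int(((y == 0) & (z == 0)).sum())
        fp = int(((y == 0) & (z == 1)).sum())
        fn = int(((y == 1) & (z == 0)).sum())
        acc = (tp + tn) / len(y)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
        out[name] = {"accuracy": float(acc), "mcc": float(mcc)}
    return out
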