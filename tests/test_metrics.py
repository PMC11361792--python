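"""Multi-label metrics against naive per-definition oracles and sklearn."""

import numpy as np
import pytest
from sklearn.metrics import (
    coverage_error,
    label_ranking_average_precision_score,
    label_ranking_loss,
)

from rnaloc.errors import DataError
from rnaloc.metrics import binarize, multilabel_metrics, per_label_metrics


# -- naive double-loop oracle ------------------------------------------------

def oracle_metrics(Y, P, threshold=0.5):
    n, q = Y.shape
    Z = (P >= threshold).astype(int)
    acc_terms, ham = [], 0.0
    one_err, cov, rloss, ap = [], [], [], []
    for i in range(n):
        inter = sum(1 for j in range(q) if Y[i, j] and Z[i, j])
        union = sum(1 for j in range(q) if Y[i, j] or Z[i, j])
        acc_terms.append(1.0 if union == 0 else inter / union)
        ham += sum(1 for j in range(q) if Y[i, j] != Z[i, j]) / q
        if not Y[i].any():
            continue
        # 1-based ranks, ties by ascending label index
        order = sorted(range(q), key=lambda j: (-P[i, j], j))
        rank = {j: r + 1 for r, j in enumerate(order)}
        one_err.append(0.0 if Y[i, order[0]] else 1.0)
        cov.append(max(rank[j] for j in range(q) if Y[i, j]) - 1)
        true = [j for j in range(q) if Y[i, j]]
        false = [j for j in range(q) if not Y[i, j]]
        if false:
            bad = sum(
                1.0 if P[i, t] < P[i, f] else (0.5 if P[i, t] == P[i, f] else 0.0)
                for t in true for f in false
            )
            rloss.append(bad / (len(true) * len(false)))
        else:
            rloss.append(0.0)
        precs = []
        for t in true:
            r = rank[t]
            precs.append(sum(1 for u in true if rank[u] <= r) / r)
        ap.append(np.mean(precs))
    return {
        "acc_exam": np.mean(acc_terms),
        "hamming_loss": ham / n,
        "one_error": np.mean(one_err),
        "coverage": np.mean(cov),
        "ranking_loss": np.mean(rloss),
        "average_precision": np.mean(ap),
    }


def test_worked_single_sample_example():
    """Y=(1,1,0,0,0,0), P=(0.9,0.8,0.1,0.2,0.3,0.05): a perfect ranking."""
    Y = np.array([[1, 1, 0, 0, 0, 0]])
    P = np.array([[0.9, 0.8, 0.1, 0.2, 0.3, 0.05]])
    r = multilabel_metrics(Y, P)
    assert r.one_error == 0.0
    assert r.coverage == 1.0
    assert r.ranking_loss == 0.0
    assert r.average_precision == 1.0
    assert r.hamming_loss == 0.0
    assert r.acc_exam == 1.0


def test_top_ranked_false_label_scores_one_error():
    Y = np.array([[0, 1, 0, 0, 0, 0]])
    P = np.array([[0.9, 0.8, 0.1, 0.2, 0.3, 0.05]])
    assert multilabel_metrics(Y, P).one_error == 1.0


def test_perfect_separation_across_samples(rng):
    """All true probs above all false probs: ideal values for every metric."""
    n = 20
    Y = np.zeros((n, 6), dtype=int)
    P = np.zeros((n, 6))
    for i in range(n):
        k = int(rng.integers(1, 6))
        pos = rng.choice(6, k, replace=False)
        Y[i, pos] = 1
        P[i] = rng.uniform(0.0, 0.4, 6)
        P[i, pos] = rng.uniform(0.6, 1.0, k)
    r = multilabel_metrics(Y, P)
    assert r.one_error == 0.0 and r.ranking_loss == 0.0
    assert r.hamming_loss == 0.0 and r.acc_exam == 1.0
    assert r.average_precision == 1.0
    np.testing.assert_allclose(r.coverage, Y.sum(axis=1).mean() - 1)


def test_matches_naive_oracle_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(1, 12))
        Y = rng.integers(0, 2, size=(n, 6))
        P = np.round(rng.random((n, 6)), 2)  # rounding forces some ties
        if not Y.any(axis=1).all():
            Y[0] = 1  # keep at least one rankable sample
        r = multilabel_metrics(Y, P)
        expected = oracle_metrics(Y, P)
        for key, val in expected.items():
            assert abs(getattr(r, key) - val) < 1e-9, key


def test_matches_sklearn_on_tie_free_instances(rng):
    """Independent cross-check against sklearn's ranking metrics (which use
    the same conventions when probabilities are tie-free and every sample has
    both a positive and a negative label)."""
    for _ in range(20):
        n = int(rng.integers(2, 30))
        Y = rng.integers(0, 2, size=(n, 6))
        for i in range(n):
            if Y[i].sum() in (0, 6):
                Y[i, int(rng.integers(0, 6))] = 1 - Y[i, 0]
                Y[i, 0] = 1 - Y[i, 1]
        P = rng.random((n, 6))
        r = multilabel_metrics(Y, P)
        np.testing.assert_allclose(r.coverage, coverage_error(Y, P) - 1, atol=1e-9)
        np.testing.assert_allclose(r.ranking_loss, label_ranking_loss(Y, P),
                                   atol=1e-9)
        np.testing.assert_allclose(
            r.average_precision,
            label_ranking_average_precision_score(Y, P), atol=1e-9,
        )


def test_bounds_on_random_draws(rng):
    Y = rng.integers(0, 2, size=(1000, 6))
    Y[~Y.any(axis=1), 0] = 1
    P = rng.random((1000, 6))
    r = multilabel_metrics(Y, P)
    for name in ("acc_exam", "average_precision", "one_error", "ranking_loss",
                 "hamming_loss"):
        assert 0.0 <= getattr(r, name) <= 1.0, name
    assert 0.0 <= r.coverage <= 5.0


def test_rank_metrics_invariant_to_monotone_transforms(rng):
    Y = rng.integers(0, 2, size=(30, 6))
    Y[~Y.any(axis=1), 2] = 1
    P = rng.random((30, 6))
    r1 = multilabel_metrics(Y, P)
    r2 = multilabel_metrics(Y, np.exp(3 * P) / 50.0)
    assert r1.coverage == r2.coverage
    assert r1.ranking_loss == r2.ranking_loss
    assert r1.one_error == r2.one_error
    assert r1.average_precision == r2.average_precision


def test_zero_label_rows_excluded_from_ranking_but_scored_for_accuracy():
    Y = np.array([[0, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0]])
    P = np.array([[0.1] * 6, [0.9, 0.1, 0.1, 0.1, 0.1, 0.1]])
    r = multilabel_metrics(Y, P)
    assert r.acc_exam == 1.0  # empty prediction matches empty truth
    assert r.one_error == 0.0  # only the second row is ranked
    assert r.n_samples == 2


def test_shape_mismatch_raises():
    with pytest.raises(DataError):
        multilabel_metrics(np.zeros((2, 6), dtype=int), np.zeros((3, 6)))


# -- binarize ----------------------------------------------------------------

def test_binarize_threshold_and_tie_rule():
    p = np.array([[0.9, 0.4, 0.5, 0.1, 0.6, 0.2]])
    np.testing.assert_array_equal(binarize(p), [[1, 0, 1, 0, 1, 0]])
    per_label = np.array([0.95, 0.3, 0.6, 0.05, 0.7, 0.1])
    np.testing.assert_array_equal(binarize(p, per_label), [[0, 1, 0, 1, 0, 1]])


# -- per-label ---------------------------------------------------------------

def test_per_label_perfect_and_inverted_predictions():
    Y = np.array([[1, 0] * 3, [0, 1] * 3, [1, 1, 0, 0, 1, 0]])
    perfect = per_label_metrics(Y, Y)
    for stats in perfect.values():
        assert stats["accuracy"] == 1.0 and stats["mcc"] == 1.0
    inverted = per_label_metrics(Y, 1 - Y)
    for stats in inverted.values():
        assert stats["accuracy"] == 0.0 and stats["mcc"] == -1.0


def test_mcc_confusion_matrix_example():
    """TP=4, TN=3, FP=1, FN=2 -> MCC = (4*3 - 1*2)/sqrt(5*6*4*5)."""
    y = np.array([1] * 4 + [0] * 3 + [0] + [1] * 2)
    z = np.array([1] * 4 + [0] * 3 + [1] + [0] * 2)
    Y = np.tile(y[:, None], (1, 6))
    Z = np.tile(z[:, None], (1, 6))
    stats = per_label_metrics(Y, Z)
    for s in stats.values():
        np.testing.assert_allclose(s["mcc"], 10 / np.sqrt(600))
        np.testing.assert_allclose(s["accuracy"], 7 / 10)


def test_mcc_zero_when_marginal_degenerate():
    Y = np.zeros((5, 6), dtype=int)
    Z = np.zeros((5, 6), dtype=int)
    for s in per_label_metrics(Y, Z).values():
        assert s["mcc"] == 0.0 and s["accuracy"] == 1.0
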