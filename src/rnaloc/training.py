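"""Multi-label training: loss, splitting, the Adam loop, and prediction.

The objective is the summed binary cross-entropy over the six compartments,

    loss_i = - sum_j [ y_ij log p_ij + (1 - y_ij) log(1 - p_ij) ],

averaged over the mini-batch. Probabilities are clamped to
[1e-7, 1 - 1e-7] before the logs. Training runs a fixed number of epochs
(no early stopping); the weights with the lowest validation loss are kept as
the best checkpoint alongside the final ones.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .encoders import cksnap_frequencies, kmer_frequencies
from .errors import ConfigError, DataError
from .metrics import MetricsReport, multilabel_metrics
from .model import LocalizationNet, ModelConfig, make_optimizer
from .nn import GraphBatch
from .records import RnaRecord
from .structure import StructureGraph, dotbracket_to_graph

logger = logging.getLogger(__name__)

PROB_EPS = 1e-7


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the published recipe
    (learning rate 3e-4, dropout 0.1, 200 epochs, 8:1:1 split)."""

    learning_rate: float = 0.0003
    epochs: int = 200
    batch_size: int = 32
    dropout: float = 0.1
    seed: int = 0
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    threshold: float = 0.5
    model: ModelConfig = field(default_factory=ModelConfig)
    #: optional per-label positive weights for the BCE terms (off by default)
    positive_weights: tuple[float, ...] | None = None
    #: evaluate metrics on the validation set every this many epochs
    eval_every: int = 1

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ConfigError(f"split ratios {self.split_ratios} must sum to 1")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        self.model.dropout = self.dropout


def bce_multilabel_loss(
    y: Tensor | np.ndarray,
    p: Tensor,
    positive_weights: np.ndarray | None = None,
) -> Tensor:
    """Mean-over-samples summed binary cross-entropy.

    `p` values at exactly 0 or 1 are clamped (debug-logged) so the logs stay
    finite; the gradient passes through unclipped entries only.
    """
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=float)
    if np.any(p.data <= 0.0) or np.any(p.data >= 1.0):
        logger.debug("probabilities clamped to [%g, %g]", PROB_EPS, 1 - PROB_EPS)
    p = p.clip(PROB_EPS, 1.0 - PROB_EPS)
    y_t = Tensor(y_arr)
    pos = y_t * p.log()
    if positive_weights is not None:
        pos = pos * Tensor(np.asarray(positive_weights, dtype=float))
    neg = (1.0 - y_t) * (1.0 - p).log()
    per_sample = -(pos + neg).sum(axis=-1)
    return per_sample.mean() if per_sample.ndim else per_sample


def split_dataset(
    records: list,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Random train/validation/test partition.

    Validation and test sizes are floor(n * ratio); the remainder goes to
    training, so the three parts are disjoint and cover the input exactly.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"split ratios {ratios} must sum to 1")
    if len(records) < 10:
        raise DataError(f"need at least 10 records to split, got {len(records)}")
    n = len(records)
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(np.floor(n * ratios[1]))
    n_test = int(np.floor(n * ratios[2]))
    n_train = n - n_val - n_test
    shuffled = [records[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------


@dataclass
class PreparedRecord:
    """One record with all model inputs precomputed."""

    record: RnaRecord
    kmer: np.ndarray
    cksnap: np.ndarray
    graph1: StructureGraph
    graph2: StructureGraph


def prepare_records(
    records: list[RnaRecord],
    sources: tuple[str, str] = ("nussinov", "nussinov"),
    require_labels: bool = False,
) -> list[PreparedRecord]:
    """Precompute composition vectors and both structure graphs per record.

    When a record carries only one structure source it is reused for both
    graph branches (logged once).
    """
    prepared = []
    reused_warned = False
    for rec in records:
        if require_labels and rec.labels is None:
            raise DataError(f"record {rec.id!r} has no labels")
        if not rec.structures:
            raise DataError(f"record {rec.id!r} has no structure")
        actual = []
        for src in sources:
            if src not in rec.structures:
                fallback = next(iter(rec.structures))
                if not reused_warned:
                    logger.info(
                        "structure source %r missing; reusing %r for that branch",
                        src, fallback,
                    )
                    reused_warned = True
                actual.append(fallback)
            else:
                actual.append(src)
        prepared.append(
            PreparedRecord(
                record=rec,
                kmer=kmer_frequencies(rec.sequence),
                cksnap=cksnap_frequencies(rec.sequence),
                graph1=dotbracket_to_graph(rec, source=actual[0]),
                graph2=dotbracket_to_graph(rec, source=actual[1]),
            )
        )
    return prepared


def _batch_inputs(prepared: list[PreparedRecord]) -> dict:
    return {
        "kmer": np.stack([p.kmer for p in prepared]),
        "cksnap": np.stack([p.cksnap for p in prepared]),
        "graphs1": GraphBatch([p.graph1 for p in prepared]),
        "graphs2": GraphBatch([p.graph2 for p in prepared]),
    }


def _labels_of(prepared: list[PreparedRecord]) -> np.ndarray:
    return np.stack([p.record.labels for p in prepared])


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: LocalizationNet
    history: list[dict]
    best_epoch: int
    best_val_loss: float
    best_state: tuple[list[np.ndarray], list[np.ndarray]]

    def restore_best(self) -> LocalizationNet:
        params, buffers = self.best_state
        self.model.load_state_arrays(params)
        self.model.load_buffer_arrays(buffers)
        return self.model


def _snapshot(model: LocalizationNet) -> tuple[list[np.ndarray], list[np.ndarray]]:
    return ([a.copy() for a in model.state_arrays()],
            [np.array(a, copy=True) for a in model.buffer_arrays()])


def train(
    train_records: list[RnaRecord] | list[PreparedRecord],
    config: TrainConfig,
    val_records: list[RnaRecord] | list[PreparedRecord] | None = None,
) -> TrainResult:
    """Train a model with Adam; returns the model plus per-epoch history.

    With a fixed `config.seed` the weight initialization, batch shuffling and
    dropout masks are all reproducible, so two runs produce identical loss
    curves.
    """
    prepared = _ensure_prepared(train_records, config)
    val_prepared = _ensure_prepared(val_records, config) if val_records else None

    model = LocalizationNet(config.model, seed=config.seed)
    optimizer = make_optimizer(model, config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    Y_train = _labels_of(prepared)
    pw = (np.asarray(config.positive_weights, dtype=float)
          if config.positive_weights is not None else None)

    history: list[dict] = []
    best_val = np.inf
    best_epoch = -1
    best_state = _snapshot(model)
    n = len(prepared)
    t0 = time.time()
    for epoch in range(config.epochs):
        model.train()
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            chunk = [prepared[i] for i in idx]
            inputs = _batch_inputs(chunk)
            probs = model.forward(**inputs)
            loss = bce_multilabel_loss(Y_train[idx], probs, positive_weights=pw)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item() * len(idx)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n}

        if val_prepared and (epoch % config.eval_every == 0
                             or epoch == config.epochs - 1):
            val_loss, report = evaluate(model, val_prepared, config)
            entry["val_loss"] = val_loss
            entry["val_metrics"] = report.to_dict()
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch
                best_state = _snapshot(model)
        history.append(entry)
    logger.info(
        "trained %d epochs on %d records in %.1f s (final train loss %.4f)",
        config.epochs, n, time.time() - t0, history[-1]["train_loss"],
    )
    if not val_prepared:
        best_state = _snapshot(model)
        best_epoch = config.epochs - 1
        best_val = history[-1]["train_loss"]
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_loss=float(best_val), best_state=best_state)


def _ensure_prepared(records, config: TrainConfig):
    if records is None:
        return None
    if records and isinstance(records[0], PreparedRecord):
        return records
    return prepare_records(records, sources=config.model.structure_sources,
                           require_labels=True)


def predict(
    model: LocalizationNet,
    records: list[RnaRecord] | list[PreparedRecord],
    batch_size: int = 64,
    sources: tuple[str, str] | None = None,
) -> np.ndarray:
    """Predicted probabilities (n, 6) in input order; model runs in eval mode."""
    if records and isinstance(records[0], PreparedRecord):
        prepared = records
    else:
        prepared = prepare_records(
            records, sources=sources or model.config.structure_sources
        )
    model.eval()
    chunks = []
    for start in range(0, len(prepared), batch_size):
        chunk = prepared[start : start + batch_size]
        chunks.append(model.forward(**_batch_inputs(chunk)).data)
    return np.concatenate(chunks, axis=0)


def evaluate(
    model: LocalizationNet,
    prepared: list[PreparedRecord],
    config: TrainConfig,
) -> tuple[float, MetricsReport]:
    """Validation loss and the full metrics report for a prepared set."""
    probs = predict(model, prepared, batch_size=config.batch_size)
    Y = _labels_of(prepared)
    loss = bce_multilabel_loss(Y, Tensor(probs)).item()
    report = multilabel_metrics(Y, probs, threshold=config.threshold)
    return loss, report
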