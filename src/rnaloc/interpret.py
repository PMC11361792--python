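"""Edge-importance interpretation via a learned edge mask.

A sigmoid-squashed mask over the edges of one record's structure graph is
optimized so that the masked model still predicts the record's positive
compartments, while L1 and entropy penalties push the mask to be small and
near-binary. High-scoring edges indicate structure the model relies on. The
top edges are then grouped into connected substructures (at least three
bases), reported with the field's notation: ``==`` for a base-pair edge and
``<->`` for a backbone (adjacent) edge. Positions in all user-facing output
are 1-based.

Node-feature importance is estimated by occlusion: zeroing each of the four
node-encoding groups (one-hot, NCP, EIIP, ANF) and measuring the mean
absolute change in the predicted probabilities, per compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .errors import ConfigError
from .metrics import binarize
from .model import LocalizationNet
from .nn import Adam, GraphBatch
from .records import LABEL_NAMES
from .structure import EDGE_BASE_PAIR, StructureGraph
from .training import PreparedRecord, _batch_inputs, bce_multilabel_loss

logger = logging.getLogger(__name__)

FEATURE_GROUPS = {
    "one_hot": slice(0, 5),
    "ncp": slice(5, 8),
    "eiip": slice(8, 9),
    "anf": slice(9, 10),
}

PAIR_SYMBOL = "=="
ADJ_SYMBOL = "<->"


@dataclass
class EdgeScore:
    """Importance of one undirected edge, 1-based endpoint positions."""

    i: int
    j: int
    edge_type: str
    score: float

    def to_dict(self) -> dict:
        return {"i": self.i, "j": self.j, "type": self.edge_type,
                "score": self.score}


def learn_edge_mask(
    model: LocalizationNet,
    prepared: PreparedRecord,
    steps: int = 100,
    seed: int = 0,
    lr: float = 0.1,
    l1_weight: float = 0.005,
    entropy_weight: float = 0.1,
    branch: int = 1,
) -> list[EdgeScore]:
    """Optimize an edge mask for one record and return per-edge scores.

    The mask (one logit per undirected edge, applied to both directions of
    the chosen graph branch) is trained to minimize the BCE of the record's
    target labels — its true positives if present, otherwise the model's own
    binarized prediction — plus size and entropy penalties. Scores are the
    final sigmoid mask values in [0, 1]; with a fixed seed the result is
    reproducible.
    """
    graph = prepared.graph1 if branch == 1 else prepared.graph2
    branch_module = model.graph_branch1 if branch == 1 else model.graph_branch2
    if branch_module is None:
        raise ConfigError(f"graph branch {branch} is disabled in this model")
    model.eval()
    inputs = _batch_inputs([prepared])

    base_probs = model.forward(**inputs).data[0]
    if prepared.record.labels is not None and prepared.record.labels.any():
        target = prepared.record.labels.astype(float)
    else:
        target = binarize(base_probs).astype(float)
        logger.info("record %s has no positive labels; explaining the "
                    "model's own prediction", prepared.record.id)

    rng = np.random.default_rng(seed)
    logits = Tensor(
        (rng.normal(0.0, 0.1, size=graph.n_edges) + 1.0).astype(model.np_dtype),
        requires_grad=True,
    )
    optimizer = Adam([logits], lr=lr)
    mask_kw = "edge_mask1" if branch == 1 else "edge_mask2"
    for _ in range(steps):
        mask = logits.sigmoid()
        probs = model.forward(**inputs, **{mask_kw: mask})
        pred_loss = bce_multilabel_loss(target[None, :], probs)
        m = mask.clip(1e-6, 1 - 1e-6)
        entropy = -(m * m.log() + (1.0 - m) * (1.0 - m).log()).mean()
        loss = pred_loss + l1_weight * mask.mean() * graph.n_edges \
            + entropy_weight * entropy
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()

    scores = 1.0 / (1.0 + np.exp(-logits.data))
    return [
        EdgeScore(i=int(a) + 1, j=int(b) + 1, edge_type=t, score=float(s))
        for (a, b), t, s in zip(graph.edges, graph.edge_types, scores)
    ]


def top_edges(scores: list[EdgeScore], k: int = 300) -> list[EdgeScore]:
    """The k highest-scoring edges, descending; ties broken toward the edge
    with the smaller endpoints for determinism."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    ranked = sorted(scores, key=lambda e: (-e.score, e.i, e.j))
    return ranked[:k]


@dataclass
class Substructure:
    """A connected component of the top-edge subgraph (1-based positions)."""

    positions: list[int]
    bases: str
    edges: list[EdgeScore]

    def notation(self) -> str:
        """Human-readable edge list, e.g. ``A(5)<->C(6), G(2)==C(9)``."""
        parts = []
        for e in sorted(self.edges, key=lambda e: (e.i, e.j)):
            sym = PAIR_SYMBOL if e.edge_type == EDGE_BASE_PAIR else ADJ_SYMBOL
            parts.append(
                f"{self.bases[self.positions.index(e.i)]}({e.i})"
                f"{sym}"
                f"{self.bases[self.positions.index(e.j)]}({e.j})"
            )
        return ", ".join(parts)

    def to_dict(self) -> dict:
        return {
            "positions": self.positions,
            "bases": self.bases,
            "notation": self.notation(),
            "edges": [e.to_dict() for e in self.edges],
        }


def extract_substructures(
    graph: StructureGraph,
    edges: list[EdgeScore],
    min_bases: int = 3,
) -> list[Substructure]:
    """Connected components of the subgraph induced by `edges`.

    Components with fewer than `min_bases` nodes are dropped. Components are
    returned ordered by their smallest position.
    """
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        for node in (e.i, e.j):
            parent.setdefault(node, node)
        ra, rb = find(e.i), find(e.j)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    components: dict[int, list[int]] = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    out = []
    for root in sorted(components):
        nodes = sorted(components[root])
        if len(nodes) < min_bases:
            continue
        node_set = set(nodes)
        comp_edges = [e for e in edges if e.i in node_set and e.j in node_set]
        bases = "".join(graph.sequence[p - 1] for p in nodes) \
            if graph.sequence else "?" * len(nodes)
        out.append(Substructure(positions=nodes, bases=bases, edges=comp_edges))
    return out


def substructure_proportions(
    substructures_per_record: dict[str, list[Substructure]],
    labels_per_record: dict[str, np.ndarray],
) -> dict[str, dict[str, dict[str, float]]]:
    """Frequency of each substructure notation within each compartment.

    Both normalizations are reported: ``per_record`` (fraction of that
    compartment's records containing the substructure) and ``per_edge``
    (the substructure's edge count over all top-edge counts in that
    compartment).
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for j, label in enumerate(LABEL_NAMES):
        rec_ids = [rid for rid, y in labels_per_record.items() if y[j] == 1]
        if not rec_ids:
            continue
        counts: dict[str, int] = {}
        edge_counts: dict[str, int] = {}
        total_edges = 0
        for rid in rec_ids:
            seen = set()
            for sub in substructures_per_record.get(rid, []):
                key = sub.notation()
                edge_counts[key] = edge_counts.get(key, 0) + len(sub.edges)
                total_edges += len(sub.edges)
                if key not in seen:
                    counts[key] = counts.get(key, 0) + 1
                    seen.add(key)
        out[label] = {
            key: {
                "per_record": counts.get(key, 0) / len(rec_ids),
                "per_edge": (edge_counts[key] / total_edges) if total_edges else 0.0,
            }
            for key in edge_counts
        }
    return out


def node_feature_importance(
    model: LocalizationNet,
    prepared: list[PreparedRecord],
) -> dict[str, dict[str, float]]:
    """Occlusion importance of the four node-feature groups, per compartment.

    For each group, its columns are zeroed in both structure graphs and the
    mean absolute change in predicted probability is recorded per label.
    Deterministic (no sampling).
    """
    model.eval()
    inputs = _batch_inputs(prepared)
    base = model.forward(**inputs).data

    out: dict[str, dict[str, float]] = {}
    for group, cols in FEATURE_GROUPS.items():
        occluded = {k: v for k, v in inputs.items()}
        for key in ("graphs1", "graphs2"):
            batch = inputs[key]
            clone = GraphBatch.__new__(GraphBatch)
            clone.__dict__.update(batch.__dict__)
            clone.x = batch.x.copy()
            clone.x[:, cols] = 0.0
            occluded[key] = clone
        probs = model.forward(**occluded).data
        delta = np.abs(probs - base).mean(axis=0)
        out[group] = {name: float(delta[j]) for j, name in enumerate(LABEL_NAMES)}
    return out
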