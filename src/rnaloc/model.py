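"""The multi-view localization network.

Four parallel feature extractors produce 128-dim embeddings that are
concatenated and passed to a two-layer sigmoid head emitting six
per-compartment probabilities:

* two sequence-context branches (k-mer 1364-dim input, CKSNAP 96-dim input),
  each an MLP followed by multi-head self-attention over the MLP's output
  re-shaped into tokens, mean-pooled and projected to 128;
* two graph-structural branches (one per secondary-structure source), each a
  stack of GNN layers (GIN by default; GCN/GAT selectable) followed by a
  set2set readout and a projection to 128.

Ablation flags can disable any branch; the head input width shrinks
accordingly. Disabling all branches is a configuration error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .encoders import CKSNAP_DIM, KMER_DIM, NODE_FEATURE_DIM
from .errors import ConfigError
from .nn import (
    Adam,
    Dropout,
    GATLayer,
    GCNLayer,
    GINLayer,
    GraphBatch,
    Linear,
    MLP,
    Module,
    MultiHeadSelfAttention,
    Set2Set,
)
from .records import LABEL_NAMES

GNN_LAYER_CLASSES = {"gin": GINLayer, "gcn": GCNLayer, "gat": GATLayer}

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters (all config-exposed).

    The attention tokenization maps each composition vector through the MLP
    to `attn_tokens * attn_dim` values, viewed as `attn_tokens` tokens of
    `attn_dim` dims for the self-attention layer.
    """

    embed_dim: int = 128
    # sequence branches
    seq_mlp_hidden: tuple[int, ...] = (256, 128)
    attn_tokens: int = 16
    attn_dim: int = 32
    n_heads: int = 4
    # graph branches
    gnn_variant: str = "gin"
    gnn_layers: int = 4
    gnn_hidden: int = 64
    set2set_steps: int = 3
    # head
    head_hidden: int = 256
    dropout: float = 0.1
    #: compute precision; float32 roughly halves training time
    dtype: str = "float32"
    # branch enable flags (ablations)
    use_kmer: bool = True
    use_cksnap: bool = True
    use_graph1: bool = True
    use_graph2: bool = True
    #: structure sources feeding the two graph branches, in order
    structure_sources: tuple[str, str] = ("nussinov", "nussinov")

    def __post_init__(self) -> None:
        if self.gnn_variant not in GNN_LAYER_CLASSES:
            raise ConfigError(
                f"unknown gnn_variant {self.gnn_variant!r}; "
                f"choose from {sorted(GNN_LAYER_CLASSES)}"
            )
        if not any((self.use_kmer, self.use_cksnap, self.use_graph1,
                    self.use_graph2)):
            raise ConfigError("all branches disabled")
        if self.dtype not in ("float32", "float64"):
            raise ConfigError(f"unsupported dtype {self.dtype!r}")

    @property
    def n_branches(self) -> int:
        return sum((self.use_kmer, self.use_cksnap, self.use_graph1,
                    self.use_graph2))

    @property
    def concat_dim(self) -> int:
        return self.n_branches * self.embed_dim

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seq_mlp_hidden"] = list(self.seq_mlp_hidden)
        d["structure_sources"] = list(self.structure_sources)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "seq_mlp_hidden" in d:
            d["seq_mlp_hidden"] = tuple(d["seq_mlp_hidden"])
        if "structure_sources" in d:
            d["structure_sources"] = tuple(d["structure_sources"])
        return cls(**d)


class SequenceExtractor(Module):
    """MLP + multi-head self-attention branch for one composition vector."""

    def __init__(self, rng, in_dim: int, config: ModelConfig):
        super().__init__()
        self.in_dim = in_dim
        self.tokens = config.attn_tokens
        self.d_model = config.attn_dim
        dims = [in_dim, *config.seq_mlp_hidden, self.tokens * self.d_model]
        self.mlp = MLP(rng, dims, dropout=config.dropout, final_activation=True)
        self.attention = MultiHeadSelfAttention(rng, self.d_model, config.n_heads)
        self.proj = Linear(rng, self.d_model, config.embed_dim)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 2 or x.shape[1] != self.in_dim:
            raise ConfigError(
                f"sequence branch expected (B, {self.in_dim}) input, got {x.shape}"
            )
        B = x.shape[0]
        h = self.mlp(x).reshape(B, self.tokens, self.d_model)
        h = self.attention(h)
        pooled = h.mean(axis=1)
        return self.proj(pooled).relu()


class GraphExtractor(Module):
    """Stacked GNN layers + set2set readout branch for one structure source."""

    def __init__(self, rng, config: ModelConfig):
        super().__init__()
        layer_cls = GNN_LAYER_CLASSES[config.gnn_variant]
        dims = [NODE_FEATURE_DIM] + [config.gnn_hidden] * config.gnn_layers
        self.layers = [
            layer_cls(rng, a, config.gnn_hidden, b, dropout=config.dropout)
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.pool = Set2Set(rng, config.gnn_hidden, config.set2set_steps)
        self.proj = Linear(rng, 2 * config.gnn_hidden, config.embed_dim)

    def __call__(self, batch: GraphBatch,
                 edge_mask: Tensor | None = None) -> Tensor:
        h = Tensor(batch.x)
        for layer in self.layers:
            h = layer(h, batch, edge_mask=edge_mask)
        pooled = self.pool(h, batch.batch, batch.n_graphs)
        return self.proj(pooled).relu()


class PredictionHead(Module):
    """Two linear layers; sigmoid on the second produces the 6 probabilities."""

    def __init__(self, rng, in_dim: int, hidden: int, dropout: float):
        super().__init__()
        self.lin1 = Linear(rng, in_dim, hidden)
        self.dropout = Dropout(dropout, rng)
        self.lin2 = Linear(rng, hidden, len(LABEL_NAMES))

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.dropout(self.lin1(x))).sigmoid()


class LocalizationNet(Module):
    """Full multi-view model: enabled extractors -> concat -> sigmoid head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.kmer_branch = (
            SequenceExtractor(rng, KMER_DIM, config) if config.use_kmer else None
        )
        self.cksnap_branch = (
            SequenceExtractor(rng, CKSNAP_DIM, config) if config.use_cksnap else None
        )
        self.graph_branch1 = GraphExtractor(rng, config) if config.use_graph1 else None
        self.graph_branch2 = GraphExtractor(rng, config) if config.use_graph2 else None
        self.head = PredictionHead(rng, config.concat_dim, config.head_hidden,
                                   config.dropout)
        self.np_dtype = np.dtype(config.dtype)
        self.astype(self.np_dtype)

    def parameters(self) -> list[Tensor]:
        params = []
        for m in (self.kmer_branch, self.cksnap_branch, self.graph_branch1,
                  self.graph_branch2, self.head):
            if m is not None:
                params.extend(m.parameters())
        return params

    def _submodules(self):
        for m in (self.kmer_branch, self.cksnap_branch, self.graph_branch1,
                  self.graph_branch2, self.head):
            if m is not None:
                yield m

    def forward(
        self,
        kmer: np.ndarray | None = None,
        cksnap: np.ndarray | None = None,
        graphs1: GraphBatch | None = None,
        graphs2: GraphBatch | None = None,
        edge_mask1: Tensor | None = None,
        edge_mask2: Tensor | None = None,
    ) -> Tensor:
        """Predicted probabilities, shape (B, 6).

        Optional edge masks (one value per undirected edge of the
        corresponding graph batch) scale the messages in that graph branch;
        they exist for interpretation.
        """
        embeddings = []
        if self.kmer_branch is not None:
            if kmer is None:
                raise ConfigError("model requires k-mer features")
            embeddings.append(
                self.kmer_branch(Tensor(np.asarray(kmer, dtype=self.np_dtype)))
            )
        if self.cksnap_branch is not None:
            if cksnap is None:
                raise ConfigError("model requires CKSNAP features")
            embeddings.append(
                self.cksnap_branch(Tensor(np.asarray(cksnap, dtype=self.np_dtype)))
            )
        if self.graph_branch1 is not None:
            if graphs1 is None:
                raise ConfigError("model requires the first structure graph")
            graphs1.x = graphs1.x.astype(self.np_dtype, copy=False)
            embeddings.append(self.graph_branch1(graphs1, edge_mask=edge_mask1))
        if self.graph_branch2 is not None:
            if graphs2 is None:
                raise ConfigError("model requires the second structure graph")
            graphs2.x = graphs2.x.astype(self.np_dtype, copy=False)
            embeddings.append(self.graph_branch2(graphs2, edge_mask=edge_mask2))
        return self.head(concat(embeddings, axis=1))

    __call__ = forward

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON sidecar with config + label order."""
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        arrays.update({f"b{i}": a for i, a in enumerate(self.buffer_arrays())})
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "label_order": list(LABEL_NAMES),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "LocalizationNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ConfigError(
                f"unsupported checkpoint version {meta.get('version')!r}"
            )
        if meta.get("label_order") != list(LABEL_NAMES):
            raise ConfigError("checkpoint label order does not match this package")
        model = cls(ModelConfig.from_dict(meta["config"]), seed=seed)
        with np.load(path.with_suffix(".npz")) as npz:
            n_params = sum(1 for k in npz.files if k.startswith("p"))
            n_bufs = sum(1 for k in npz.files if k.startswith("b"))
            model.load_state_arrays([npz[f"p{i}"] for i in range(n_params)])
            model.load_buffer_arrays([npz[f"b{i}"] for i in range(n_bufs)])
        return model


def make_optimizer(model: LocalizationNet, lr: float) -> Adam:
    return Adam(model.parameters(), lr=lr)
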