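"""Neural-network building blocks on top of the autodiff engine.

Provides the layers the localization model composes: linear/MLP stacks with
dropout, multi-head scaled-dot-product self-attention, three GNN message
passing variants (GIN, GCN, GAT), the set2set recurrent-attention readout,
and the Adam optimizer. Graph mini-batches are disjoint unions with a
per-node graph-membership index, so all graph ops are vectorized over the
whole batch.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, concat
from .errors import ConfigError

# ---------------------------------------------------------------------------
# Module infrastructure
# ---------------------------------------------------------------------------


class Module:
    """Minimal parameter container with train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def astype(self, dtype) -> "Module":
        """Cast all parameters in place (e.g. float32 for faster training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def buffer_arrays(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats), in tree order."""
        out = [getattr(self, name) for name in getattr(self, "_buffer_names", ())]
        for m in self._submodules():
            out.extend(m.buffer_arrays())
        return out

    def load_buffer_arrays(self, arrays: list[np.ndarray]) -> None:
        expected = self.buffer_arrays()
        if len(arrays) != len(expected):
            raise ConfigError(
                f"checkpoint has {len(arrays)} buffers, model expects "
                f"{len(expected)}"
            )
        it = iter(arrays)
        self._assign_buffers(it)

    def _assign_buffers(self, it) -> None:
        for name in getattr(self, "_buffer_names", ()):
            setattr(self, name, np.asarray(next(it)))
        for m in self._submodules():
            m._assign_buffers(it)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ConfigError(
                f"checkpoint has {len(arrays)} parameter arrays, model expects "
                f"{len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ConfigError(
                    f"checkpoint parameter shape {a.shape} does not match model "
                    f"shape {p.data.shape}"
                )
            p.data = np.asarray(a, dtype=p.data.dtype)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int,
                 bias: bool = True):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W = glorot(rng, in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ConfigError(
                f"Linear expected input dim {self.in_dim}, got {x.shape[-1]}"
            )
        out = x @ self.W
        return out + self.b if self.b is not None else out


class Dropout(Module):
    """Inverted dropout driven by an owned seeded generator."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        dtype = x.data.dtype
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep)
        return x * Tensor(mask.astype(dtype) * np.asarray(1.0 / keep, dtype=dtype))


class BatchNorm(Module):
    """Per-feature batch normalization with running statistics for eval."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._buffer_names = ("running_mean", "running_var")

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            x_hat = (x - mu) * (var + self.eps) ** -0.5
        else:
            dtype = x.data.dtype
            mu = Tensor(self.running_mean.astype(dtype))
            scale = Tensor(
                (1.0 / np.sqrt(self.running_var + self.eps)).astype(dtype)
            )
            x_hat = (x - mu) * scale
        return x_hat * self.gamma + self.beta


class MLP(Module):
    """Linear stack with ReLU activations and dropout after each hidden layer.

    With `use_norm` a BatchNorm sits between each linear map and its ReLU
    (the convention for GIN update networks).
    """

    def __init__(self, rng, dims: list[int], dropout: float = 0.0,
                 final_activation: bool = False, use_norm: bool = False):
        super().__init__()
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.norms = [BatchNorm(b) for b in dims[1:]] if use_norm else []
        self.dropout = Dropout(dropout, rng)
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            last = i == len(self.layers) - 1
            if not last or self.final_activation:
                if self.norms:
                    x = self.norms[i](x)
                x = x.relu()
                x = self.dropout(x)
        return x


# ---------------------------------------------------------------------------
# Multi-head self-attention
# ---------------------------------------------------------------------------


class MultiHeadSelfAttention(Module):
    """Scaled dot-product attention over token sequences.

    head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i with Q_i = X W_i^Q,
    K_i = X W_i^K, V_i = X W_i^V; the concatenated heads pass through the
    output projection W_0. Input shape (B, T, d_model).
    """

    def __init__(self, rng, d_model: int, n_heads: int):
        super().__init__()
        if d_model % n_heads != 0:
            raise ConfigError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.Wq = Linear(rng, d_model, d_model, bias=False)
        self.Wk = Linear(rng, d_model, d_model, bias=False)
        self.Wv = Linear(rng, d_model, d_model, bias=False)
        self.Wo = Linear(rng, d_model, d_model, bias=False)

    def _split_heads(self, x: Tensor, B: int, T: int) -> Tensor:
        # (B, T, d_model) -> (B*H, T, d_head)
        return (
            x.reshape(B, T, self.n_heads, self.d_head)
            .transpose((0, 2, 1, 3))
            .reshape(B * self.n_heads, T, self.d_head)
        )

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Attention matrices (B*H, T, T) for inspection; no grad tracking."""
        _, alpha = self._forward(x, return_alpha=True)
        return alpha

    def _forward(self, x: Tensor, return_alpha: bool = False):
        if x.ndim != 3 or x.shape[2] != self.d_model:
            raise ConfigError(
                f"attention expects (B, T, {self.d_model}) input, got {x.shape}"
            )
        B, T, _ = x.shape
        q = self._split_heads(self.Wq(x), B, T)
        k = self._split_heads(self.Wk(x), B, T)
        v = self._split_heads(self.Wv(x), B, T)
        scores = (q @ k.transpose((0, 2, 1))) * float(1.0 / np.sqrt(self.d_head))
        # softmax over the last axis; max-shift is a gradient-free constant
        shifted = scores - Tensor(scores.data.max(axis=-1, keepdims=True))
        e = shifted.exp()
        alpha = e / e.sum(axis=-1, keepdims=True)
        out = alpha @ v
        out = (
            out.reshape(B, self.n_heads, T, self.d_head)
            .transpose((0, 2, 1, 3))
            .reshape(B, T, self.d_model)
        )
        out = self.Wo(out)
        if return_alpha:
            return out, alpha.data
        return out, None

    def __call__(self, x: Tensor) -> Tensor:
        out, _ = self._forward(x)
        return out


# ---------------------------------------------------------------------------
# Graph batches and GNN layers
# ---------------------------------------------------------------------------


class GraphBatch:
    """Disjoint union of structure graphs.

    Attributes
    ----------
    x : np.ndarray
        Node features, shape (N_total, F).
    src, dst : np.ndarray
        Directed edge endpoints (every undirected edge doubled).
    edge_uid : np.ndarray
        Undirected-edge id per directed edge (for edge masking).
    batch : np.ndarray
        Graph-membership index per node.
    n_graphs : int
    n_und_edges : int
        Number of undirected edges across the batch.
    """

    def __init__(self, graphs):
        xs, srcs, dsts, uids, batch = [], [], [], [], []
        node_off = 0
        uid_off = 0
        self.graph_slices: list[tuple[int, int]] = []
        for g_idx, g in enumerate(graphs):
            if g.n_nodes == 0:
                raise ConfigError("empty graph in batch")
            xs.append(g.node_features)
            s, d, u = g.directed_edges()
            srcs.append(s + node_off)
            dsts.append(d + node_off)
            uids.append(u + uid_off)
            batch.append(np.full(g.n_nodes, g_idx, dtype=np.int64))
            self.graph_slices.append((uid_off, uid_off + g.n_edges))
            node_off += g.n_nodes
            uid_off += g.n_edges
        self.x = np.concatenate(xs, axis=0)
        self.src = np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64)
        self.dst = np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64)
        self.edge_uid = np.concatenate(uids) if uids else np.zeros(0, dtype=np.int64)
        self.batch = np.concatenate(batch)
        self.n_graphs = len(graphs)
        self.n_nodes = node_off
        self.n_und_edges = uid_off
        # symmetric adjacency for the fast (unmasked) aggregation path and
        # reduceat boundaries for the contiguous per-graph segment ops
        self.adjacency = sp.csr_matrix(
            (np.ones(len(self.src), dtype=np.float32), (self.dst, self.src)),
            shape=(self.n_nodes, self.n_nodes),
        )
        self.graph_starts = np.searchsorted(self.batch, np.arange(self.n_graphs))


def neighbor_sum(h: Tensor, batch: GraphBatch) -> Tensor:
    """Sum of neighbor features via the sparse adjacency (symmetric, so the
    backward pass reuses the same matrix)."""
    adj = batch.adjacency
    if adj.dtype != h.data.dtype:
        adj = adj.astype(h.data.dtype)
        batch.adjacency = adj

    def backward(out):
        if h.requires_grad:
            h._accum(adj @ out.grad)

    data = adj @ h.data
    rg = h.requires_grad
    return Tensor(data, requires_grad=rg, _parents=(h,) if rg else (),
                  _backward=backward if rg else None)


def segment_sum_contiguous(x: Tensor, starts: np.ndarray,
                           index: np.ndarray) -> Tensor:
    """Segment sum for contiguous, non-empty segments (np.add.reduceat)."""

    def backward(out):
        if x.requires_grad:
            x._accum(out.grad[index])

    data = np.add.reduceat(x.data, starts, axis=0)
    rg = x.requires_grad
    return Tensor(data, requires_grad=rg, _parents=(x,) if rg else (),
                  _backward=backward if rg else None)


def _edge_weights(edge_mask: Tensor | None, batch: GraphBatch) -> Tensor | None:
    """Per-directed-edge weight column from an undirected-edge mask."""
    if edge_mask is None:
        return None
    return edge_mask.gather_rows(batch.edge_uid).reshape(-1, 1)


class GINLayer(Module):
    """Graph isomorphism network update.

    h_v' = MLP((1 + eps) * h_v + sum_{u in N(v)} h_u), with a learnable eps
    and neighbors taken over the union of adjacent and base-pair edges.
    """

    def __init__(self, rng, in_dim: int, hidden_dim: int, out_dim: int,
                 dropout: float = 0.0):
        super().__init__()
        self.eps = Tensor(np.zeros(1), requires_grad=True)
        self.mlp = MLP(rng, [in_dim, hidden_dim, out_dim], dropout=dropout,
                       final_activation=True, use_norm=True)

    def __call__(self, h: Tensor, batch: GraphBatch,
                 edge_mask: Tensor | None = None) -> Tensor:
        if edge_mask is None:
            agg = neighbor_sum(h, batch)
        else:
            msg = h.gather_rows(batch.src) * _edge_weights(edge_mask, batch)
            agg = msg.segment_sum(batch.dst, batch.n_nodes)
        return self.mlp(h * (1.0 + self.eps) + agg)


class GCNLayer(Module):
    """Graph convolution with symmetric degree normalization and self-loops."""

    def __init__(self, rng, in_dim: int, hidden_dim: int, out_dim: int,
                 dropout: float = 0.0):
        super().__init__()
        del hidden_dim  # single linear transform; kept for a uniform signature
        self.lin = Linear(rng, in_dim, out_dim)
        self.dropout = Dropout(dropout, rng)

    def __call__(self, h: Tensor, batch: GraphBatch,
                 edge_mask: Tensor | None = None) -> Tensor:
        dtype = h.data.dtype
        deg = np.bincount(batch.dst, minlength=batch.n_nodes) + 1.0
        inv_sqrt = 1.0 / np.sqrt(deg)
        norm = (inv_sqrt[batch.src] * inv_sqrt[batch.dst]).astype(dtype)
        msg = h.gather_rows(batch.src) * Tensor(norm[:, None])
        w = _edge_weights(edge_mask, batch)
        if w is not None:
            msg = msg * w
        agg = msg.segment_sum(batch.dst, batch.n_nodes)
        agg = agg + h * Tensor((1.0 / deg[:, None]).astype(dtype))  # self-loop
        return self.dropout(self.lin(agg).relu())


class GATLayer(Module):
    """Single-head graph attention with self-loops folded into the softmax."""

    def __init__(self, rng, in_dim: int, hidden_dim: int, out_dim: int,
                 dropout: float = 0.0):
        super().__init__()
        del hidden_dim
        self.lin = Linear(rng, in_dim, out_dim, bias=False)
        self.a_src = glorot(rng, out_dim, 1)
        self.a_dst = glorot(rng, out_dim, 1)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)
        self.dropout = Dropout(dropout, rng)

    def __call__(self, h: Tensor, batch: GraphBatch,
                 edge_mask: Tensor | None = None) -> Tensor:
        z = self.lin(h)
        # attention logits for real edges plus one self-loop per node
        src = np.concatenate([batch.src, np.arange(batch.n_nodes)])
        dst = np.concatenate([batch.dst, np.arange(batch.n_nodes)])
        alpha_src = (z @ self.a_src).gather_rows(src)
        alpha_dst = (z @ self.a_dst).gather_rows(dst)
        logits = (alpha_src + alpha_dst).leaky_relu(0.2)
        alpha = segment_softmax(logits, dst, batch.n_nodes)
        msg = z.gather_rows(src) * alpha
        if edge_mask is not None:
            w = edge_mask.gather_rows(batch.edge_uid).reshape(-1, 1)
            msg = msg * _concat_rows(w, batch.n_nodes, h.data.dtype)
        agg = msg.segment_sum(dst, batch.n_nodes)
        return self.dropout((agg + self.bias).relu())


def _concat_rows(w: Tensor, n_extra: int, dtype=np.float64) -> Tensor:
    """Append `n_extra` rows of ones (unmasked self-loops) below `w`."""
    return concat([w, Tensor(np.ones((n_extra, 1), dtype=dtype))], axis=0)


def segment_softmax(logits: Tensor, index: np.ndarray, n_segments: int,
                    starts: np.ndarray | None = None) -> Tensor:
    """Softmax over rows sharing a segment index; shape preserved.

    The per-segment max used for numerical stability is treated as a constant
    shift, which leaves the softmax gradient unchanged. When segments are
    contiguous and non-empty, pass `starts` (first row of each segment) to use
    the faster reduceat path.
    """
    if starts is not None:
        seg_max = np.maximum.reduceat(logits.data, starts, axis=0)
        e = (logits - Tensor(seg_max[index])).exp()
        denom = segment_sum_contiguous(e, starts, index)
        return e / denom.gather_rows(index)
    seg_max = np.full((n_segments,) + logits.shape[1:], -np.inf,
                      dtype=logits.data.dtype)
    np.maximum.at(seg_max, index, logits.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    e = (logits - Tensor(seg_max[index])).exp()
    denom = e.segment_sum(index, n_segments)
    return e / denom.gather_rows(index)


class LSTMCell(Module):
    def __init__(self, rng, input_dim: int, hidden_dim: int):
        super().__init__()
        self.hidden_dim = hidden_dim
        self.Wx = glorot(rng, input_dim, 4 * hidden_dim)
        self.Wh = glorot(rng, hidden_dim, 4 * hidden_dim)
        self.b = Tensor(np.zeros(4 * hidden_dim), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor):
        gates = x @ self.Wx + h @ self.Wh + self.b
        d = self.hidden_dim
        i = gates[:, 0 * d : 1 * d].sigmoid()
        f = gates[:, 1 * d : 2 * d].sigmoid()
        g = gates[:, 2 * d : 3 * d].tanh()
        o = gates[:, 3 * d : 4 * d].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class Set2Set(Module):
    """Recurrent-attention global pooling: d-dim nodes -> 2d-dim graph vector.

    Each processing step queries the node set with an LSTM state, forms an
    attention-weighted sum per graph, and feeds [query, readout] back into the
    LSTM. Permutation invariant by construction.
    """

    def __init__(self, rng, dim: int, processing_steps: int = 3):
        super().__init__()
        self.dim = dim
        self.processing_steps = processing_steps
        self.lstm = LSTMCell(rng, 2 * dim, dim)

    def __call__(self, h: Tensor, batch_index: np.ndarray, n_graphs: int) -> Tensor:
        if h.shape[0] == 0:
            raise ConfigError("set2set received an empty node set")
        dtype = h.data.dtype
        q_star = Tensor(np.zeros((n_graphs, 2 * self.dim), dtype=dtype))
        hx = Tensor(np.zeros((n_graphs, self.dim), dtype=dtype))
        cx = Tensor(np.zeros((n_graphs, self.dim), dtype=dtype))
        starts = np.searchsorted(batch_index, np.arange(n_graphs))
        for _ in range(self.processing_steps):
            hx, cx = self.lstm(q_star, hx, cx)
            energies = (h * hx.gather_rows(batch_index)).sum(axis=1, keepdims=True)
            alpha = segment_softmax(energies, batch_index, n_graphs, starts=starts)
            readout = segment_sum_contiguous(h * alpha, starts, batch_index)
            q_star = concat([hx, readout], axis=1)
        return q_star


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
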