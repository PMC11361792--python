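"""Model components: attention, GIN, set2set, head, and the full network."""

import numpy as np
import pytest

from rnaloc.autodiff import Tensor
from rnaloc.errors import ConfigError
from rnaloc.model import (
    GraphExtractor,
    LocalizationNet,
    ModelConfig,
    PredictionHead,
    SequenceExtractor,
)
from rnaloc.nn import Adam, GINLayer, GraphBatch, MultiHeadSelfAttention, Set2Set
from rnaloc.structure import StructureGraph
from rnaloc.training import _batch_inputs, bce_multilabel_loss, prepare_records

RNG = np.random.default_rng(3)


def make_graph(n_nodes, edges, features=None, pair_edges=()):
    feats = features if features is not None else np.eye(n_nodes, 10)
    return StructureGraph(
        n_nodes=n_nodes,
        node_features=np.asarray(feats, dtype=float),
        adjacent_edges=list(edges),
        pair_edges=list(pair_edges),
    )


# -- attention ---------------------------------------------------------------

def identity_attention(d=1):
    attn = MultiHeadSelfAttention(np.random.default_rng(0), d_model=d, n_heads=1)
    for lin in (attn.Wq, attn.Wk, attn.Wv, attn.Wo):
        lin.W.data = np.eye(d)
    return attn


def test_attention_hand_computed_single_head():
    """One head, d=1, identity projections, X = (1, 0)^T: row 1 attends with
    softmax((1, 0)) = (e/(e+1), 1/(e+1)), so output_1 = e/(e+1)."""
    attn = identity_attention(d=1)
    x = Tensor(np.array([[[1.0], [0.0]]]))
    out = attn(x)
    e = np.e
    np.testing.assert_allclose(out.data[0, 0, 0], e / (e + 1), atol=1e-12)
    np.testing.assert_allclose(out.data[0, 1, 0], 0.5, atol=1e-12)


def test_attention_rows_are_probability_distributions():
    attn = MultiHeadSelfAttention(RNG, d_model=8, n_heads=4)
    x = Tensor(RNG.normal(size=(3, 5, 8)))
    alpha = attn.attention_weights(x)
    assert alpha.shape == (12, 5, 5)
    assert (alpha >= 0).all()
    np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)


def test_attention_zero_input_gives_zero_output():
    attn = MultiHeadSelfAttention(RNG, d_model=4, n_heads=2)
    out = attn(Tensor(np.zeros((2, 3, 4))))
    np.testing.assert_allclose(out.data, 0.0)


# -- GIN ---------------------------------------------------------------------

def identity_gin(dim):
    layer = GINLayer(np.random.default_rng(0), dim, dim, dim)
    for lin in layer.mlp.layers:
        lin.W.data = np.eye(dim)
        lin.b.data = np.zeros(dim)
    layer.mlp.layers = layer.mlp.layers[:1]  # single identity transform
    layer.mlp.final_activation = False
    return layer


def test_gin_path_graph_neighbor_sums():
    """eps=0, identity MLP, path 1-2-3 with scalar features (1,2,3):
    updated features are (1+2, 2+1+3, 3+2) = (3, 6, 5)."""
    layer = identity_gin(1)
    g = make_graph(3, [(0, 1), (1, 2)], features=[[1.0], [2.0], [3.0]])
    batch = GraphBatch([g])
    out = layer(Tensor(batch.x), batch)
    np.testing.assert_allclose(out.data.ravel(), [3.0, 6.0, 5.0])


def test_gin_isolated_node_keeps_scaled_self_feature():
    layer = identity_gin(1)
    layer.eps.data = np.array([0.5])
    g = make_graph(1, [], features=[[2.0]])
    batch = GraphBatch([g])
    out = layer(Tensor(batch.x), batch)
    np.testing.assert_allclose(out.data.ravel(), [3.0])  # (1 + 0.5) * 2


def test_gin_matches_bruteforce_equation_on_random_graphs(rng):
    """MLP=identity, fixed eps: output equals the direct neighbor-sum formula
    on random graphs of <= 10 nodes, to 1e-9."""
    for _ in range(20):
        n = int(rng.integers(2, 11))
        layer = identity_gin(4)
        eps = float(rng.normal())
        layer.eps.data = np.array([eps])
        adj = [(i - 1, i) for i in range(1, n)]
        extra = [
            tuple(sorted(rng.choice(n, 2, replace=False)))
            for _ in range(int(rng.integers(0, n)))
        ]
        extra = [e for e in set(extra) if abs(e[0] - e[1]) >= 2]
        feats = rng.normal(size=(n, 4))
        g = make_graph(n, adj, features=feats, pair_edges=extra)
        batch = GraphBatch([g])
        out = layer(Tensor(batch.x), batch).data

        expected = np.zeros_like(feats)
        for v in range(n):
            nbrs = [u for (a, b) in adj + extra for u in (a, b)
                    if v in (a, b) and u != v]
            expected[v] = (1 + eps) * feats[v] + feats[nbrs].sum(axis=0) \
                if nbrs else (1 + eps) * feats[v]
        np.testing.assert_allclose(out, expected, atol=1e-9)


def test_gin_is_permutation_equivariant(rng):
    layer = GINLayer(np.random.default_rng(5), 10, 16, 16)
    layer.eval()
    n = 8
    feats = rng.normal(size=(n, 10))
    edges = [(i - 1, i) for i in range(1, n)]
    g = make_graph(n, edges, features=feats)
    out = layer(Tensor(GraphBatch([g]).x), GraphBatch([g])).data

    perm = rng.permutation(n)
    inv = np.argsort(perm)
    p_edges = [tuple(sorted((int(inv[a]), int(inv[b])))) for a, b in edges]
    gp = make_graph(n, p_edges, features=feats[perm])
    outp = layer(Tensor(GraphBatch([gp]).x), GraphBatch([gp])).data
    np.testing.assert_allclose(outp, out[perm], atol=1e-9)


# -- set2set -----------------------------------------------------------------

def test_set2set_output_dim_and_permutation_invariance(rng):
    pool = Set2Set(np.random.default_rng(2), dim=6, processing_steps=3)
    x = rng.normal(size=(7, 6))
    batch_idx = np.zeros(7, dtype=np.int64)
    out = pool(Tensor(x), batch_idx, 1)
    assert out.data.shape == (1, 12)
    perm = rng.permutation(7)
    out_p = pool(Tensor(x[perm]), batch_idx, 1)
    np.testing.assert_allclose(out_p.data, out.data, atol=1e-6)


def test_set2set_single_node_matches_direct_computation():
    """With one node, attention is a point mass: the readout equals the node
    embedding and q* = [LSTM query, node]."""
    pool = Set2Set(np.random.default_rng(4), dim=3, processing_steps=1)
    x = np.array([[0.3, -1.2, 2.0]])
    out = pool(Tensor(x), np.zeros(1, dtype=np.int64), 1).data
    q, _ = pool.lstm(Tensor(np.zeros((1, 6))), Tensor(np.zeros((1, 3))),
                     Tensor(np.zeros((1, 3))))
    np.testing.assert_allclose(out[0, :3], q.data[0], atol=1e-9)
    np.testing.assert_allclose(out[0, 3:], x[0], atol=1e-9)


def test_set2set_rejects_empty_input():
    pool = Set2Set(np.random.default_rng(0), dim=2)
    with pytest.raises(ConfigError):
        pool(Tensor(np.zeros((0, 2))), np.zeros(0, dtype=np.int64), 0)


# -- prediction head ---------------------------------------------------------

def test_head_all_zero_weights_gives_half_probabilities():
    head = PredictionHead(np.random.default_rng(0), 8, 4, dropout=0.0)
    for p in head.parameters():
        p.data[...] = 0.0
    out = head(Tensor(np.zeros((2, 8))))
    np.testing.assert_allclose(out.data, 0.5)


def test_head_scalar_identity_example():
    """1-dim toy: W1=1, b1=0, W2=1, b2=0, x=0.8473 -> sigmoid(0.8473)."""
    head = PredictionHead(np.random.default_rng(0), 1, 1, dropout=0.0)
    head.lin1.W.data = np.array([[1.0]])
    head.lin1.b.data = np.array([0.0])
    head.lin2.W.data = np.ones((1, 6))
    head.lin2.b.data = np.zeros(6)
    out = head(Tensor(np.array([[0.8473]])))
    np.testing.assert_allclose(out.data, 1 / (1 + np.exp(-0.8473)), atol=1e-9)
    assert abs(out.data[0, 0] - 0.700) < 5e-4


def test_head_outputs_strictly_inside_unit_interval(rng):
    head = PredictionHead(np.random.default_rng(1), 8, 4, dropout=0.0)
    out = head(Tensor(rng.normal(size=(10, 8)) * 5)).data
    assert ((out > 0) & (out < 1)).all()


# -- extractors and full model ----------------------------------------------

def test_sequence_extractors_emit_128_and_are_deterministic_in_eval():
    cfg = ModelConfig(dtype="float64")
    for in_dim in (1364, 96):
        branch = SequenceExtractor(np.random.default_rng(0), in_dim, cfg)
        branch.eval()
        x = Tensor(RNG.normal(size=(2, in_dim)))
        out1, out2 = branch(x).data, branch(x).data
        assert out1.shape == (2, 128)
        np.testing.assert_array_equal(out1, out2)
        assert np.isfinite(branch(Tensor(np.zeros((1, in_dim)))).data).all()


def test_graph_extractor_emits_128_and_depends_only_on_structure():
    cfg = ModelConfig(dtype="float64")
    branch = GraphExtractor(np.random.default_rng(0), cfg)
    branch.eval()
    feats = RNG.normal(size=(5, 10))
    g1 = make_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)], features=feats,
                    pair_edges=[(0, 4)])
    g2 = make_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)], features=feats.copy(),
                    pair_edges=[(0, 4)])
    out1 = branch(GraphBatch([g1])).data
    out2 = branch(GraphBatch([g2])).data
    assert out1.shape == (1, 128)
    np.testing.assert_allclose(out1, out2, atol=1e-6)


@pytest.mark.parametrize("variant", ["gin", "gcn", "gat"])
def test_gnn_variants_all_run(variant, folded_records):
    cfg = ModelConfig(gnn_variant=variant)
    model = LocalizationNet(cfg, seed=0)
    model.eval()
    prep = prepare_records(folded_records[:4])
    probs = model.forward(**_batch_inputs(prep)).data
    assert probs.shape == (4, 6)
    assert ((probs > 0) & (probs < 1)).all()


def test_full_model_concat_width_and_ablations():
    assert ModelConfig().concat_dim == 512
    seq_only = ModelConfig(use_graph1=False, use_graph2=False)
    assert seq_only.concat_dim == 256
    with pytest.raises(ConfigError):
        ModelConfig(use_kmer=False, use_cksnap=False, use_graph1=False,
                    use_graph2=False)


def test_full_model_deterministic_in_eval_mode(folded_records):
    model = LocalizationNet(ModelConfig(), seed=0)
    model.eval()
    prep = prepare_records(folded_records[:3])
    p1 = model.forward(**_batch_inputs(prep)).data
    p2 = model.forward(**_batch_inputs(prep)).data
    np.testing.assert_array_equal(p1, p2)


def test_one_adam_step_decreases_single_sample_loss(folded_records):
    """Gradient flow: a small enough Adam step on one sample reduces its loss."""
    model = LocalizationNet(ModelConfig(dtype="float64"), seed=1)
    model.eval()  # disable dropout so the comparison is exact
    prep = prepare_records(folded_records[:1])
    inputs = _batch_inputs(prep)
    y = np.stack([p.record.labels for p in prep])
    probs = model.forward(**inputs)
    loss0 = bce_multilabel_loss(y, probs)
    opt = Adam(model.parameters(), lr=1e-4)
    opt.zero_grad()
    loss0.backward()
    opt.step()
    loss1 = bce_multilabel_loss(y, model.forward(**_batch_inputs(prep)))
    assert loss1.item() < loss0.item()


def test_checkpoint_round_trip_and_config_guard(tmp_path, folded_records):
    model = LocalizationNet(ModelConfig(), seed=0)
    model.eval()
    prep = prepare_records(folded_records[:2])
    before = model.forward(**_batch_inputs(prep)).data
    model.save(tmp_path / "ckpt")
    loaded = LocalizationNet.load(tmp_path / "ckpt")
    loaded.eval()
    after = loaded.forward(**_batch_inputs(prep)).data
    np.testing.assert_array_equal(before, after)

    import json
    meta_path = (tmp_path / "ckpt").with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    meta["config"]["gnn_hidden"] = 999
    meta_path.write_text(json.dumps(meta))
    with pytest.raises(ConfigError):
        LocalizationNet.load(tmp_path / "ckpt")
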