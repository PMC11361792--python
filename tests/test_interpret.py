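"""Edge-mask interpretation, top-edge ranking, substructure extraction."""

import networkx as nx
import numpy as np

from rnaloc.autodiff import Tensor
from rnaloc.interpret import (
    EdgeScore,
    extract_substructures,
    learn_edge_mask,
    node_feature_importance,
    substructure_proportions,
    top_edges,
)
from rnaloc.model import LocalizationNet, ModelConfig
from rnaloc.structure import EDGE_ADJACENT, EDGE_BASE_PAIR, StructureGraph
from rnaloc.training import _batch_inputs, prepare_records


def make_graph(seq, adjacent, pairs):
    from rnaloc.encoders import node_feature_matrix

    return StructureGraph(
        n_nodes=len(seq),
        node_features=node_feature_matrix(seq),
        adjacent_edges=adjacent,
        pair_edges=pairs,
        sequence=seq,
    )


# -- masked forward ----------------------------------------------------------

def test_all_ones_mask_equals_unmasked_forward(folded_records):
    model = LocalizationNet(ModelConfig(), seed=0)
    model.eval()
    prep = prepare_records(folded_records[:2])
    inputs = _batch_inputs(prep)
    base = model.forward(**inputs).data
    ones = Tensor(np.ones(inputs["graphs1"].n_und_edges, dtype=np.float32))
    masked = model.forward(**inputs, edge_mask1=ones).data
    np.testing.assert_allclose(masked, base, atol=1e-6)


def test_learned_mask_scores_are_bounded_and_reproducible(folded_records):
    model = LocalizationNet(ModelConfig(), seed=0)
    prep = prepare_records(folded_records[:1])[0]
    s1 = learn_edge_mask(model, prep, steps=5, seed=3)
    s2 = learn_edge_mask(model, prep, steps=5, seed=3)
    assert len(s1) == prep.graph1.n_edges
    assert all(0.0 <= e.score <= 1.0 for e in s1)
    assert [e.score for e in s1] == [e.score for e in s2]
    # 1-based positions
    assert min(min(e.i, e.j) for e in s1) >= 1


# -- top-k ranking -----------------------------------------------------------

def test_top_edges_saturation_argmax_and_tie_rule():
    scores = [
        EdgeScore(1, 2, EDGE_ADJACENT, 0.9),
        EdgeScore(2, 3, EDGE_ADJACENT, 0.5),
        EdgeScore(3, 4, EDGE_ADJACENT, 0.9),
    ]
    assert len(top_edges(scores, k=10)) == 3
    assert top_edges(scores, k=1)[0].i == 1
    picked = top_edges(scores, k=2)
    assert [(e.i, e.j) for e in picked] == [(1, 2), (3, 4)]  # tie -> smaller endpoint


# -- substructures -----------------------------------------------------------

def test_substructure_single_chain_and_min_bases_filter():
    g = make_graph("ACGUACGUAC", [(i, i + 1) for i in range(9)], [])
    chain = [EdgeScore(1, 2, EDGE_ADJACENT, 0.9), EdgeScore(2, 3, EDGE_ADJACENT, 0.8)]
    subs = extract_substructures(g, chain)
    assert len(subs) == 1 and subs[0].positions == [1, 2, 3]
    two_pairs = [EdgeScore(1, 5, EDGE_BASE_PAIR, 0.9),
                 EdgeScore(2, 8, EDGE_BASE_PAIR, 0.8)]
    assert extract_substructures(g, two_pairs, min_bases=3) == []


def test_substructure_mixed_components_and_notation():
    g = make_graph("ACGUACGUACGU", [(i, i + 1) for i in range(11)],
                   [(4, 8), (3, 9)])
    edges = [
        EdgeScore(1, 2, EDGE_ADJACENT, 0.9),
        EdgeScore(6, 10, EDGE_BASE_PAIR, 0.8),
        EdgeScore(6, 7, EDGE_ADJACENT, 0.7),
    ]
    subs = extract_substructures(g, edges)
    assert len(subs) == 1
    assert subs[0].positions == [6, 7, 10]
    note = subs[0].notation()
    assert "==" in note and "<->" in note
    assert "(6)" in note and "(10)" in note


def test_substructures_match_networkx_components(rng):
    """Reference connected-components implementation on random edge subsets."""
    L = 40
    g = make_graph("ACGU" * 10, [(i, i + 1) for i in range(L - 1)],
                   [(0, 20), (5, 30), (10, 35)])
    all_edges = [
        EdgeScore(a + 1, b + 1, t, float(s))
        for (a, b), t, s in zip(g.edges, g.edge_types,
                                rng.random(len(g.edges)))
    ]
    for _ in range(10):
        subset = [e for e in all_edges if rng.random() < 0.2]
        ours = extract_substructures(g, subset, min_bases=3)
        G = nx.Graph()
        G.add_edges_from((e.i, e.j) for e in subset)
        expected = sorted(
            sorted(c) for c in nx.connected_components(G) if len(c) >= 3
        )
        assert [s.positions for s in ours] == expected


def test_substructure_proportions_reports_both_normalizations():
    g = make_graph("ACGUAC", [(i, i + 1) for i in range(5)], [])
    sub = extract_substructures(
        g, [EdgeScore(1, 2, EDGE_ADJACENT, 0.9), EdgeScore(2, 3, EDGE_ADJACENT, 0.8)]
    )
    labels = {"a": np.array([1, 0, 0, 0, 0, 0]), "b": np.array([1, 0, 0, 0, 0, 0])}
    out = substructure_proportions({"a": sub, "b": []}, labels)
    stats = next(iter(out["nucleus"].values()))
    assert stats["per_record"] == 0.5
    assert stats["per_edge"] == 1.0


# -- node feature importance -------------------------------------------------

def test_node_feature_importance_shape_and_determinism(folded_records):
    model = LocalizationNet(ModelConfig(), seed=0)
    prep = prepare_records(folded_records[:3])
    imp1 = node_feature_importance(model, prep)
    imp2 = node_feature_importance(model, prep)
    assert set(imp1) == {"one_hot", "ncp", "eiip", "anf"}
    for group in imp1.values():
        assert set(group) == {"nucleus", "exosome", "cytosol", "ribosome",
                              "membrane", "er"}
        assert all(v >= 0 for v in group.values())
    assert imp1 == imp2


def test_occluding_an_ignored_feature_group_has_no_effect(folded_records):
    """A model whose first GNN layer ignores the EIIP column must assign it
    zero occlusion importance, and less than any used group."""
    model = LocalizationNet(ModelConfig(use_kmer=False, use_cksnap=False),
                            seed=0)
    for branch in (model.graph_branch1, model.graph_branch2):
        for lin in branch.layers[0].mlp.layers[:1]:
            lin.W.data[8, :] = 0.0  # EIIP row of the first transform
    prep = prepare_records(folded_records[:3])
    imp = node_feature_importance(model, prep)
    eiip_total = sum(imp["eiip"].values())
    anf_total = sum(imp["anf"].values())
    assert eiip_total < 1e-8
    assert anf_total > eiip_total
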