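from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from hypermux import (LayerGraph, PsoParams, borda_aggregate, grow_pso,
                      score_car, score_cjc, score_cn, score_hp, score_pa,
                      score_rank_cn_hp, score_wcn)
from hypermux.embedding import EmbeddingCoordinates, pairwise_distances
from hypermux.similarity import HIGHER, LOWER, ScoreTable, read_scores, write_scores


# --------------------------------------------------------------- oracles

def oracle_scores(G: nx.Graph, u, v):
    """Independent set-arithmetic implementation of PA/CN/CAR/CJC."""
    gu, gv = set(G[u]), set(G[v])
    common = gu & gv
    pa = len(gu) * len(gv)
    cn = len(common)
    lcl = sum(1 for a, b in combinations(common, 2) if G.has_edge(a, b))
    car = cn * lcl
    union = gu | gv
    cjc = car / len(union) if union else 0.0
    return {"pa": pa, "cn": cn, "car": car, "cjc": cjc}


SCORERS = {"pa": score_pa, "cn": score_cn, "car": score_car, "cjc": score_cjc}


@pytest.mark.parametrize("measure", sorted(SCORERS))
def test_structural_measures_match_brute_force(measure):
    for seed in range(10):
        G = nx.gnp_random_graph(12, 0.3, seed=seed)
        g = LayerGraph.from_networkx(G)
        g = LayerGraph(nodes=tuple(range(12)), edges=g.edges)
        table = SCORERS[measure](g)
        assert table.orientation == HIGHER
        for (u, v), s in table.scores.items():
            assert s == pytest.approx(oracle_scores(G, u, v)[measure]), (u, v)


def test_pa_examples():
    star = LayerGraph.from_networkx(nx.star_graph(3))
    assert score_pa(star)[(0, 1)] == 3.0
    g = LayerGraph(nodes=(0, 1, 2), edges=frozenset({(0, 1)}))
    assert score_pa(g)[(0, 2)] == 0.0


def test_cn_path_example(path3):
    assert score_cn(path3)[(0, 2)] == 1.0
    assert score_cn(path3)[(0, 1)] == 0.0  # disjoint neighborhoods


def test_car_cjc_k4_example():
    """K4 pair (0,1): CN=2, one edge between the common neighbors -> CAR=2;
    |union of neighborhoods| = 4 -> CJC = 0.5."""
    k4 = LayerGraph.from_networkx(nx.complete_graph(4))
    assert score_car(k4)[(0, 1)] == 2.0
    assert score_cjc(k4)[(0, 1)] == 0.5


def test_car_zero_when_single_common_neighbor(path3):
    assert score_car(path3)[(0, 2)] == 0.0


def test_cjc_empty_union_scores_zero():
    g = LayerGraph(nodes=(0, 1, 2, 3), edges=frozenset({(2, 3)}))
    assert score_cjc(g)[(0, 1)] == 0.0


# --------------------------------------------------------------- WCN

def coords_for(nodes, radii, angles):
    return EmbeddingCoordinates(nodes=tuple(nodes), radii=np.array(radii),
                                angles=np.array(angles), disk_radius=5.0,
                                temperature=0.5, gamma=3.0)


def test_wcn_no_common_neighbors_zero():
    g = LayerGraph(nodes=(0, 1, 2, 3), edges=frozenset({(0, 1), (2, 3)}))
    coords = coords_for(range(4), [1, 1, 1, 1], [0, 1, 2, 3])
    assert score_wcn(g, coords)[(0, 2)] == 0.0


def test_wcn_symmetric_path_all_weak(path3):
    """Path 0-1-2 with symmetric coordinates: both tie distances equal the
    mean h, so both ties are weak (strict <) and WCN = 2 CN = 2."""
    coords = coords_for(range(3), [1, 1, 1], [0.0, 0.1, 0.2])
    assert score_wcn(path3, coords)[(0, 2)] == pytest.approx(2.0)


def test_wcn_strong_tie_adds_inverse_distance():
    """Pair whose common-neighbor ties are both shorter than the mean link
    distance gains 1/H per tie."""
    # path 0-1-2-3-4: ties (1,2),(2,3) short, edges (0,1),(3,4) long
    g = LayerGraph.from_edges([(0, 1), (1, 2), (2, 3), (3, 4)])
    coords = coords_for(range(5), [3, 1, 1, 1, 3], [2.0, 1.0, 1.05, 1.1, 0.1])
    table = score_wcn(g, coords)
    dists = dict(zip(sorted(g.edges),
                     pairwise_distances(coords, sorted(g.edges))))
    h = np.mean(list(dists.values()))
    d12, d23 = dists[(1, 2)], dists[(2, 3)]
    assert d12 < h and d23 < h
    assert table[(1, 3)] == pytest.approx((1 + 1 / d12) + (1 + 1 / d23))


def pseudocode_wcn(G: nx.Graph, coords, i, j):
    """Line-by-line transcription of the WCN procedure as an oracle."""
    H = {}
    for (u, v) in G.edges():
        H[frozenset((u, v))] = float(pairwise_distances(
            coords, [(min(u, v), max(u, v))])[0])
    h = np.mean(list(H.values()))
    wcn = 0.0
    for k in set(G[i]) & set(G[j]):
        for a, b in ((i, k), (k, j)):
            d = H[frozenset((a, b))]
            if d < h:
                wcn += 1 + 1 / d
            else:
                wcn += 1
    return wcn


def test_wcn_matches_pseudocode_oracle():
    rng = np.random.default_rng(7)
    G = nx.gnp_random_graph(14, 0.35, seed=3)
    g = LayerGraph(nodes=tuple(range(14)),
                   edges=LayerGraph.from_networkx(G).edges)
    coords = coords_for(range(14), rng.uniform(0.5, 6, 14),
                        rng.uniform(0, 2 * np.pi, 14))
    table = score_wcn(g, coords)
    for (u, v), s in table.scores.items():
        assert s == pytest.approx(pseudocode_wcn(G, coords, u, v)), (u, v)


def test_wcn_lower_bound_twice_cn():
    rng = np.random.default_rng(11)
    for seed in range(5):
        G = nx.gnp_random_graph(12, 0.4, seed=seed)
        g = LayerGraph(nodes=tuple(range(12)),
                       edges=LayerGraph.from_networkx(G).edges)
        if g.n_edges == 0:
            continue
        coords = coords_for(range(12), rng.uniform(0.5, 6, 12),
                            rng.uniform(0, 2 * np.pi, 12))
        wcn, cn = score_wcn(g, coords), score_cn(g)
        for p in wcn.scores:
            assert wcn.scores[p] >= 2 * cn.scores[p] - 1e-12


# --------------------------------------------------------------- Borda

def table_from_ranking(order, name="t"):
    """Build a higher-is-link table whose score ranking equals ``order``
    (best first)."""
    return ScoreTable(name, HIGHER,
                      {p: float(len(order) - i) for i, p in enumerate(order)})


def test_borda_consensus_preserves_order():
    order = [(0, 1), (0, 2), (1, 2), (2, 3)]
    agg = borda_aggregate([table_from_ranking(order), table_from_ranking(order)])
    assert agg.ranked() == order


def test_borda_opposite_rankings_full_tie():
    a, b, c = (0, 1), (0, 2), (1, 2)
    l1 = table_from_ranking([a, b, c])
    l2 = table_from_ranking([c, b, a])
    agg = borda_aggregate([l1, l2])
    assert agg.scores[a] == agg.scores[b] == agg.scores[c] == 2.0


def brute_borda(rankings, pairs):
    """Count-strictly-worse oracle over raw score lists."""
    total = {p: 0 for p in pairs}
    for scores in rankings:
        for p in pairs:
            total[p] += sum(1 for q in pairs if scores[q] < scores[p])
    return total


def test_borda_matches_count_strictly_worse_oracle():
    rng = np.random.default_rng(5)
    pairs = [(0, i) for i in range(1, 9)]
    tables, raw = [], []
    for k in range(6):
        scores = {p: float(v) for p, v in
                  zip(pairs, rng.permutation(len(pairs)))}
        tables.append(ScoreTable(f"l{k}", HIGHER, scores))
        raw.append(scores)
    agg = borda_aggregate(tables)
    expected = brute_borda(raw, pairs)
    for p in pairs:
        assert agg.scores[p] == expected[p]


def test_borda_handles_ties_with_equal_credit():
    pairs = [(0, 1), (0, 2), (1, 2)]
    t1 = ScoreTable("a", HIGHER, {pairs[0]: 1.0, pairs[1]: 1.0, pairs[2]: 0.0})
    t2 = ScoreTable("b", HIGHER, {pairs[0]: 2.0, pairs[1]: 1.0, pairs[2]: 0.0})
    agg = borda_aggregate([t1, t2])
    # t1: credits 1,1,0 (two tied above one); t2: credits 2,1,0
    assert agg.scores[pairs[0]] == 3.0
    assert agg.scores[pairs[1]] == 2.0
    assert agg.scores[pairs[2]] == 0.0


def test_borda_rejects_mismatched_pair_sets():
    t1 = ScoreTable("a", HIGHER, {(0, 1): 1.0})
    t2 = ScoreTable("b", HIGHER, {(0, 2): 1.0})
    with pytest.raises(ValueError, match="identical pair set"):
        borda_aggregate([t1, t2])


# --------------------------------------------------------------- Rank-CN-HP

def test_rank_cn_hp_agreement_preserves_order():
    """When CN and HP (after orientation) rank candidates identically the
    aggregate reproduces that order."""
    g = LayerGraph.from_edges([(0, 1), (0, 2), (1, 2), (1, 3), (2, 3),
                               (3, 4)])
    # CN: (0,3)=2 > (1,4)=1 > (0,4)=0; angles make distances agree
    coords = coords_for(range(5), [2, 2, 2, 2, 2],
                        [0.0, 0.5, 0.25, 0.05, 1.8])
    pairs = [(0, 3), (1, 4), (0, 4)]
    agg = score_rank_cn_hp(g, coords, pairs)
    cn = score_cn(g, pairs)
    hp = score_hp(coords, pairs)
    assert cn.ranked() == hp.ranked() == agg.ranked()


def test_two_pair_disagreement_ties():
    """CN prefers one pair, HP (smaller distance) the other: Borda ties."""
    pairs = [(0, 2), (1, 3)]
    cn = ScoreTable("cn", HIGHER, {pairs[0]: 2.0, pairs[1]: 1.0})
    hp = ScoreTable("hp", LOWER, {pairs[0]: 5.0, pairs[1]: 1.0})
    agg = borda_aggregate([cn, hp])
    assert agg.scores[pairs[0]] == agg.scores[pairs[1]] == 1.0


def test_rank_cn_hp_equals_component_composition():
    g, coords = grow_pso(PsoParams(n_nodes=60, m=3, gamma=3.0,
                                   temperature=0.3, seed=6))
    rng = np.random.default_rng(0)
    non_edges = [p for p in combinations(g.nodes, 2) if p not in g.edges]
    idx = rng.choice(len(non_edges), size=20, replace=False)
    pairs = [non_edges[i] for i in idx]
    agg = score_rank_cn_hp(g, coords, pairs)
    expected = borda_aggregate([score_cn(g, pairs), score_hp(coords, pairs)])
    assert agg.scores == expected.scores


# --------------------------------------------------------------- ScoreTable

def test_score_table_validation():
    with pytest.raises(ValueError, match="orientation"):
        ScoreTable("x", "sideways", {})
    with pytest.raises(ValueError, match="self-pair"):
        ScoreTable("x", HIGHER, {(1, 1): 0.0})
    with pytest.raises(ValueError, match="canonical"):
        ScoreTable("x", HIGHER, {(2, 1): 0.0})


def test_score_table_round_trip(tmp_path):
    table = ScoreTable("cn", HIGHER, {(0, 1): 2.0, (0, 2): 0.5})
    path = tmp_path / "scores.txt"
    write_scores(table, str(path))
    back = read_scores(str(path))
    assert back.measure == "cn"
    assert back.orientation == HIGHER
    assert back.scores == table.scores
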