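"""Interlayer relevance and multiplex score fusion.

Layers of a multiplex network tend to be structurally correlated, so the
score of a candidate pair in the target layer can borrow evidence from the
other layers.  Relevance between two layers is quantified by link overlap
O = 2 |E_a intersect E_b| / (|E_a| + |E_b|) (or by Pearson/Spearman
correlation of the vectorized pair indicators), and the fused multiplex
score is the relevance-weighted linear combination

    S_ij = s_ij^alpha + eta * sum_{beta != alpha} mu^{alpha,beta} s_ij^beta

with target layer alpha and a tunable coupling eta.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats

from .multiplex import LayerGraph, MultiplexNetwork
from .similarity import HIGHER, ScoreTable


@dataclass(frozen=True)
class LayerRelevance:
    """Symmetric matrix of pairwise relevance values mu^{alpha,beta}."""

    matrix: np.ndarray
    method: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("relevance matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("relevance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, ab: tuple[int, int]) -> float:
        return float(self.matrix[ab])


def link_overlap(a: LayerGraph, b: LayerGraph) -> float:
    """Fraction of shared links: 2 |E_a ∩ E_b| / (|E_a| + |E_b|).

    0 iff the edge sets are disjoint, 1 iff identical; errors when both
    layers are edgeless."""
    if a.nodes != b.nodes:
        raise ValueError("layers must share one node universe")
    if a.n_edges == 0 and b.n_edges == 0:
        raise ValueError("link overlap undefined for two empty layers")
    return 2.0 * len(a.edges & b.edges) / (a.n_edges + b.n_edges)


def layer_correlation(a: LayerGraph, b: LayerGraph, method: str = "pearson") -> float:
    """Pearson or Spearman correlation between the two layers' 0/1 indicator
    vectors over all unordered node pairs of the shared universe."""
    if a.nodes != b.nodes:
        raise ValueError("layers must share one node universe")
    pairs = list(combinations(a.nodes, 2))
    va = np.fromiter((p in a.edges for p in pairs), dtype=float, count=len(pairs))
    vb = np.fromiter((p in b.edges for p in pairs), dtype=float, count=len(pairs))
    if method == "pearson":
        return float(stats.pearsonr(va, vb).statistic)
    if method == "spearman":
        return float(stats.spearmanr(va, vb).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def compute_relevance(net: MultiplexNetwork, method: str = "lo") -> LayerRelevance:
    """All-pairs relevance matrix for a multiplex network; ``method`` is
    ``lo`` (link overlap, the default used throughout), ``pearson`` or
    ``spearman``."""
    m = net.n_layers
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            if method == "lo":
                val = link_overlap(net.layers[i], net.layers[j])
            else:
                val = layer_correlation(net.layers[i], net.layers[j], method)
            mat[i, j] = mat[j, i] = val
    return LayerRelevance(matrix=mat, method=method)


def fuse_scores(target_scores: ScoreTable,
                other_scores: Mapping[int, ScoreTable],
                relevance: LayerRelevance,
                target_layer: int,
                eta: float = 1.0) -> ScoreTable:
    """Fused multiplex score S = s^alpha + eta * sum_beta mu^{alpha,beta} s^beta.

    All tables must cover the identical pair set with the same measure
    orientation.  Distance-valued (lower_is_link) inputs are negated before
    fusion so the output is uniformly higher_is_link.
    """
    pair_set = set(target_scores.scores)
    for beta, table in other_scores.items():
        if beta == target_layer:
            raise ValueError("other_scores must not include the target layer")
        if table.orientation != target_scores.orientation:
            raise ValueError("orientation mismatch between layers")
        if set(table.scores) != pair_set:
            raise ValueError(f"layer {beta} scores cover a different pair set")
    sign = 1.0 if target_scores.orientation == HIGHER else -1.0
    pairs = sorted(pair_set)
    fused = sign * np.array([target_scores.scores[p] for p in pairs])
    for beta, table in other_scores.items():
        mu = relevance[target_layer, beta]
        fused += eta * mu * sign * np.array([table.scores[p] for p in pairs])
    name = f"fused-{target_scores.measure}"
    return ScoreTable(name, HIGHER, dict(zip(pairs, fused.tolist())))
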