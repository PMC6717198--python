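"""Per-layer node-pair similarity indices for link prediction.

Classical structural indices (preferential attachment, common neighbors,
CAR, CJC), the hyperbolic-distance index HP, and two hybrids that blend
popularity with hyperbolic similarity: WCN, which up-weights a common
neighbor whose tie to the candidate pair is hyperbolically short, and
Rank-CN-HP, a Borda rank aggregation of the CN and HP orderings.

Every index returns a ScoreTable; the orientation field records whether
larger values mean "more likely a link" (everything except raw HP distance,
where smaller distance means more likely).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .embedding import EmbeddingCoordinates, pairwise_distances
from .multiplex import LayerGraph, Pair, normalize_pair

WCN_MIN_DISTANCE = 1e-9  # cap for 1/H on coincident coordinates

HIGHER = "higher_is_link"
LOWER = "lower_is_link"


@dataclass
class ScoreTable:
    """Scores of one measure over a set of unordered node pairs."""

    measure: str
    orientation: str
    scores: dict[Pair, float]

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER, LOWER):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for u, v in self.scores:
            if u == v:
                raise ValueError("self-pair in score table")
            if u > v:
                raise ValueError(f"pair ({u},{v}) not canonical (min,max)")

    def __getitem__(self, pair: tuple[int, int]) -> float:
        return self.scores[normalize_pair(*pair)]

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def pairs(self) -> list[Pair]:
        return list(self.scores)

    def oriented_values(self) -> np.ndarray:
        """Scores flipped so that larger always means more link-like."""
        vals = np.fromiter(self.scores.values(), dtype=float, count=len(self.scores))
        return vals if self.orientation == HIGHER else -vals

    def ranked(self, best_first: bool = True) -> list[Pair]:
        """Pairs sorted best candidate first (or worst first), with the
        canonical pair order as a deterministic tie-break."""
        sign = -1.0 if (self.orientation == HIGHER) == best_first else 1.0
        return sorted(sorted(self.scores), key=lambda p: (sign * self.scores[p], p))


def _resolve_pairs(g: LayerGraph, pairs: Sequence[tuple[int, int]] | None) -> list[Pair]:
    if pairs is None:
        return list(combinations(g.nodes, 2))
    node_set = set(g.nodes)
    out = []
    for u, v in pairs:
        if u not in node_set or v not in node_set:
            raise KeyError(f"pair ({u},{v}) has a node outside the layer")
        out.append(normalize_pair(u, v))
    return out


def score_pa(g: LayerGraph, pairs: Sequence[tuple[int, int]] | None = None) -> ScoreTable:
    """Preferential attachment: degree product |Gamma_i| * |Gamma_j|."""
    pairs = _resolve_pairs(g, pairs)
    deg = g.degrees()
    return ScoreTable("pa", HIGHER, {(u, v): float(deg[u] * deg[v]) for u, v in pairs})


def score_cn(g: LayerGraph, pairs: Sequence[tuple[int, int]] | None = None) -> ScoreTable:
    """Common neighbors: |Gamma_i intersect Gamma_j|."""
    pairs = _resolve_pairs(g, pairs)
    return ScoreTable("cn", HIGHER, {
        (u, v): float(len(g.neighbors(u) & g.neighbors(v))) for u, v in pairs})


def score_car(g: LayerGraph, pairs: Sequence[tuple[int, int]] | None = None) -> ScoreTable:
    """CAR: common-neighbor count times the number of links among the common
    neighbors (local community links, LCL)."""
    pairs = _resolve_pairs(g, pairs)
    out: dict[Pair, float] = {}
    for u, v in pairs:
        common = g.neighbors(u) & g.neighbors(v)
        if len(common) < 2:
            out[(u, v)] = 0.0
            continue
        lcl = sum(1 for a, b in combinations(sorted(common), 2) if g.has_edge(a, b))
        out[(u, v)] = float(len(common) * lcl)
    return ScoreTable("car", HIGHER, out)


def score_cjc(g: LayerGraph, pairs: Sequence[tuple[int, int]] | None = None) -> ScoreTable:
    """CJC: CAR normalized by the neighborhood union |Gamma_i union Gamma_j|
    (0 when the union is empty)."""
    pairs = _resolve_pairs(g, pairs)
    car = score_car(g, pairs)
    out: dict[Pair, float] = {}
    for u, v in pairs:
        union = len(g.neighbors(u) | g.neighbors(v))
        out[(u, v)] = car.scores[(u, v)] / union if union else 0.0
    return ScoreTable("cjc", HIGHER, out)


def score_hp(coords: EmbeddingCoordinates,
             pairs: Sequence[tuple[int, int]]) -> ScoreTable:
    """HP: exact hyperbolic distance of each pair; smaller distance means a
    more likely link (lower_is_link orientation)."""
    pairs = [normalize_pair(u, v) for u, v in pairs]
    dist = pairwise_distances(coords, pairs)
    return ScoreTable("hp", LOWER, dict(zip(pairs, dist.tolist())))


def score_wcn(g: LayerGraph, coords: EmbeddingCoordinates,
              pairs: Sequence[tuple[int, int]] | None = None) -> ScoreTable:
    """Weighted common neighbors.

    Let H(u, v) be the hyperbolic distance of an existing link and h the mean
    of H over all links of the layer.  Each common neighbor k of a candidate
    pair (i, j) contributes, for each of its two ties (i, k) and (k, j):
    1 + 1/H(tie) when the tie is strong (H(tie) < h), else 1.  Hence
    WCN(i, j) >= 2 CN(i, j), with equality when every tie is weak.
    Coincident coordinates (H < 1e-9) are capped at 1 + 1/1e-9.
    """
    if g.n_edges == 0:
        raise ValueError("WCN needs at least one existing link to set the threshold")
    pairs = _resolve_pairs(g, pairs)
    edge_list = sorted(g.edges)
    edge_dist = dict(zip(edge_list, pairwise_distances(coords, edge_list)))
    h = float(np.mean(list(edge_dist.values())))

    def tie_weight(a: int, b: int) -> float:
        d = float(edge_dist[normalize_pair(a, b)])
        if d >= h:
            return 1.0
        return 1.0 + 1.0 / max(d, WCN_MIN_DISTANCE)

    out: dict[Pair, float] = {}
    for u, v in pairs:
        total = 0.0
        for k in g.neighbors(u) & g.neighbors(v):
            total += tie_weight(u, k) + tie_weight(k, v)
        out[(u, v)] = total
    return ScoreTable("wcn", HIGHER, out)


def borda_aggregate(tables: Sequence[ScoreTable],
                    measure: str = "borda") -> ScoreTable:
    """Borda rank aggregation over two or more score tables of one pair set.

    Within each input list an element's credit is the number of elements
    ranked strictly worse than it (ties share the same credit); the aggregate
    score is the sum of credits over the lists.  Output is higher_is_link.
    """
    if len(tables) < 2:
        raise ValueError("Borda aggregation needs at least two rankings")
    pair_set = set(tables[0].scores)
    for t in tables[1:]:
        if set(t.scores) != pair_set:
            raise ValueError("all rankings must cover the identical pair set")
    pairs = sorted(pair_set)
    total = np.zeros(len(pairs))
    for t in tables:
        vals = np.array([t.scores[p] for p in pairs])
        if t.orientation == LOWER:
            vals = -vals
        # rankdata(min) = 1 + count strictly worse
        total += rankdata(vals, method="min") - 1
    return ScoreTable(measure, HIGHER, dict(zip(pairs, total.tolist())))


def score_rank_cn_hp(g: LayerGraph, coords: EmbeddingCoordinates,
                     pairs: Sequence[tuple[int, int]] | None = None) -> ScoreTable:
    """Rank-CN-HP: Borda aggregation (equal weight) of the common-neighbor
    ranking and the hyperbolic-distance ranking over the candidate pairs."""
    pairs = _resolve_pairs(g, pairs)
    cn = score_cn(g, pairs)
    hp = score_hp(coords, pairs)
    return borda_aggregate([cn, hp], measure="rank-cn-hp")


# score files: "u v score" records under a "# measure=<name> orientation=<o>" header

def write_scores(table: ScoreTable, path: str,
                 header_lines: Sequence[str] = ()) -> None:
    lines = [f"# {extra}" for extra in header_lines]
    lines.append(f"#measure: {table.measure} orientation: {table.orientation}")
    for (u, v) in sorted(table.scores):
        lines.append(f"{u} {v} {float(table.scores[(u, v)])!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_scores(path: str) -> ScoreTable:
    measure, orientation = "unknown", HIGHER
    scores: dict[Pair, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("measure:"):
                    toks = body.split()
                    measure = toks[1]
                    orientation = toks[3]
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'u v score'")
            scores[normalize_pair(int(parts[0]), int(parts[1]))] = float(parts[2])
    return ScoreTable(measure, orientation, scores)
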