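"""Missing- and spurious-link experiment protocols and precision reporting.

Missing-link protocol: a fraction of the target layer's links is hidden
(disjoint k-fold batches, cycled and reshuffled across repetitions with
k = round(1/holdout_fraction)); every measure then scores all non-observed
pairs of the perturbed layer, and precision is the fraction of the top-L
ranked candidates that are truly hidden links (L = number removed).

Spurious-link protocol: random non-edges are added to the target layer;
every measure scores all observed links, the ranking is reversed (least
link-like first), and precision is the fraction of the top-L that are the
injected edges (L = number added).

Coordinate-based measures (hp, wcn, rank-cn-hp) re-embed the perturbed
target layer in every repetition; non-target layers are embedded once from
their full topology and are never perturbed.  In multiplex mode scores are
fused across layers with link-overlap (or correlation) relevance weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .embedding import (EmbeddingCoordinates, embed_layer, gamma_or_default,
                        estimate_temperature, pairwise_distances)
from .fusion import LayerRelevance, compute_relevance, fuse_scores
from .multiplex import LayerGraph, MultiplexNetwork, Pair, normalize_pair
from .similarity import (ScoreTable, score_car, score_cjc, score_cn,
                         score_hp, score_pa, score_rank_cn_hp, score_wcn)

logger = logging.getLogger(__name__)

COORD_MEASURES = frozenset({"hp", "wcn", "rank-cn-hp"})
ALL_MEASURES = ("pa", "cn", "car", "cjc", "hp", "wcn", "rank-cn-hp")


@dataclass
class EvaluationReport:
    """Per-measure precision across repetitions of one protocol run."""

    protocol: str
    measures: tuple[str, ...]
    precisions: dict[str, list[float]]
    params: dict
    seed: int

    def mean(self, measure: str) -> float:
        return float(np.mean(self.precisions[measure]))

    def std(self, measure: str) -> float:
        return float(np.std(self.precisions[measure]))

    def summary(self) -> dict:
        return {
            "protocol": self.protocol,
            "seed": self.seed,
            "params": self.params,
            "repetitions": {m: list(v) for m, v in self.precisions.items()},
            "mean": {m: self.mean(m) for m in self.measures},
            "std": {m: self.std(m) for m in self.measures},
        }


def precision_at(ranked_pairs: Sequence[tuple[int, int]],
                 positives: set[Pair] | frozenset[Pair],
                 L: int) -> float:
    """Top-L precision |TP| / (|TP| + |FP|): the fraction of the first L
    ranked candidates that are true positives."""
    if L <= 0:
        raise ValueError("L must be positive")
    if L > len(ranked_pairs):
        raise ValueError("L exceeds the ranking length")
    positives = {normalize_pair(*p) for p in positives}
    hits = sum(1 for p in ranked_pairs[:L] if normalize_pair(*p) in positives)
    return hits / L


def distance_bin_curve(g: LayerGraph, coords: EmbeddingCoordinates,
                       n_bins: int) -> list[tuple[float, float, int, float]]:
    """Link probability as a function of hyperbolic distance.

    All unordered node pairs are sorted by distance and split into
    ``n_bins`` equal-count bins; each entry is (distance lo, distance hi,
    bin size, fraction of the bin's pairs that are links).  The size-weighted
    mean of the bin probabilities equals the graph density exactly.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    pairs = list(combinations(g.nodes, 2))
    if n_bins > len(pairs):
        raise ValueError("more bins than node pairs")
    dist = pairwise_distances(coords, pairs)
    order = np.argsort(dist, kind="stable")
    is_edge = np.fromiter((p in g.edges for p in pairs), dtype=float,
                          count=len(pairs))[order]
    dist = dist[order]
    out = []
    for chunk in np.array_split(np.arange(len(pairs)), n_bins):
        out.append((float(dist[chunk[0]]), float(dist[chunk[-1]]),
                    len(chunk), float(np.mean(is_edge[chunk]))))
    return out


# ---------------------------------------------------------------------------
# Protocol internals
# ---------------------------------------------------------------------------

def _as_measures(measure) -> tuple[str, ...]:
    measures = (measure,) if isinstance(measure, str) else tuple(measure)
    for m in measures:
        if m not in ALL_MEASURES:
            raise ValueError(f"unknown measure {m!r}; choose from {ALL_MEASURES}")
    return measures


def _score_layer(measure: str, g: LayerGraph,
                 coords: EmbeddingCoordinates | None,
                 pairs: list[Pair]) -> ScoreTable:
    if measure == "pa":
        return score_pa(g, pairs)
    if measure == "cn":
        return score_cn(g, pairs)
    if measure == "car":
        return score_car(g, pairs)
    if measure == "cjc":
        return score_cjc(g, pairs)
    if measure == "hp":
        return score_hp(coords, pairs)
    if measure == "wcn":
        return score_wcn(g, coords, pairs)
    if measure == "rank-cn-hp":
        return score_rank_cn_hp(g, coords, pairs)
    raise ValueError(f"unknown measure {measure!r}")


def _per_layer_parameters(net: MultiplexNetwork, gamma, temperature,
                          seed: int) -> tuple[list[float], list[float]]:
    """Resolve gamma and T for every layer: scalars broadcast, sequences map
    per layer, None triggers estimation from the unperturbed topology."""
    m = net.n_layers

    def broadcast(value, estimator):
        if value is None:
            return [estimator(k) for k in range(m)]
        if np.isscalar(value):
            return [float(value)] * m
        vals = list(value)
        if len(vals) != m:
            raise ValueError("need one value per layer")
        return [float(v) for v in vals]

    gammas = broadcast(gamma, lambda k: gamma_or_default(net.layers[k]))
    temps = broadcast(
        temperature,
        lambda k: estimate_temperature(net.layers[k], gammas[k],
                                       seed=seed + 7919 * (k + 1)))
    return gammas, temps


def _needs_coords(measures: Sequence[str]) -> bool:
    return bool(COORD_MEASURES.intersection(measures))


def _prepare(net, target_layer, measures, eta, gamma, temperature, seed,
             grid_size, sweeps):
    measures = _as_measures(measures)
    if target_layer is None:
        target_layer = net.densest_layer()
    multiplex = eta != 0.0 and net.n_layers > 1
    gammas, temps = _per_layer_parameters(net, gamma, temperature, seed)
    other_coords: dict[int, EmbeddingCoordinates] = {}
    if _needs_coords(measures) and multiplex:
        for k in range(net.n_layers):
            if k != target_layer:
                other_coords[k] = embed_layer(net.layers[k], gammas[k], temps[k],
                                              grid_size=grid_size, sweeps=sweeps)
    return measures, target_layer, multiplex, gammas, temps, other_coords


def _rank_and_score(measures, g_obs, coords_obs, candidates, positives, L,
                    net, target_layer, multiplex, other_coords, eta,
                    relevance_method, reverse: bool) -> dict[str, float]:
    """Score the candidate pairs with every measure (fused across layers in
    multiplex mode) and return top-L precision per measure."""
    relevance: LayerRelevance | None = None
    if multiplex:
        perturbed = MultiplexNetwork(
            layers=tuple(g_obs if k == target_layer else net.layers[k]
                         for k in range(net.n_layers)),
            layer_names=net.layer_names, node_labels=net.node_labels)
        relevance = compute_relevance(perturbed, relevance_method)
    out: dict[str, float] = {}
    for measure in measures:
        table = _score_layer(measure, g_obs, coords_obs, candidates)
        if multiplex:
            others = {
                k: _score_layer(measure, net.layers[k], other_coords.get(k),
                                candidates)
                for k in range(net.n_layers) if k != target_layer}
            table = fuse_scores(table, others, relevance, target_layer, eta)
        ranked = table.ranked(best_first=not reverse)
        out[measure] = precision_at(ranked, positives, L)
    return out


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def run_missing(net: MultiplexNetwork, target_layer: int | None = None,
                measure="cn", holdout_fraction: float = 0.15,
                repetitions: int = 20, eta: float = 1.0,
                relevance_method: str = "lo", seed: int = 0,
                gamma=None, temperature=None,
                grid_size: int | None = None, sweeps: int = 1) -> EvaluationReport:
    """Missing-link prediction experiment (see module docstring).

    ``measure`` may be one name or a list; perturbations and embeddings are
    shared across measures within a repetition, which is equivalent to
    separate same-seed runs since scoring consumes no randomness.
    ``gamma``/``temperature`` may be scalars, per-layer sequences, or None
    (estimated once from the unperturbed layers).
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    (measures, target_layer, multiplex, gammas, temps,
     other_coords) = _prepare(net, target_layer, measure, eta, gamma,
                              temperature, seed, grid_size, sweeps)
    target = net.layers[target_layer]
    if target.n_edges < 20:
        raise ValueError("target layer needs at least 20 edges")
    rng = np.random.default_rng(seed)
    k_folds = max(2, round(1.0 / holdout_fraction))
    edges = sorted(target.edges)
    folds: list[list[Pair]] = []
    precisions: dict[str, list[float]] = {m: [] for m in measures}
    non_edges_full = set(combinations(target.nodes, 2)) - target.edges
    for rep in range(repetitions):
        if not folds:
            perm = rng.permutation(len(edges))
            folds = [[edges[i] for i in chunk]
                     for chunk in np.array_split(perm, k_folds)]
        hidden = set(folds.pop(0))
        observed = target.edges - hidden
        g_obs = LayerGraph(nodes=target.nodes, edges=frozenset(observed))
        candidates = sorted(non_edges_full | hidden)
        coords_obs = None
        if _needs_coords(measures):
            try:
                coords_obs = embed_layer(g_obs, gammas[target_layer],
                                         temps[target_layer],
                                         grid_size=grid_size, sweeps=sweeps)
            except ValueError as exc:
                logger.warning("repetition %d skipped: embedding failed (%s)",
                               rep, exc)
                continue
        rep_prec = _rank_and_score(measures, g_obs, coords_obs, candidates,
                                   hidden, len(hidden), net, target_layer,
                                   multiplex, other_coords, eta,
                                   relevance_method, reverse=False)
        for m, p in rep_prec.items():
            precisions[m].append(p)
    params = dict(target_layer=target_layer, holdout_fraction=holdout_fraction,
                  repetitions=repetitions, eta=eta,
                  relevance_method=relevance_method, gamma=gammas,
                  temperature=temps, multiplex=multiplex)
    return EvaluationReport("missing", measures, precisions, params, seed)


def run_spurious(net: MultiplexNetwork, target_layer: int | None = None,
                 measure="cn", added_fraction: float = 0.15,
                 repetitions: int = 20, eta: float = 1.0,
                 relevance_method: str = "lo", seed: int = 0,
                 gamma=None, temperature=None,
                 grid_size: int | None = None, sweeps: int = 1) -> EvaluationReport:
    """Spurious-link identification experiment (see module docstring)."""
    if added_fraction <= 0.0:
        raise ValueError("added_fraction must be positive")
    (measures, target_layer, multiplex, gammas, temps,
     other_coords) = _prepare(net, target_layer, measure, eta, gamma,
                              temperature, seed, grid_size, sweeps)
    target = net.layers[target_layer]
    if target.n_edges < 20:
        raise ValueError("target layer needs at least 20 edges")
    n_add = round(added_fraction * target.n_edges)
    if n_add == 0:
        raise ValueError("added_fraction adds zero links")
    non_edges = sorted(set(combinations(target.nodes, 2)) - target.edges)
    if len(non_edges) < n_add:
        raise ValueError("not enough non-edges to inject")
    rng = np.random.default_rng(seed)
    precisions: dict[str, list[float]] = {m: [] for m in measures}
    for rep in range(repetitions):
        idx = rng.choice(len(non_edges), size=n_add, replace=False)
        added = {non_edges[int(i)] for i in idx}
        g_obs = LayerGraph(nodes=target.nodes,
                           edges=frozenset(target.edges | added))
        candidates = sorted(g_obs.edges)
        coords_obs = None
        if _needs_coords(measures):
            coords_obs = embed_layer(g_obs, gammas[target_layer],
                                     temps[target_layer],
                                     grid_size=grid_size, sweeps=sweeps)
        rep_prec = _rank_and_score(measures, g_obs, coords_obs, candidates,
                                   added, len(added), net, target_layer,
                                   multiplex, other_coords, eta,
                                   relevance_method, reverse=True)
        for m, p in rep_prec.items():
            precisions[m].append(p)
    params = dict(target_layer=target_layer, added_fraction=added_fraction,
                  repetitions=repetitions, eta=eta,
                  relevance_method=relevance_method, gamma=gammas,
                  temperature=temps, multiplex=multiplex)
    return EvaluationReport("spurious", measures, precisions, params, seed)
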