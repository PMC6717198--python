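"""Popularity x similarity optimization (PSO) network generator.

Networks grow one node at a time on the hyperbolic disk.  Node t appears at
radius r_t = 2 ln t (popularity: early nodes stay central) and a random angle
(similarity).  Existing nodes drift outward ("popularity fading"):
r_s(t) = beta r_s + (1 - beta) r_t with beta = 1/(gamma - 1), which produces
a power-law degree distribution with exponent gamma.  The newcomer connects
to m existing nodes: the hyperbolically nearest at temperature T = 0, or a
Fermi-Dirac-weighted random draw at T > 0, with the disk cutoff R_t
calibrated by bisection so the expected number of connections is m.  The
nonuniform (N-PSO) mode replaces the uniform angle with a mixture of equally
spaced community centers, giving angular (community) structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingCoordinates, _exact_distance, angular_separation
from .multiplex import LayerGraph, MultiplexNetwork, Pair, normalize_pair

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PsoParams:
    """Generator inputs: final size N, links per newcomer m (mean degree
    approx 2m), degree exponent gamma > 2, temperature T >= 0 (clustering),
    and an optional community count for the nonuniform angular mode."""

    n_nodes: int
    m: int
    gamma: float
    temperature: float
    seed: int
    communities: int | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 2:
            raise ValueError("gamma must exceed 2 (beta = 1/(gamma-1) in (0,1))")
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.n_nodes <= self.m + 1:
            raise ValueError("n_nodes must exceed m by at least 2 "
                             "(otherwise growth degenerates to a clique)")
        if self.communities is not None and self.communities < 1:
            raise ValueError("communities must be at least 1")

    @property
    def beta(self) -> float:
        return 1.0 / (self.gamma - 1.0)


def _draw_angles(params: PsoParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform angles, or a wrapped-normal mixture of equally spaced
    community centers (spread sigma = pi / (2C)) in nonuniform mode."""
    n = params.n_nodes
    if params.communities is None:
        return rng.uniform(0.0, TWO_PI, size=n)
    c = params.communities
    centers = TWO_PI * np.arange(c) / c
    which = rng.integers(0, c, size=n)
    sigma = np.pi / (2.0 * c)
    return np.mod(centers[which] + rng.normal(0.0, sigma, size=n), TWO_PI)


def _calibrate_cutoff(dist: np.ndarray, T: float, m: int) -> float:
    """Bisection for R_t such that sum_s 1/(1 + exp((x_s - R_t)/(2T))) = m."""
    lo = float(dist.min()) - 40.0 * T
    hi = float(dist.max()) + 40.0 * T

    def expected(R: float) -> float:
        with np.errstate(over="ignore"):
            return float(np.sum(1.0 / (1.0 + np.exp((dist - R) / (2.0 * T)))))

    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expected(mid) < m:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def grow_pso(params: PsoParams) -> tuple[LayerGraph, EmbeddingCoordinates]:
    """Grow one PSO network; returns the graph (internal node ids 0..N-1,
    id i born at time t = i + 1) and the true coordinates with final-time
    radii r_s(N) = beta 2 ln s + (1 - beta) 2 ln N.

    At T = 0 the newcomer takes the min(m, t-1) hyperbolically nearest
    existing nodes (exactly sum_t min(m, t-1) edges); at T > 0 it draws
    min(m, t-1) distinct targets with probability proportional to the
    calibrated Fermi-Dirac factor.  Fully deterministic given the seed.
    """
    n, m, T, beta = params.n_nodes, params.m, params.temperature, params.beta
    rng = np.random.default_rng(params.seed)
    theta = _draw_angles(params, rng)
    birth_r = 2.0 * np.log(np.arange(1, n + 1))  # r_t at birth
    edges: set[Pair] = set()
    for i in range(1, n):
        t = i + 1
        r_new = birth_r[i]
        # existing nodes s = 1..t-1 drift toward the newcomer's radius
        r_old = beta * birth_r[:i] + (1.0 - beta) * r_new
        dtheta = angular_separation(theta[i], theta[:i])
        dist = _exact_distance(r_new, r_old, dtheta)
        k = min(m, i)
        if T == 0.0:
            # stable argsort: equal distances resolve to the older node
            targets = np.argsort(dist, kind="stable")[:k]
        elif i <= m:
            targets = np.arange(i)
        else:
            R_t = _calibrate_cutoff(dist, T, m)
            with np.errstate(over="ignore"):
                p = 1.0 / (1.0 + np.exp((dist - R_t) / (2.0 * T)))
            p = np.maximum(p, 1e-300)
            targets = rng.choice(i, size=k, replace=False, p=p / p.sum())
        for s in targets:
            edges.add(normalize_pair(int(s), i))
    graph = LayerGraph(nodes=tuple(range(n)), edges=frozenset(edges))
    final_r = beta * birth_r + (1.0 - beta) * 2.0 * np.log(n)
    coords = EmbeddingCoordinates(
        nodes=tuple(range(n)), radii=final_r, angles=theta,
        disk_radius=2.0 * np.log(n), temperature=T, gamma=params.gamma,
        inferred=False)
    return graph, coords


def grow_multiplex(params: PsoParams, n_layers: int,
                   rewire_fraction: float) -> MultiplexNetwork:
    """Correlated synthetic multiplex: layer 1 is a PSO network; each further
    layer copies it and rewires ``rewire_fraction`` of the edges to uniformly
    random non-edges.  Edge counts are preserved in every layer, and the
    expected interlayer link overlap decreases monotonically with the rewire
    fraction (1 at fraction 0)."""
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if not 0.0 <= rewire_fraction <= 1.0:
        raise ValueError("rewire_fraction must lie in [0, 1]")
    base, _ = grow_pso(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5EED]))
    n = base.n_nodes
    layers = [base]
    for _layer in range(1, n_layers):
        edges = sorted(base.edges)
        n_rewire = round(rewire_fraction * len(edges))
        keep_idx = rng.choice(len(edges), size=len(edges) - n_rewire,
                              replace=False)
        kept = {edges[int(i)] for i in keep_idx}
        new_edges = set(kept)
        while len(new_edges) < len(edges):
            u, v = rng.integers(0, n, size=2)
            if u == v:
                continue
            pair = normalize_pair(int(u), int(v))
            if pair in base.edges or pair in new_edges:
                continue
            new_edges.add(pair)
        layers.append(LayerGraph(nodes=base.nodes, edges=frozenset(new_edges)))
    return MultiplexNetwork(layers=tuple(layers),
                            layer_names=tuple(str(k + 1) for k in range(n_layers)))
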