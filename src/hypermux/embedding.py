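"""Hyperbolic geometry kernel and per-layer embedding.

The native space is the hyperbolic disk: node i sits at polar coordinates
(r_i, theta_i), the radius encoding popularity (high-degree nodes are close
to the origin) and the angle encoding similarity.  Connection probability is
the Fermi-Dirac sigmoid p(x) = 1 / (1 + exp((x - R) / (2T))) of the
hyperbolic distance x, with disk radius R and temperature T controlling
clustering.

The embedding routine is a maximum-likelihood layout in the HyperMap family:
radii follow a degree-rank schedule consistent with r_i ~ ln N - ln k_i,
angles are placed sequentially (then refined by coordinate-ascent sweeps)
on a uniform angular grid, maximizing the Bernoulli log-likelihood of the
observed adjacency under the Fermi-Dirac model.  The power-law exponent
gamma is estimated with Clauset's discrete MLE, and the temperature by
matching degree distribution and mean clustering against PSO-grown synthetic
networks of the same size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .multiplex import LayerGraph, Pair, layer_stats, normalize_pair

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class EmbeddingCoordinates:
    """Per-node disk coordinates for one layer, plus model parameters.

    ``nodes[i]`` owns ``radii[i]`` and ``angles[i]``; every node of the layer
    has a record, isolated nodes included.  ``inferred`` distinguishes
    embeddings recovered from topology from generator ground truth.
    """

    nodes: tuple[int, ...]
    radii: np.ndarray
    angles: np.ndarray
    disk_radius: float
    temperature: float
    gamma: float
    inferred: bool = True

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        angles = np.mod(np.asarray(self.angles, dtype=float), TWO_PI)
        if radii.shape != (len(self.nodes),) or angles.shape != (len(self.nodes),):
            raise ValueError("one (radius, angle) record per node required")
        if not np.all(np.isfinite(radii)) or np.any(radii < 0):
            raise ValueError("radii must be finite and nonnegative")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.nodes)})

    def index_of(self, node: int) -> int:
        try:
            return self._index[node]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"node {node} has no coordinates") from None

    def radius(self, node: int) -> float:
        return float(self.radii[self.index_of(node)])

    def angle(self, node: int) -> float:
        return float(self.angles[self.index_of(node)])


# ---------------------------------------------------------------------------
# Geometry kernel
# ---------------------------------------------------------------------------

def angular_separation(theta_i, theta_j):
    """Smallest angle between two directions: pi - |pi - |theta_i - theta_j||.

    Accepts scalars or arrays; result lies in [0, pi]."""
    diff = np.abs(np.mod(theta_i, TWO_PI) - np.mod(theta_j, TWO_PI))
    return np.pi - np.abs(np.pi - diff)


def hyperbolic_distance(r_i, theta_i, r_j, theta_j, mode: str = "exact"):
    """Hyperbolic distance between (r_i, theta_i) and (r_j, theta_j).

    ``exact``: arccosh(cosh r_i cosh r_j - sinh r_i sinh r_j cos dtheta),
    always >= 0 and symmetric.  ``approx``: r_i + r_j + 2 ln(dtheta / 2),
    the standard large-radius small-angle form; ``approx_sin``:
    r_i + r_j + 2 ln sin(dtheta / 2), accurate at large radii for any
    angle.  The approximations may be negative for tiny dtheta and are NOT
    clamped.  A dtheta of exactly 0 in either approximate mode falls back
    to the exact value (the log would be -inf); the fallback is logged.
    """
    dtheta = angular_separation(theta_i, theta_j)
    if mode == "exact":
        return _exact_distance(r_i, r_j, dtheta)
    if mode in ("approx", "approx_sin"):
        ri, rj, dth = np.broadcast_arrays(
            np.asarray(r_i, dtype=float), np.asarray(r_j, dtype=float),
            np.asarray(dtheta, dtype=float))
        scalar = dth.ndim == 0
        ri, rj, dth = np.atleast_1d(ri), np.atleast_1d(rj), np.atleast_1d(dth)
        with np.errstate(divide="ignore"):
            half = np.sin(dth / 2.0) if mode == "approx_sin" else dth / 2.0
            out = ri + rj + 2.0 * np.log(half)
        zero = dth == 0.0
        if np.any(zero):
            logger.debug("approx distance with dtheta=0: falling back to exact form")
            out[zero] = _exact_distance(ri, rj, dth)[zero]
        return float(out[0]) if scalar else out
    raise ValueError(f"unknown mode {mode!r}")


def _exact_distance(r_i, r_j, dtheta):
    arg = (np.cosh(r_i) * np.cosh(r_j)
           - np.sinh(r_i) * np.sinh(r_j) * np.cos(dtheta))
    # roundoff can push the argument a hair below 1 for near-coincident points
    return np.arccosh(np.maximum(arg, 1.0))


def fermi_dirac_probability(x, R: float, T: float):
    """Connection probability p(x) = 1 / (1 + exp((x - R) / (2T))), T > 0.

    Strictly decreasing in x with p(R) = 1/2.  The T = 0 step-function limit
    is the caller's concern and raises here."""
    if T <= 0:
        raise ValueError("fermi_dirac_probability requires T > 0")
    return special.expit(-(np.asarray(x, dtype=float) - R) / (2.0 * T))


def pairwise_distances(coords: EmbeddingCoordinates,
                       pairs: Sequence[Pair]) -> np.ndarray:
    """Exact hyperbolic distances for the given node pairs, vectorized."""
    ii = np.fromiter((coords.index_of(u) for u, _ in pairs), dtype=int,
                     count=len(pairs))
    jj = np.fromiter((coords.index_of(v) for _, v in pairs), dtype=int,
                     count=len(pairs))
    dtheta = angular_separation(coords.angles[ii], coords.angles[jj])
    return _exact_distance(coords.radii[ii], coords.radii[jj], dtheta)


def distance_matrix(coords: EmbeddingCoordinates,
                    pairs: Sequence[Pair] | None = None):
    """Exact-mode distances for the requested pairs (default: all pairs),
    returned as a lower-is-link ScoreTable."""
    from .similarity import ScoreTable  # local import: avoid cycle
    if pairs is None:
        from itertools import combinations
        pairs = list(combinations(coords.nodes, 2))
    pairs = [normalize_pair(u, v) for u, v in pairs]
    dist = pairwise_distances(coords, pairs)
    return ScoreTable(measure="hyperbolic_distance", orientation="lower_is_link",
                      scores=dict(zip(pairs, dist.tolist())))


# ---------------------------------------------------------------------------
# Power-law exponent (Clauset's discrete MLE)
# ---------------------------------------------------------------------------

def _discrete_mle_approx(tail: np.ndarray, k_min: int) -> float:
    """Closed-form approximation 1 + n / sum ln(k_i/(k_min - 1/2)); biased
    low for small k_min, used only to bracket the exact solution."""
    return 1.0 + len(tail) / float(np.sum(np.log(tail / (k_min - 0.5))))


def _discrete_mle(tail: np.ndarray, k_min: int) -> float:
    """Exact discrete power-law MLE: minimize the zeta-normalized negative
    log-likelihood n ln zeta(gamma, k_min) + gamma sum ln k_i."""
    from scipy import optimize
    n = len(tail)
    sum_ln = float(np.sum(np.log(tail)))

    def nll(gamma: float) -> float:
        return n * np.log(special.zeta(gamma, k_min)) + gamma * sum_ln

    approx = _discrete_mle_approx(tail, k_min)
    lo = max(1.05, approx - 1.0)
    res = optimize.minimize_scalar(nll, bounds=(lo, approx + 2.0),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def _ks_distance(tail: np.ndarray, k_min: int, gamma: float) -> float:
    """KS distance between the empirical tail CDF and the zeta model CDF."""
    values = np.arange(k_min, tail.max() + 1)
    norm = special.zeta(gamma, k_min)
    pmf = values**(-gamma) / norm
    model_cdf = np.cumsum(pmf)
    emp_cdf = np.searchsorted(np.sort(tail), values, side="right") / len(tail)
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def estimate_gamma(g: LayerGraph, k_min: int | None = None) -> float:
    """Power-law degree exponent via the exact discrete maximum-likelihood
    estimator over degrees >= k_min (zeta-normalized likelihood; the familiar
    closed form 1 + n [sum ln(k_i/(k_min - 1/2))]^{-1} seeds the search).

    When ``k_min`` is None it is chosen by minimizing the Kolmogorov-Smirnov
    distance between the empirical degree tail and the fitted zeta model,
    over all candidate cutoffs leaving at least 10 tail degrees.  Degenerate
    tails (all degrees equal) raise, as does an insufficient tail.
    """
    degrees = np.array([g.degree(i) for i in g.nodes], dtype=float)
    degrees = degrees[degrees >= 1]
    if k_min is not None:
        if k_min < 1:
            raise ValueError("k_min must be >= 1")
        tail = degrees[degrees >= k_min]
        if len(tail) < 10:
            raise ValueError(
                f"only {len(tail)} degrees >= k_min={k_min}; need >= 10 "
                "(pass a smaller explicit k_min)")
        if np.ptp(tail) == 0:
            raise ValueError("degenerate degree tail: all degrees equal")
        return _discrete_mle(tail, k_min)
    candidates = np.unique(degrees).astype(int)
    best: tuple[float, int, float] | None = None
    for km in candidates:
        tail = degrees[degrees >= km]
        if len(tail) < 10 or np.ptp(tail) == 0:
            continue
        gam = _discrete_mle(tail, km)
        ks = _ks_distance(tail, km, gam)
        if best is None or ks < best[0]:
            best = (ks, km, gam)
    if best is None:
        raise ValueError("no k_min leaves a usable tail; pass an explicit k_min")
    return best[2]


def gamma_or_default(g: LayerGraph, default: float = 2.5) -> float:
    """estimate_gamma with a warning fallback for layers whose degree
    distribution does not support a power-law fit (common in small social
    layers, where hyperbolic-distance prediction is known to degrade)."""
    try:
        gamma = estimate_gamma(g)
    except ValueError as exc:
        warnings.warn(f"gamma estimation failed ({exc}); using gamma={default}")
        return default
    if gamma <= 2.0:
        warnings.warn(
            f"estimated gamma={gamma:.2f} <= 2 is outside the embeddable "
            f"range; using gamma={default}")
        return default
    return gamma


# ---------------------------------------------------------------------------
# Likelihood embedding
# ---------------------------------------------------------------------------

def _bernoulli_loglik(dist: np.ndarray, adj: np.ndarray,
                      R: float, T: float) -> np.ndarray:
    """Sum_j [a_j ln p(x_j) + (1-a_j) ln(1-p(x_j))], stable via logaddexp.

    ``dist`` has shape (..., n_placed); ``adj`` is the 0/1 vector over the
    placed nodes.  Returns the sum over the last axis."""
    s = (dist - R) / (2.0 * T)
    log_p = -np.logaddexp(0.0, s)
    log_q = -np.logaddexp(0.0, -s)
    return log_p @ adj + log_q @ (1.0 - adj)


def log_likelihood(g: LayerGraph, coords: EmbeddingCoordinates) -> float:
    """Total Bernoulli log-likelihood of the layer under the Fermi-Dirac
    model at the given coordinates (sum over all unordered pairs)."""
    nodes = list(g.nodes)
    idx = np.array([coords.index_of(n) for n in nodes])
    r = coords.radii[idx]
    th = coords.angles[idx]
    R, T = coords.disk_radius, coords.temperature
    total = 0.0
    pos = {n: k for k, n in enumerate(nodes)}
    adj_mat = np.zeros((len(nodes), len(nodes)))
    for u, v in g.edges:
        adj_mat[pos[u], pos[v]] = adj_mat[pos[v], pos[u]] = 1.0
    for k in range(1, len(nodes)):
        dth = angular_separation(th[k], th[:k])
        d = _exact_distance(r[k], r[:k], dth)
        total += float(_bernoulli_loglik(d, adj_mat[k, :k], R, T))
    return total


def _spectral_angles(g: LayerGraph) -> dict[int, float]:
    """Initial angles from the normalized-Laplacian eigenmap.

    The second and third eigenvectors of L = I - D^{-1/2} A D^{-1/2} trace
    the angular ("similarity") circle of geometric networks; the initial
    angle of node i is atan2(v3_i, v2_i).  Eigenvector signs are fixed
    deterministically (largest-magnitude entry positive)."""
    import scipy.linalg

    nodes = sorted(g.nodes)
    n = len(nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in g.edges:
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = 1.0
    d = A.sum(axis=1)
    d[d == 0] = 1.0
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
    _, vecs = scipy.linalg.eigh(L, subset_by_index=[0, 2])
    v2, v3 = vecs[:, 1].copy(), vecs[:, 2].copy()
    for v in (v2, v3):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v *= -1.0
    theta = np.mod(np.arctan2(v3, v2), TWO_PI)
    return {u: float(theta[pos[u]]) for u in nodes}


def embed_layer(g: LayerGraph, gamma: float, T: float,
                grid_size: int | None = None, sweeps: int = 1,
                disk_radius: float | None = None,
                init: str = "auto") -> EmbeddingCoordinates:
    """Infer disk coordinates for one layer by maximum-likelihood angular
    placement with coordinate-ascent refinement.

    Nodes are ordered by decreasing degree (ties by ascending id); the node
    at rank t receives radius r_t = 2 beta ln t + 2 (1 - beta) ln N with
    beta = 1/(gamma - 1), and the disk radius defaults to R = 2 ln N.

    Initial angles come from the normalized-Laplacian eigenmap (``init`` =
    "spectral"), snapped to a uniform grid of ``grid_size`` candidate
    angles; graphs too small for a spectral decomposition (or ``init`` =
    "sequential") instead place nodes one at a time, each taking the grid
    angle maximizing the Bernoulli log-likelihood against the already-placed
    nodes (first node pinned at angle 0).  The global spectral start exists
    because purely sequential greedy placement routinely locks whole angular
    arcs into a wrong circular order that single-node refinement cannot
    undo.  ``sweeps`` full passes then re-optimize every node's angle over
    the same grid against all others, so the total log-likelihood is
    non-decreasing across sweeps.  Ties always break toward the smallest
    grid angle; the whole procedure is deterministic.

    Degree-0 nodes are pinned at (r = 2 ln N, theta = 0); they carry no
    adjacency signal and never affect the ranking of observed candidates.
    """
    if gamma <= 2:
        raise ValueError("gamma must exceed 2")
    if T <= 0:
        raise ValueError("temperature must be positive")
    if init not in ("auto", "spectral", "sequential"):
        raise ValueError(f"unknown init {init!r}")
    n = g.n_nodes
    if n < 1:
        raise ValueError("empty layer")
    if grid_size is None:
        grid_size = max(360, n)
    beta = 1.0 / (gamma - 1.0)
    R = 2.0 * np.log(n) if disk_radius is None else float(disk_radius)
    deg = g.degrees()
    order = sorted(g.nodes, key=lambda i: (-deg[i], i))
    radii = np.empty(n)
    for rank, node in enumerate(order, start=1):
        radii[rank - 1] = 2.0 * beta * np.log(rank) + 2.0 * (1.0 - beta) * np.log(n)
    active = [k for k, node in enumerate(order) if deg[node] > 0]
    pos_of = {node: k for k, node in enumerate(order)}
    angles = np.zeros(n)
    inactive = [k for k, node in enumerate(order) if deg[node] == 0]
    radii[inactive] = 2.0 * np.log(n)  # degree-0 pin, per module contract

    grid = np.arange(grid_size) * (TWO_PI / grid_size)
    cosh_r = np.cosh(radii)
    sinh_r = np.sinh(radii)
    adj = np.zeros((n, n))
    for u, v in g.edges:
        adj[pos_of[u], pos_of[v]] = adj[pos_of[v], pos_of[u]] = 1.0

    def best_angle(k: int, others: np.ndarray) -> float:
        """Grid angle maximizing the local log-likelihood of node k against
        the nodes at positions ``others`` (at their current coordinates)."""
        dtheta = angular_separation(grid[:, None], angles[others][None, :])
        arg = cosh_r[k] * cosh_r[others] - sinh_r[k] * sinh_r[others] * np.cos(dtheta)
        dist = np.arccosh(np.maximum(arg, 1.0))
        ll = _bernoulli_loglik(dist, adj[k, others], R, T)
        return float(grid[int(np.argmax(ll))])  # argmax takes the first (smallest) tie

    use_spectral = init in ("auto", "spectral") and len(active) >= 5
    if init == "spectral" and len(active) < 5:
        raise ValueError("spectral initialization needs at least 5 non-isolated nodes")
    if use_spectral:
        theta0 = _spectral_angles(g)
        step = TWO_PI / grid_size
        for k in active:
            angles[k] = grid[int(round(theta0[order[k]] / step)) % grid_size]
    else:
        # sequential greedy placement (small-graph path)
        placed: list[int] = []
        for k in active:
            if placed:
                angles[k] = best_angle(k, np.array(placed))
            else:
                angles[k] = 0.0
            placed.append(k)

    # coordinate-ascent refinement
    all_active = np.array(active)
    for _ in range(sweeps):
        for k in active:
            others = all_active[all_active != k]
            if len(others):
                angles[k] = best_angle(k, others)

    sorted_nodes = tuple(sorted(g.nodes))
    out_r = np.array([radii[pos_of[i]] for i in sorted_nodes])
    out_th = np.array([angles[pos_of[i]] for i in sorted_nodes])
    return EmbeddingCoordinates(nodes=sorted_nodes, radii=out_r, angles=out_th,
                                disk_radius=R, temperature=T, gamma=gamma,
                                inferred=True)


# ---------------------------------------------------------------------------
# Temperature estimation by synthetic matching
# ---------------------------------------------------------------------------

def estimate_temperature(g: LayerGraph, gamma: float,
                         t_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5,
                                                    0.6, 0.7, 0.8, 0.9),
                         replicates: int = 3, seed: int = 0) -> float:
    """Pick the temperature whose PSO-grown synthetic twin best matches the
    layer's degree distribution and mean clustering.

    For each candidate T, ``replicates`` synthetic networks are grown with
    the layer's N, m = round(<k>/2) and the supplied gamma; the discrepancy
    is |mean clustering difference| + KS distance between degree
    distributions, averaged over replicates.  Ties go to the smaller T.
    """
    from .pso import PsoParams, grow_pso  # local import: avoid cycle
    t_grid = list(t_grid)
    if not t_grid:
        raise ValueError("t_grid must be nonempty")
    if any(t <= 0 or t > 1 for t in t_grid):
        raise ValueError("candidate temperatures must lie in (0, 1]")
    if g.n_nodes < 3 or g.n_edges == 0:
        raise ValueError("layer too degenerate for temperature matching")
    ref = layer_stats(g)
    m = max(1, round(ref.mean_degree / 2.0))
    deg_ref = np.array([g.degree(i) for i in g.nodes], dtype=float)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(len(t_grid), replicates))
    best_t, best_disc = None, np.inf
    for ti, t_cand in enumerate(sorted(t_grid)):
        discs = []
        for rep in range(replicates):
            params = PsoParams(n_nodes=g.n_nodes, m=m, gamma=gamma,
                               temperature=t_cand, seed=int(sub_seeds[ti, rep]))
            synth, _ = grow_pso(params)
            st = layer_stats(synth)
            deg_syn = np.array([synth.degree(i) for i in synth.nodes], dtype=float)
            ks = stats.ks_2samp(deg_ref, deg_syn).statistic
            discs.append(abs(ref.mean_clustering - st.mean_clustering) + ks)
        mean_disc = float(np.mean(discs))
        if mean_disc < best_disc:  # strict: ties keep the smaller T
            best_t, best_disc = t_cand, mean_disc
    return float(best_t)


# ---------------------------------------------------------------------------
# Angular-recovery diagnostics
# ---------------------------------------------------------------------------

def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular correlation coefficient between two angle arrays
    (invariant under rotation of either variable)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    abar = np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))
    bbar = np.arctan2(np.mean(np.sin(b)), np.mean(np.cos(b)))
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)


def aligned_circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Circular correlation after choosing the better of the two chiralities
    (an embedding recovers angles only up to rotation and reflection)."""
    return max(circular_correlation(a, b), circular_correlation(a, -np.asarray(b)))
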