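# Methods

This note records the models, estimators, numerical choices and known
limitations behind `hypermux`. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; no empirical claim below goes
beyond what those runs measure.

## Multiplex representation

A multiplex network is an ordered tuple of layers over one shared node
universe of size N; isolated nodes are kept in every layer. Input labels
are normalized to a contiguous internal index 0..N−1 with the label map
persisted on the network object, because layers of real datasets often
cover different label subsets while the model requires one universe.
Edge-list I/O is plain text (`layer u v`, optional ignored weight column);
two structured comments (`#nodes:`, `#layers:`) make write→read lossless
for isolated nodes and empty layers. Written files are canonically sorted,
so equal networks produce byte-identical files.

Per-layer statistics are the standard set: mean degree ⟨k⟩ = 2E/N, density
S = 2E/(N(N−1)), degree heterogeneity H = ⟨k²⟩/⟨k⟩² (≥ 1 by Jensen; NaN for
edgeless layers), and mean local clustering with degree-<2 nodes counted as
zero. Published tables for the reference datasets print these values with
inconsistent rounding (some entries truncated, one rounded), so the
acceptance comparison accepts a match under either convention at the
printed precision.

## PSO generator

Growth follows the popularity×similarity optimization rule. Node t enters
at radius r_t = 2 ln t with an angle drawn uniformly (or, in nonuniform
mode, from a wrapped-normal mixture of C equally spaced community centers
with spread σ = π/(2C) — a documented approximation, since the nonuniform
variant's angular law is not standardized). Existing nodes fade outward,
r_s(t) = β r_s + (1−β) r_t with β = 1/(γ−1), and the newcomer links to
min(m, t−1) targets: the hyperbolically nearest at T = 0, else a
without-replacement draw weighted by the Fermi–Dirac factor with the
cutoff R_t calibrated by bisection so the expected connection count is m.
Consequences asserted in tests: the edge count is exactly Σ_t min(m, t−1)
at every temperature, final radii are nondecreasing in birth time and
bounded by 2 ln N, and the Clauset estimate of the degree exponent at
N = 1000 recovers γ within 0.3 (10-seed mean).

`grow_multiplex` builds correlated fixtures: layer 1 is a PSO network and
each further layer rewires a fraction f of its edges to uniformly random
non-edges, preserving edge counts; the interlayer link overlap decreases
monotonically in f (≈ 1−f for sparse layers). N ≥ m+2 is required — at
m = N−1 growth degenerates to a clique.

Generator defaults used throughout testing are the study conditions of the
evaluation protocols: N = 500 (precision comparisons, scaled for desk
runtimes) or N = 1000 (exponent recovery), m = 4, γ = 3, T = 0.3/0.6.

## Geometry kernel

Distances use the exact hyperboloid formula
x = arccosh(cosh r_i cosh r_j − sinh r_i sinh r_j cos Δθ) with
Δθ = π − |π − |θ_i − θ_j||; the argument is clamped at 1 against roundoff
for near-coincident points. Two large-radius approximations are provided
for study (r_i + r_j + 2 ln sin(Δθ/2), valid at any angle, and the
small-angle r_i + r_j + 2 ln(Δθ/2) form); scoring always uses the exact
form, and Δθ = 0 in an approximate mode falls back to the exact value
rather than returning −∞. The Fermi–Dirac probability is computed with a
logistic expit and its log-forms via `logaddexp` for stability deep in the
tails.

## Parameter estimation

**Degree exponent γ.** Exact discrete power-law MLE: minimize
n ln ζ(γ, k_min) + γ Σ ln k_i over γ, with the familiar closed form
1 + n [Σ ln(k_i/(k_min−½))]⁻¹ only bracketing the search (that closed form
is biased low at small k_min — ≈2.33 instead of 2.5 at k_min = 2 in our
calibration — which is why it is not used directly). When k_min is not
given it is chosen by minimizing the Kolmogorov–Smirnov distance between
the empirical tail and the fitted zeta model, requiring at least 10 tail
degrees. Layers whose degree sequence supports no fit (small dense social
layers typically don't) fall back to γ = 2.5 with a warning; hyperbolic
prediction is known to degrade on such layers.

**Temperature T.** For each candidate on a grid (default 0.1..0.9), grow
`replicates` PSO twins with the layer's N, m = round(⟨k⟩/2) and γ, and
score the discrepancy |Δ mean clustering| + KS distance between degree
distributions, equally weighted; the grid value with the smallest mean
discrepancy wins, ties to the smaller T (less clustering assumed when
indistinguishable). Self-consistency: layers grown at T = 0.3 are recovered
within one grid step in the majority of seeds.

## Embedding

Radii follow the degree-rank schedule r_rank(t) = 2β ln t + 2(1−β) ln N
(decreasing degree, ties by ascending id), which operationalizes
r_i ~ ln N − ln k_i while fixing the free constant; the disk radius
defaults to R = 2 ln N and is exposed as an override, as the model fixes
only R ~ ln N.

Angles are optimized on a uniform grid of max(360, N) candidates
(deterministic, ties to the smallest angle; no random restarts). The
initial configuration comes from the normalized-Laplacian eigenmap: the
angle atan2(v₃, v₂) of eigenvectors 2 and 3 traces the similarity circle of
geometric networks. We use this global start because purely sequential
greedy placement — insert nodes one at a time at their local likelihood
optimum — systematically locks whole angular arcs into a wrong circular
order that later single-node moves cannot repair: on PSO ground truth its
recovered angles correlate poorly (median aligned circular correlation
≈ 0.15 at N = 300) even though its likelihood keeps improving, while the
spectral start reaches ≈ 0.95 under the identical refinement. Sequential
placement is retained for graphs with fewer than 5 non-isolated nodes and
as `init="sequential"`.

Refinement is coordinate ascent: each sweep re-optimizes every node's angle
over the same grid against all other nodes under the Bernoulli likelihood,
so the total log-likelihood is non-decreasing across sweeps (asserted per
run). One sweep is the default; more sweeps buy small gains at linear cost.
Degree-0 nodes carry no signal and are pinned at (2 ln N, 0), where they
cannot perturb candidate rankings.

Limitation: on a minority of PSO realizations (~1 in 5 at N = 300, m = 4,
T = 0.3) the maximum-likelihood configuration genuinely differs from the
generator's angles — the refined likelihood exceeds that of the true
coordinates while the angular correlation stays low. No optimizer of this
objective can recover such seeds; the recovery criterion is therefore a
median across seeds, not a per-seed guarantee.

## Similarity measures

PA, CN, CAR (CN × links among common neighbors) and CJC (CAR / neighborhood
union, defined as 0 on an empty union) are set arithmetic, each verified
against brute-force enumeration on random graphs. HP is the exact
hyperbolic distance with lower-is-link orientation; every other table is
higher-is-link, and the orientation travels with the table so downstream
ranking and fusion never guess.

WCN thresholds each common-neighbor tie against h, the mean hyperbolic
length of the layer's existing links: a strong tie (H < h, strictly)
contributes 1 + 1/H, a weak tie contributes 1 — hence WCN ≥ 2·CN with
equality when all ties are weak. The strong-tie test is applied to the tie
(i,k), not the candidate pair (i,j): H is defined only on existing links
and a candidate pair typically is not one. Coincident coordinates are
capped at H = 1e−9 so a zero distance cannot produce an infinite score.

Borda aggregation scores each element by the number of elements ranked
strictly worse within each input list (tied raw scores share credit) and
sums across lists; this handles ties without fractional ranks and is
verified against a count-strictly-worse oracle. Rank-CN-HP is the Borda
aggregate of the CN and HP orderings over the candidate set with equal
weight.

## Fusion and layer relevance

Link overlap O = 2|E_α ∩ E_β| / (|E_α| + |E_β|) is the default relevance;
Pearson and Spearman correlations over the upper-triangular 0/1 pair
indicators are available alternatives (the indicator-vector construction is
our choice of vectorization). The fused score is the linear combination
S = s^α + η Σ μ^{αβ} s^β with η = 1 by default (the coupling strength is a
free parameter of the method; 1 weights interlayer evidence exactly by
overlap). Distance-valued tables are negated before fusion so "higher =
more link-like" holds uniformly. Raw scores are fused without per-layer
normalization, matching the formula as published even though score scales
differ across measures; a rank-normalizing variant would be a
straightforward extension but is deliberately not the default.

## Evaluation protocols

*Missing links*: hide a fraction (default 15%) of the target layer's edges
using cycled disjoint k-folds (k = round(1/fraction), reshuffled when a
cycle completes — our reading of "k-fold decomposition" with more
repetitions than folds), re-embed the perturbed target layer for
coordinate-based measures, score all non-observed pairs, and take top-L
precision with L = number hidden. *Spurious links*: inject random
non-edges numbering 15% of |E| by default (the injected fraction is not
standardized; it mirrors the holdout), re-embed, score all observed links,
rank in reverse (least link-like first), precision at L = number injected.

Default 20 repetitions; the acceptance runs use 5 at N = 500 to stay
within desk runtimes, which is enough to separate the measures from the
random baseline by an order of magnitude. The target layer defaults to the
densest layer. Non-target layers are never perturbed and are embedded once
from their full topology; γ and T are resolved once per layer (estimated
from the unperturbed topology when not supplied) and reused across
repetitions, while angular coordinates of the perturbed layer are re-inferred
every repetition. Relevance weights are recomputed against the perturbed
(observed) target layer each repetition. All randomness flows from one
master seed; identical seeds give identical reports.

The distance-bin diagnostic sorts all node pairs by hyperbolic distance
into equal-count bins and reports the link fraction per bin; the
size-weighted mean of the bin probabilities equals the graph density
exactly, by construction. In sparse low-temperature regimes (e.g. N = 500,
m = 4, T = 0.3) all links fall in the nearest few bins and the remaining
bins are exactly zero; a rank correlation across all 20 bins is then capped
by the tied zeros (ρ ≈ −0.7..−0.8) even though the decay is as strong as it
can be. At T = 0.6 links spread across bins and ρ reaches ≤ −0.9. Tests
assert the sharp threshold in the spread regime and the trend plus exact
conservation in the sparse regime.

## What the synthetic generator does and does not emulate

PSO networks reproduce the features that matter for hyperbolic link
prediction — scale-free degrees, strong clustering, geometric link
probability — and `grow_multiplex` adds tunable interlayer overlap. They do
not emulate degree-degree correlations between layers beyond what copying
induces, non-power-law small social layers (where γ estimation falls back),
or community structure unless the nonuniform mode is used. Passing tests
on these fixtures therefore demonstrate correctness of the machinery and
the qualitative ordering of measures, not performance guarantees on any
particular real dataset.

## Known limitations

- Scoring all non-edges is O(N²) pairs; desk-scale (N ≤ ~2000) is the
  intended regime.
- The spectral initialization needs a reasonably connected layer; heavily
  fragmented layers fall back to sequential placement and embed each
  component on the same disk without aligning components.
- Fusion of raw WCN scores across layers can be dominated by a single
  strong-tie term (scores are unbounded); with overlapping layers this
  occasionally costs a little precision relative to the single-layer run,
  within the tolerance asserted by the tests.
- The spurious-link protocol re-embeds with the injected edges included, as
  published; an embedding robust to adversarial edges is out of scope.
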