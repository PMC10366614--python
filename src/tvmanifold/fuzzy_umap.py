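"""UMAP from its defining equations.

Phase 1 builds a fuzzy weighted graph: a directed k-NN graph whose edge
weights decay exponentially with distance beyond each node's nearest-neighbor
distance rho_i, scaled by a per-node sigma_i calibrated so the total
membership mass equals log2(k); the directed matrix B is symmetrized by the
fuzzy union C = B + B^T - B o B^T. Phase 2 lays out the graph in R^m by
stochastic gradient descent on the edge-wise cross-entropy between C and the
low-dimensional similarity kernel 1/(1 + a d^(2b)), with negative sampling
for the repulsive term and a learning rate decaying linearly to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import curve_fit

from .containers import DissimilarityMatrix, Embedding
from .tvfc import knn_sets

_SIGMA_TOL = 1e-5
_SIGMA_MAX_ITER = 64


@dataclass
class UmapParams:
    k: int = 70
    m: int = 3
    min_dist: float = 0.8
    learning_rate: float = 1.0
    n_epochs: int = 500
    negative_sample_rate: int = 5
    init: str = "spectral"  # {"spectral", "random"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 < self.min_dist < 2):
            raise ValueError("min_dist must be in (0, 2)")
        if self.init not in ("spectral", "random"):
            raise ValueError("init must be 'spectral' or 'random'")


@dataclass
class FuzzyGraph:
    """Directed membership matrix B, fuzzy union C, and (rho, sigma)."""

    B: np.ndarray
    C: np.ndarray
    rho: np.ndarray
    sigma: np.ndarray
    k: int
    metric: str
    neighbor_index: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.B.shape[0]


def rho_sigma(ds: DissimilarityMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-node normalization: rho_i is the smallest positive neighbor
    distance; sigma_i solves sum_j exp(-max(0, d_ij - rho_i)/sigma_i) = log2(k)
    over the k nearest neighbors, by bisection.

    If all k neighbors are equidistant the sum is k for every sigma; the lower
    bracket limit is returned with a warning (documented degenerate case).
    """
    n = ds.n
    if not (2 <= k <= n - 1):
        raise ValueError(f"k must be in [2, {n - 1}]")
    nbrs = knn_sets(ds, k)
    target = np.log2(k)
    rho = np.empty(n)
    sigma = np.empty(n)
    d_max = ds.values.max()
    lo0, hi0 = 1e-8 * d_max, 1e3 * d_max
    for i in range(n):
        d = ds.values[i, nbrs[i]]
        pos = d[d > 0]
        rho[i] = pos.min() if pos.size else 0.0
        adj = np.maximum(0.0, d - rho[i])
        with np.errstate(under="ignore"):
            s_floor = np.exp(-adj / lo0).sum() if adj.max() > 0 else float(k)
        if s_floor >= target:
            # membership mass cannot drop below the count of ties at rho; the
            # equation has no root and sigma is pinned to the bracket floor
            warnings.warn(
                f"node {i}: neighbor ties leave membership sum >= log2(k) for all "
                "sigma; pinned to bracket floor",
                stacklevel=2,
            )
            sigma[i] = lo0
            continue
        lo, hi = lo0, hi0
        s = None
        for _ in range(_SIGMA_MAX_ITER):
            mid = (lo + hi) / 2.0
            s = np.exp(-adj / mid).sum()
            if abs(s - target) < _SIGMA_TOL:
                break
            if s > target:  # too much mass -> shrink sigma
                hi = mid
            else:
                lo = mid
        if s is not None and abs(s - target) > 1e-2:
            raise RuntimeError(f"sigma calibration failed for node {i}")
        sigma[i] = mid
    return rho, sigma


def fuzzy_graph(ds: DissimilarityMatrix, k: int) -> FuzzyGraph:
    """Directed membership strengths over the k-NN edge set and their fuzzy
    union C = B + B^T - B o B^T."""
    rho, sigma = rho_sigma(ds, k)
    nbrs = knn_sets(ds, k)
    n = ds.n
    B = np.zeros((n, n))
    for i in range(n):
        d = ds.values[i, nbrs[i]]
        B[i, nbrs[i]] = np.exp(-np.maximum(0.0, d - rho[i]) / sigma[i])
    C = B + B.T - B * B.T
    return FuzzyGraph(B=B, C=C, rho=rho, sigma=sigma, k=k, metric=ds.metric, neighbor_index=nbrs)


def fit_ab(min_dist: float, spread: float = 1.0) -> tuple[float, float]:
    """Least-squares fit of 1/(1 + a d^(2b)) to the piecewise target curve
    (1 for d <= min_dist, exp(-(d - min_dist)/spread) beyond) on d in [0, 3]."""
    if not (0 < min_dist < 2):
        raise ValueError("min_dist must be in (0, 2)")
    grid = np.linspace(0.0, 3.0 * spread, 300)
    target = np.where(grid <= min_dist, 1.0, np.exp(-(grid - min_dist) / spread))

    def kernel(d, a, b):
        return 1.0 / (1.0 + a * d ** (2.0 * b))

    try:
        (a, b), _ = curve_fit(kernel, grid, target, p0=(1.0, 1.0), maxfev=10_000)
    except RuntimeError as exc:  # pragma: no cover - curve_fit failure
        raise RuntimeError(f"could not fit (a, b) for min_dist={min_dist}") from exc
    return float(a), float(b)


def _spectral_init(C: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components

    from .le import NeighborGraph, le_embed

    n_comp, _ = connected_components((C > 0).astype(int), directed=False)
    if n_comp > 1:
        return 10.0 * rng.uniform(-1, 1, size=(C.shape[0], m))
    graph = NeighborGraph(weights=(C + C.T) / 2.0, k=0, metric="euclidean", n_components=1)
    coords = le_embed(graph, m).coords
    # scale to a ~10-unit box, the reference convention for SGD step sizes
    coords = coords / (np.abs(coords).max() + 1e-12) * 10.0
    return coords + 1e-4 * rng.standard_normal(coords.shape)


@njit(cache=True)
def _sgd_layout(
    Y, heads, tails, epochs_per_sample, a, b, lr, n_epochs, neg_rate, seed
):  # pragma: no cover - exercised through umap_embed
    np.random.seed(seed)
    n = Y.shape[0]
    m = Y.shape[1]
    n_edges = heads.shape[0]
    next_due = epochs_per_sample.copy()
    epochs_per_negative = epochs_per_sample / neg_rate
    next_neg_due = epochs_per_negative.copy()
    displacement = np.zeros(n_epochs)
    Y_prev = Y.copy()
    for epoch in range(1, n_epochs + 1):
        alpha = lr * (1.0 - epoch / n_epochs)
        for e in range(n_edges):
            if next_due[e] > epoch:
                continue
            i = heads[e]
            j = tails[e]
            d2 = 0.0
            for c in range(m):
                d2 += (Y[i, c] - Y[j, c]) ** 2
            if d2 > 0.0:
                coeff = (-2.0 * a * b * d2 ** (b - 1.0)) / (1.0 + a * d2**b)
            else:
                coeff = 0.0
            for c in range(m):
                g = coeff * (Y[i, c] - Y[j, c])
                if g > 4.0:
                    g = 4.0
                elif g < -4.0:
                    g = -4.0
                Y[i, c] += alpha * g
                Y[j, c] -= alpha * g
            next_due[e] += epochs_per_sample[e]

            n_neg = int((epoch - next_neg_due[e]) / epochs_per_negative[e])
            for _ in range(n_neg):
                k = np.random.randint(0, n)
                if k == i:
                    continue
                d2 = 0.0
                for c in range(m):
                    d2 += (Y[i, c] - Y[k, c]) ** 2
                coeff = (2.0 * b) / ((0.001 + d2) * (1.0 + a * d2**b))
                for c in range(m):
                    g = coeff * (Y[i, c] - Y[k, c])
                    if g > 4.0:
                        g = 4.0
                    elif g < -4.0:
                        g = -4.0
                    Y[i, c] += alpha * g
            next_neg_due[e] += n_neg * epochs_per_negative[e]
        acc = 0.0
        for i in range(n):
            s = 0.0
            for c in range(m):
                s += (Y[i, c] - Y_prev[i, c]) ** 2
            acc += np.sqrt(s)
        displacement[epoch - 1] = acc / n
        Y_prev[:, :] = Y
    return displacement


def umap_embed(
    graph: FuzzyGraph,
    params: UmapParams,
    window_labels: list[str] | None = None,
    window_starts: np.ndarray | None = None,
    subject_id: str = "sub-01",
) -> Embedding:
    """Cross-entropy layout by asynchronous per-edge stochastic gradient descent.

    Attractive updates act along graph edges sampled in proportion to their
    fuzzy weight (edges below max_weight/n_epochs are never sampled) and move
    both endpoints; repulsive updates use uniform negative sampling at
    ``negative_sample_rate`` per attractive update and move the edge head.
    Gradient components are clipped at +/-4 and the learning rate decays
    linearly to zero. The per-epoch mean coordinate displacement is recorded
    in diagnostics.
    """
    rng = np.random.default_rng(params.seed)
    C = graph.C
    n = C.shape[0]
    a, b = fit_ab(params.min_dist)

    heads, tails = np.nonzero(C > 0)  # both directions, as in the reference scheme
    w = C[heads, tails]
    w_max = w.max()
    keep = w >= w_max / params.n_epochs
    heads, tails, w = heads[keep], tails[keep], w[keep]
    epochs_per_sample = w_max / w  # sample an edge every this many epochs

    if params.init == "spectral":
        Y = _spectral_init(C, params.m, rng)
    else:
        Y = 10.0 * rng.uniform(-1, 1, size=(n, params.m))

    Y = np.ascontiguousarray(Y, dtype=np.float64)
    displacement = _sgd_layout(
        Y,
        heads.astype(np.int64),
        tails.astype(np.int64),
        epochs_per_sample.astype(np.float64),
        float(a),
        float(b),
        float(params.learning_rate),
        int(params.n_epochs),
        float(params.negative_sample_rate),
        int(params.seed) % (2**31),
    )
    displacement = displacement.tolist()
    if not np.isfinite(Y).all():
        raise FloatingPointError("non-finite coordinates during layout optimization")

    return Embedding(
        coords=Y,
        method="UMAP",
        hyperparams={
            "k": params.k,
            "m": params.m,
            "min_dist": params.min_dist,
            "learning_rate": params.learning_rate,
            "n_epochs": params.n_epochs,
            "metric": graph.metric,
            "seed": params.seed,
            "a": a,
            "b": b,
        },
        window_labels=window_labels or [],
        window_starts=window_starts,
        subject_id=subject_id,
        diagnostics={"epoch_displacement": displacement},
    )


def cross_entropy(C: np.ndarray, coords: np.ndarray, a: float, b: float) -> float:
    """Edge-wise cross-entropy between the fuzzy graph and the layout kernel."""
    eps = 1e-12
    i, j = np.nonzero(np.triu(C, k=1) > 0)
    wc = C[i, j]
    d2 = np.sum((coords[i] - coords[j]) ** 2, axis=1)
    wh = 1.0 / (1.0 + a * d2**b)
    wc = np.clip(wc, eps, 1 - eps)
    wh = np.clip(wh, eps, 1 - eps)
    return float(np.sum(wc * np.log(wc / wh) + (1 - wc) * np.log((1 - wc) / (1 - wh))))
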