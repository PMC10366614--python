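"""Laplacian Eigenmaps built from the graph Laplacian generalized eigenproblem.

Pipeline: dissimilarities -> weighted k-NN affinity W (1 for mutual neighbors,
0.5 for one-directional, 0 otherwise; a strictly binary variant is available)
-> L = D - W -> solve L f = lambda D f -> embed with eigenvectors f_1..f_m
(ascending eigenvalues, the constant f_0 dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .containers import DissimilarityMatrix, Embedding
from .tvfc import knn_sets


@dataclass
class NeighborGraph:
    """Symmetric weighted k-NN graph (values in {0, 0.5, 1})."""

    weights: np.ndarray
    k: int
    metric: str
    n_components: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("affinity must be symmetric")
        if (np.abs(np.diag(self.weights)) > 0).any():
            raise ValueError("affinity diagonal must be zero")
        if (self.weights.sum(axis=1) == 0).any():
            raise ValueError("every node needs at least one incident edge")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def le_affinity(ds: DissimilarityMatrix, k: int, weighted: bool = True) -> NeighborGraph:
    """k-NN affinity: W_ij = 1 if i and j are mutually nearest neighbors,
    0.5 if the relation holds in one direction only, 0 otherwise.

    With ``weighted=False`` any one-directional relation yields 1 (the
    undirected unweighted graph).
    """
    nbrs = knn_sets(ds, k)
    n = ds.n
    directed = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    directed[rows, nbrs.ravel()] = 1.0
    if weighted:
        W = (directed + directed.T) / 2.0
    else:
        W = np.maximum(directed, directed.T)
    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    return NeighborGraph(weights=W, k=k, metric=ds.metric, n_components=n_comp)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def le_embed(
    graph: NeighborGraph,
    m: int = 3,
    window_labels: list[str] | None = None,
    window_starts: np.ndarray | None = None,
    subject_id: str = "sub-01",
) -> Embedding:
    """Solve L f = lambda D f and return eigenvectors f_1..f_m.

    The generalized problem is solved in the symmetric normalized form
    D^(-1/2) L D^(-1/2) v = lambda v with f = D^(-1/2) v for numerical
    stability; eigenvalues are stored in the embedding diagnostics. A
    disconnected graph embeds all components jointly (zero-eigenvalue
    multiplicity equals the component count) with a warning.
    """
    n = graph.n
    if m > n - 2:
        raise ValueError(f"m must be <= n - 2 = {n - 2}")
    if graph.n_components > 1:
        warnings.warn(
            f"neighbor graph has {graph.n_components} connected components; "
            "embedding them jointly",
            stacklevel=2,
        )
    W = graph.weights
    deg = W.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(deg)
    L_sym = np.eye(n) - (d_isqrt[:, None] * W * d_isqrt[None, :])
    L_sym = (L_sym + L_sym.T) / 2.0
    eigvals, eigvecs = scipy.linalg.eigh(L_sym, subset_by_index=(0, m))
    f = d_isqrt[:, None] * eigvecs  # generalized eigenvectors of (L, D)
    f = _fix_signs(f)
    coords = f[:, 1 : m + 1]
    return Embedding(
        coords=coords,
        method="LE",
        hyperparams={"k": graph.k, "metric": graph.metric, "m": m},
        window_labels=window_labels or [],
        window_starts=window_starts,
        subject_id=subject_id,
        diagnostics={
            "eigenvalues": eigvals.tolist(),
            "n_components": graph.n_components,
        },
    )


@dataclass
class _LeRunner:
    """Convenience: dissimilarity -> affinity -> embedding in one call."""

    k: int = 75
    m: int = 3
    weighted: bool = True

    def __call__(self, ds: DissimilarityMatrix, **meta) -> Embedding:
        graph = le_affinity(ds, self.k, weighted=self.weighted)
        return le_embed(graph, self.m, **meta)
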