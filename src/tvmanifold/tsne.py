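"""T-SNE from its defining equations.

High-dimensional affinities are perplexity-calibrated conditional Gaussians
p_j|i symmetrized to a joint distribution P; low-dimensional affinities Q use
the heavy-tailed Student-t (1 degree of freedom) kernel; the layout minimizes
KL(P||Q) by exact-gradient descent with momentum and early exaggeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DissimilarityMatrix, Embedding

_EPS = 1e-12


@dataclass
class TsneParams:
    perplexity: float = 30.0
    m: int = 2
    learning_rate: float = 200.0
    n_iter: int = 1000
    early_exaggeration_factor: float = 4.0
    early_exaggeration_iters: int = 100
    init: str = "pca"  # {"pca", "random"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.perplexity <= 1:
            raise ValueError("perplexity must exceed 1")
        if self.init not in ("pca", "random"):
            raise ValueError("init must be 'pca' or 'random'")


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _conditional_p(d2_row: np.ndarray, sigma: float, i: int) -> np.ndarray:
    """p_j|i for one sample given squared distances and kernel width."""
    logits = -d2_row / (2.0 * sigma**2)
    logits[i] = -np.inf
    logits -= logits.max()
    w = np.exp(logits)
    w[i] = 0.0
    return w / w.sum()


def calibrate_sigmas(
    ds: DissimilarityMatrix,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 128,
) -> np.ndarray:
    """Per-sample Gaussian widths sigma_i such that 2^H(p_.|i) = perplexity.

    Solved by bisection on log sigma. For samples whose neighbors are all
    equidistant the achieved perplexity is n-1 regardless of sigma; the
    bracket midpoint is returned.
    """
    n = ds.n
    if not (1.0 < perplexity < n):
        raise ValueError("require 1 < perplexity < n")
    d2 = ds.values**2
    target = np.log2(perplexity)
    sigmas = np.empty(n)
    for i in range(n):
        row = d2[i]
        others = np.delete(row, i)
        scale = np.sqrt(max(others.mean(), _EPS))
        lo, hi = np.log(scale) - 25.0, np.log(scale) + 25.0
        if others.max() - others.min() < 1e-15:
            sigmas[i] = np.exp((lo + hi) / 2.0)
            continue
        converged = False
        for _ in range(max_iter):
            mid = (lo + hi) / 2.0
            h = _entropy_bits(_conditional_p(row, np.exp(mid), i))
            if abs(h - target) < tol:
                converged = True
                break
            if h > target:  # kernel too wide
                hi = mid
            else:
                lo = mid
        if not converged and abs(h - target) > 1e-2:
            raise RuntimeError(f"perplexity calibration failed for sample {i}")
        sigmas[i] = np.exp(mid)
    return sigmas


def conditional_p_matrix(ds: DissimilarityMatrix, sigmas: np.ndarray) -> np.ndarray:
    d2 = ds.values**2
    n = ds.n
    P = np.empty((n, n))
    for i in range(n):
        P[i] = _conditional_p(d2[i], sigmas[i], i)
    return P


def joint_p(ds: DissimilarityMatrix, perplexity: float) -> np.ndarray:
    """Symmetrized joint affinities P_ij = (p_i|j + p_j|i)/(2n); sum(P) = 1."""
    sigmas = calibrate_sigmas(ds, perplexity)
    cond = conditional_p_matrix(ds, sigmas)
    P = (cond + cond.T) / (2.0 * ds.n)
    return P


def low_dim_q(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t affinities Q_ij and the unnormalized kernel (1 + d^2)^-1.

    Normalization is over ordered pairs: sum_{k != l} Q_kl = 1.
    """
    coords = np.asarray(coords, dtype=float)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    num = 1.0 / (1.0 + d2)
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return Q, num


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))))


def _classical_mds(ds: DissimilarityMatrix, m: int) -> np.ndarray:
    """Classical MDS (PCoA) coordinates; equals PCA scores for Euclidean input."""
    d2 = ds.values**2
    n = ds.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:m]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def tsne_embed(
    ds: DissimilarityMatrix,
    params: TsneParams,
    window_labels: list[str] | None = None,
    window_starts: np.ndarray | None = None,
    subject_id: str = "sub-01",
) -> Embedding:
    """Minimize KL(P||Q) by exact gradient descent with momentum.

    Early exaggeration multiplies P during the initial iterations; momentum
    switches 0.5 -> 0.8 at iteration 250 (the method's published schedule).
    The per-iteration cost trace is stored in diagnostics.
    """
    n = ds.n
    P = joint_p(ds, params.perplexity)
    rng = np.random.default_rng(params.seed)
    if params.init == "pca":
        Y = _classical_mds(ds, params.m)
        # standard practice: small initial spread
        sd = Y[:, 0].std()
        if sd > 0:
            Y = Y / sd * 1e-4
    else:
        Y = rng.standard_normal((n, params.m)) * 1e-4

    update = np.zeros_like(Y)
    costs = []
    ee_iters = min(params.early_exaggeration_iters, params.n_iter)
    for it in range(params.n_iter):
        exaggerate = it < ee_iters
        P_eff = P * params.early_exaggeration_factor if exaggerate else P
        Q, num = low_dim_q(Y)
        if not np.isfinite(Y).all():
            raise FloatingPointError(f"non-finite coordinates at iteration {it}")
        PQ = (P_eff - Q) * num
        grad = 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)
        momentum = 0.5 if it < 250 else 0.8
        update = momentum * update - params.learning_rate * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0, keepdims=True)
        costs.append(kl_divergence(P, Q))

    Q, _ = low_dim_q(Y)
    final_cost = kl_divergence(P, Q)
    return Embedding(
        coords=Y,
        method="TSNE",
        hyperparams={
            "perplexity": params.perplexity,
            "m": params.m,
            "learning_rate": params.learning_rate,
            "metric": ds.metric,
            "seed": params.seed,
            "init": params.init,
        },
        window_labels=window_labels or [],
        window_starts=window_starts,
        subject_id=subject_id,
        diagnostics={
            "cost_trace": costs,
            "final_cost": final_cost,
            "early_exaggeration_iters": ee_iters,
        },
    )
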