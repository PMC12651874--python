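"""t-SNE from first principles.

t-distributed stochastic neighbour embedding maps n points to 2-D by
matching two similarity distributions. In the high-dimensional space,

    p_{j|i} = exp(-||x_i - x_j||^2 / 2 sigma_i^2) / sum_{k != i} exp(...)

with sigma_i chosen per point by bisection so that the Shannon perplexity
of p_{.|i} equals the requested value; the conditionals are symmetrized
to a joint P_ij = (p_{j|i} + p_{i|j}) / 2n. (An alternative, selectable
via ``affinity='joint'``, keeps the per-point kernels but normalizes the
whole matrix jointly in one sum.) In the embedding, a Student-t kernel
with one degree of freedom gives

    q_ij = (1 + ||y_i - y_j||^2)^-1 / sum_{k != l} (1 + ||y_k - y_l||^2)^-1

and the embedding minimizes KL(P || Q) by gradient descent with momentum
and early exaggeration. Exact (dense) gradients only — cohort sizes here
are tens of points, so no tree approximation is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["AffinityMatrices", "Embedding", "tsne_affinities", "tsne_embed", "tsne"]

_EPS = 1e-12


@dataclass
class AffinityMatrices:
    """Joint similarity matrix P with the per-point bandwidths behind it."""

    P: np.ndarray
    sigmas: np.ndarray
    achieved_perplexity: np.ndarray
    target_perplexity: float
    X: np.ndarray
    affinity: str = "conditional_symmetrized"


@dataclass
class Embedding:
    Y: np.ndarray
    Q: np.ndarray
    kl_trace: np.ndarray
    seed: int
    perplexity: float
    n_iter: int
    learning_rate: float

    @property
    def kl(self) -> float:
        return float(self.kl_trace[-1])


def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    s = np.sum(X * X, axis=1)
    d2 = s[:, None] + s[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _conditional_row(d2row: np.ndarray, i: int, beta: float) -> np.ndarray:
    """p_{.|i} for precision beta = 1/(2 sigma_i^2); entry i forced to 0."""
    logits = -beta * d2row
    logits[i] = -np.inf
    logits -= logits.max()
    p = np.exp(logits)
    p[i] = 0.0
    total = p.sum()
    return p / total


def _row_perplexity(p: np.ndarray) -> float:
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(np.exp(h))


def _bisect_beta(d2row: np.ndarray, i: int, target: float,
                 tol: float = 1e-5, max_iter: int = 200) -> tuple[float, float]:
    """Find the kernel precision whose conditional perplexity hits target."""
    beta, lo, hi = 1.0, 0.0, np.inf
    perp = _row_perplexity(_conditional_row(d2row, i, beta))
    for _ in range(max_iter):
        if abs(perp - target) < tol:
            break
        if perp > target:  # kernel too wide -> sharpen
            lo = beta
            beta = beta * 2.0 if not np.isfinite(hi) else (beta + hi) / 2.0
        else:
            hi = beta
            beta = beta / 2.0 if lo == 0.0 else (beta + lo) / 2.0
        perp = _row_perplexity(_conditional_row(d2row, i, beta))
    return beta, perp


def tsne_affinities(
    X: np.ndarray,
    perplexity: float = 5.0,
    affinity: str = "conditional_symmetrized",
    jitter: float | None = None,
    seed: int = 0,
) -> AffinityMatrices:
    """Build the joint similarity matrix P for t-SNE.

    ``jitter`` adds tiny seeded Gaussian noise to break exact duplicate
    points, whose zero distances make the bandwidth search ill-posed;
    without it, duplicates raise.
    """
    X = np.asarray(X, float)
    n = len(X)
    if n < 3:
        raise ValueError("t-SNE needs at least 3 points")
    if not 0 < perplexity < n:
        raise ValueError(f"perplexity must lie in (0, {n})")
    if perplexity > (n - 1) / 3:
        warnings.warn(
            f"perplexity {perplexity} is large for n={n} "
            f"(guideline: <= (n-1)/3)", stacklevel=2)
    d2 = _pairwise_sq_dists(X)
    off = d2[~np.eye(n, dtype=bool)]
    if np.any(off == 0.0):
        if jitter is None:
            raise ValueError(
                "duplicate points collapse pairwise distances; "
                "pass jitter=<scale> to break ties")
        rng = np.random.default_rng(seed)
        X = X + jitter * rng.standard_normal(X.shape)
        d2 = _pairwise_sq_dists(X)

    betas = np.empty(n)
    achieved = np.empty(n)
    cond = np.zeros((n, n))
    for i in range(n):
        betas[i], achieved[i] = _bisect_beta(d2[i], i, perplexity)
        cond[i] = _conditional_row(d2[i], i, betas[i])
    if affinity == "conditional_symmetrized":
        P = (cond + cond.T) / (2.0 * n)
    elif affinity == "joint":
        K = np.exp(-d2 * betas[:, None])
        np.fill_diagonal(K, 0.0)
        P = K / K.sum()
    else:
        raise ValueError(f"unknown affinity variant {affinity!r}")
    sigmas = np.sqrt(1.0 / (2.0 * betas))
    return AffinityMatrices(P=P, sigmas=sigmas, achieved_perplexity=achieved,
                            target_perplexity=perplexity, X=X, affinity=affinity)


def _q_matrix(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    num = 1.0 / (1.0 + _pairwise_sq_dists(Y))
    np.fill_diagonal(num, 0.0)
    return num / num.sum(), num


def _kl(P: np.ndarray, Q: np.ndarray) -> float:
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))))


def tsne_embed(
    aff: AffinityMatrices,
    seed: int = 42,
    n_iter: int = 1000,
    learning_rate: float | str = "auto",
    momentum: tuple[float, float] = (0.5, 0.8),
    momentum_switch: int = 250,
    early_exaggeration: float = 4.0,
    exaggeration_iters: int = 100,
    n_components: int = 2,
) -> Embedding:
    """Gradient descent on KL(P || Q) with momentum and early exaggeration.

    The KL trace is recorded against the *un-exaggerated* P at every
    iteration. ``learning_rate='auto'`` uses max(n/early_exaggeration, 50),
    which keeps tiny cohorts stable.
    """
    P = aff.P
    n = len(P)
    if learning_rate == "auto":
        learning_rate = max(n / early_exaggeration, 50.0)
    rng = np.random.default_rng(seed)
    Y = 1e-4 * rng.standard_normal((n, n_components))
    update = np.zeros_like(Y)
    kl_trace = np.empty(n_iter + 1)
    Q, _ = _q_matrix(Y)
    kl_trace[0] = _kl(P, Q)
    best_Y, best_kl = Y.copy(), kl_trace[0]
    for it in range(n_iter):
        Pe = P * early_exaggeration if it < exaggeration_iters else P
        Q, num = _q_matrix(Y)
        W = (Pe - Q) * num
        # grad_i = 4 * sum_j W_ij (y_i - y_j)
        grad = 4.0 * (np.diag(W.sum(axis=1)) - W) @ Y
        mom = momentum[0] if it < momentum_switch else momentum[1]
        update = mom * update - learning_rate * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
        Q, _ = _q_matrix(Y)
        kl = _kl(P, Q)
        if not np.isfinite(kl):
            raise FloatingPointError(
                f"t-SNE diverged at iteration {it} "
                f"(lr={learning_rate}, momentum={mom}, exaggeration="
                f"{early_exaggeration if it < exaggeration_iters else 1})")
        kl_trace[it + 1] = kl
        if kl < best_kl and it >= exaggeration_iters:
            best_kl, best_Y = kl, Y.copy()
    # report the best post-exaggeration iterate
    Q, _ = _q_matrix(best_Y)
    return Embedding(Y=best_Y, Q=Q, kl_trace=kl_trace, seed=seed,
                     perplexity=aff.target_perplexity, n_iter=n_iter,
                     learning_rate=float(learning_rate))


def tsne(X: np.ndarray, perplexity: float = 5.0, seed: int = 42,
         **kwargs) -> Embedding:
    """Convenience wrapper: affinities + embedding in one call."""
    aff = tsne_affinities(X, perplexity=perplexity,
                          jitter=kwargs.pop("jitter", None), seed=seed)
    return tsne_embed(aff, seed=seed, **kwargs)
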