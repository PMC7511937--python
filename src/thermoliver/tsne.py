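"""t-SNE implemented from its defining equations.

Built for very small cohorts (N ≈ 10 mice), so everything is dense and
exact: Gaussian conditional neighbor probabilities with per-point
bandwidths found by bisection against a target perplexity, symmetrized
joint probabilities p_ij = (p_{i|j} + p_{j|i}) / 2N, Student-t (df = 1)
low-dimensional similarities q_ij with global normalization over all
ordered pairs, and plain momentum gradient descent on the
Kullback–Leibler divergence C = KL(P‖Q) with early exaggeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass(frozen=True)
class EmbeddingConfig:
    """Optimizer and model settings for the embedding.

    Defaults follow the method's published values scaled for tiny N:
    1000 iterations, learning rate 100, momentum 0.5 switching to 0.8 at
    iteration 250, early exaggeration ×4 for the first 100 iterations,
    Gaussian initialization with sd 1e−4. Perplexity defaults to 3,
    appropriate for 10-point cohorts.
    """

    n_components: int = 2
    perplexity: float = 3.0
    max_iter: int = 1000
    learning_rate: float = 100.0
    momentum: tuple[float, float] = (0.5, 0.8)
    momentum_switch_iter: int = 250
    early_exaggeration: float = 4.0
    exaggeration_iter: int = 100
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1 or self.max_iter < 1:
            raise ValueError("n_components and max_iter must be ≥ 1")
        if self.perplexity <= 0 or self.learning_rate <= 0:
            raise ValueError("perplexity and learning_rate must be positive")


@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates with the final KL objective and its trace."""

    coords: np.ndarray  # N × d
    final_kl: float
    kl_trace: np.ndarray = field(repr=False, default=None)


def standardize(X: np.ndarray) -> np.ndarray:
    """Column-wise z-scoring with population sd; constant columns map to 0."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("standardize needs at least 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = X - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def _sq_dists(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _row_probs(d2_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Conditional probabilities and perplexity (2^H, H in bits) for one row.

    ``beta`` = 1/(2σ²); ``d2_row`` excludes the self distance.
    """
    w = np.exp(-(d2_row - d2_row.min()) * beta)
    p = w / w.sum()
    H = -np.sum(p[p > 0] * np.log2(p[p > 0]))
    return p, 2.0**H


def conditional_p(
    X: np.ndarray,
    perplexity: float,
    tol: float = 1e-5,
    max_tries: int = 64,
) -> np.ndarray:
    """N×N matrix of Gaussian conditionals p_{j|i} with adapted bandwidths.

    Each row's σ_i is found by bisection (bracket grown by doubling) so
    that the row perplexity 2^{H(P_i)} matches the target within ``tol``.
    """
    X = np.asarray(X, dtype=np.float64)
    N = X.shape[0]
    if N < 3:
        raise ValueError("need at least 3 points")
    if not perplexity < N:
        raise ValueError(f"perplexity {perplexity} must be < N = {N}")
    d2 = _sq_dists(X)
    P = np.zeros((N, N))
    idx = np.arange(N)
    for i in range(N):
        d2_row = d2[i, idx != i]
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        p, perp = _row_probs(d2_row, beta)
        tries = 0
        while abs(perp - perplexity) > tol and tries < max_tries:
            if perp > perplexity:  # kernel too wide → narrow it
                beta_lo = beta
                beta = beta * 2.0 if np.isinf(beta_hi) else (beta + beta_hi) / 2.0
            else:
                beta_hi = beta
                beta = beta / 2.0 if beta_lo == 0.0 else (beta + beta_lo) / 2.0
            p, perp = _row_probs(d2_row, beta)
            tries += 1
        if abs(perp - perplexity) > tol:
            raise RuntimeError(
                f"bandwidth bisection did not converge for row {i}: "
                f"perplexity {perp:.6f} vs target {perplexity} "
                f"in bracket beta ∈ [{beta_lo}, {beta_hi}]"
            )
        P[i, idx != i] = p
    return P


def symmetrize(p_conditional: np.ndarray) -> np.ndarray:
    """Joint probabilities p_ij = (p_{i|j} + p_{j|i}) / 2N; total mass 1."""
    C = np.asarray(p_conditional, dtype=np.float64)
    N = C.shape[0]
    return (C + C.T) / (2.0 * N)


def q_matrix(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t similarities q_ij and the unnormalized kernel.

    Returns (Q, num) where num_ij = (1 + ‖y_i − y_j‖²)^{−1} with zero
    diagonal and Q = num / Σ num over all ordered pairs.
    """
    Y = np.asarray(Y, dtype=np.float64)
    num = 1.0 / (1.0 + _sq_dists(Y))
    np.fill_diagonal(num, 0.0)
    return num / num.sum(), num


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """C = Σ p_ij log(p_ij / q_ij) over pairs with p_ij > 0 (natural log)."""
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))))


def tsne(X: np.ndarray, config: EmbeddingConfig | None = None) -> EmbeddingResult:
    """Embed X into ``config.n_components`` dimensions by minimizing KL(P‖Q).

    Deterministic under ``config.seed``. The KL trace records the
    objective against the true (un-exaggerated) P at every iteration.
    """
    config = config or EmbeddingConfig()
    X = np.asarray(X, dtype=np.float64)
    if config.standardize:
        X = standardize(X)
    N = X.shape[0]
    P = symmetrize(conditional_p(X, config.perplexity))
    rng = np.random.default_rng(config.seed)
    Y = rng.normal(0.0, 1e-4, size=(N, config.n_components))
    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)
    trace = np.empty(config.max_iter)
    prev_obj = np.inf
    for it in range(config.max_iter):
        exaggerated = it < config.exaggeration_iter
        P_eff = P * config.early_exaggeration if exaggerated else P
        if it == config.exaggeration_iter:
            prev_obj = np.inf  # objective changes at the phase switch
        Q, num = q_matrix(Y)
        W = (P_eff - Q) * num
        grad = 4.0 * ((np.diag(W.sum(axis=1)) - W) @ Y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite embedding gradient at iteration {it}")
        m = config.momentum[0] if it < config.momentum_switch_iter else config.momentum[1]
        # delta-bar-delta gains from the reference optimizer: grow a
        # coordinate's step when gradient and velocity disagree in sign
        gains = np.where(np.sign(grad) != np.sign(velocity), gains + 0.2, gains * 0.8)
        np.maximum(gains, 0.01, out=gains)
        velocity = m * velocity - config.learning_rate * gains * grad
        Y_new = Y + velocity
        obj = kl_divergence(P_eff, q_matrix(Y_new)[0])
        if obj > prev_obj:
            # momentum/gain overshoot: fall back to a backtracking
            # gradient step so the per-phase objective never increases
            velocity[:] = 0.0
            gains[:] = 1.0
            step = config.learning_rate
            Y_new = Y - step * grad
            obj = kl_divergence(P_eff, q_matrix(Y_new)[0])
            while obj > prev_obj and step > 1e-12:
                step /= 2.0
                Y_new = Y - step * grad
                obj = kl_divergence(P_eff, q_matrix(Y_new)[0])
            if obj > prev_obj:
                Y_new = Y  # stationary within precision; hold position
                obj = prev_obj
        Y = Y_new
        prev_obj = obj
        trace[it] = obj if not exaggerated else kl_divergence(P, q_matrix(Y)[0])
    return EmbeddingResult(coords=Y, final_kl=float(trace[-1]), kl_trace=trace)
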