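"""Asymptotic splitting probabilities via the sums-of-logs linear system.

The probability that a particle released at an exterior point ``x`` is
captured by receptor ``k`` before any other is, to all orders in
``1/|log eps|``,

    phi*_k(x) = -pi * sum_j A_jk nu_j G_s(x; x_j) + phibar_k,

where the strengths ``A_jk`` and far-field constants ``phibar_k`` solve an
(N+1) x (N+1) linear system built from the surface Green's function matrix.
``phibar_k`` is the splitting probability seen from infinity, independent of
the source.  The no-monopole condition ``sum_j nu_j A_jk = 0`` makes every
result invariant under the additive gauge freedom of ``G_s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .geometry import ReceptorConfig
from .greens import laplace_surface_green, laplace_surface_regular_part

__all__ = [
    "StaticSolution",
    "solve_static",
    "splitting_probability",
    "leading_order_splitting",
    "ConditioningError",
]


class ConditioningError(RuntimeError):
    """The sums-of-logs linear system is numerically singular."""


@dataclass(frozen=True)
class StaticSolution:
    """Strengths and far-field splitting constants of the static problem.

    ``A[j, k]`` is the strength of receptor j in the problem targeting
    receptor k; ``phi_bar[k]`` the far-field splitting probability.
    """

    config: ReceptorConfig
    A: np.ndarray
    phi_bar: np.ndarray
    gauge: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "phi_bar", np.asarray(self.phi_bar, dtype=float))


def _surface_matrix(config: ReceptorConfig, gauge: float) -> np.ndarray:
    """[Gs]_ij with diagonal R_s(x_i); off-diagonal G_s(x_i; x_j)."""
    centers = config.centers
    n = config.n_receptors
    gs = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                gs[i, j] = laplace_surface_regular_part(centers[i], gauge)
            else:
                gs[i, j] = laplace_surface_green(centers[i], centers[j], gauge)
    return gs


def solve_static(config: ReceptorConfig, gauge: float = 0.0) -> StaticSolution:
    """Solve the sums-of-logs system for every target receptor.

    The (N+1) x (N+1) operator is target-independent (only the right-hand
    side changes with k), so it is factorized once.
    """
    n = config.n_receptors
    nu = config.nu
    gs = _surface_matrix(config, gauge)

    op = np.zeros((n + 1, n + 1))
    op[:n, :n] = np.eye(n) + np.pi * gs * nu[None, :]
    op[:n, n] = -1.0
    op[n, :n] = nu
    try:
        factor = lu_factor(op)
    except Exception as exc:  # pragma: no cover - scipy raises LinAlgError
        raise ConditioningError(str(exc)) from exc
    cond = np.linalg.cond(op)
    if not np.isfinite(cond) or cond > 1e14:
        raise ConditioningError(
            f"sums-of-logs operator is ill-conditioned (cond ~ {cond:.2e})"
        )

    A = np.empty((n, n))
    phi_bar = np.empty(n)
    rhs = np.zeros(n + 1)
    for k in range(n):
        rhs[:] = 0.0
        rhs[k] = -1.0
        sol = lu_solve(factor, rhs)
        A[:, k] = sol[:n]
        phi_bar[k] = sol[n]
    return StaticSolution(config=config, A=A, phi_bar=phi_bar, gauge=gauge)


def splitting_probability(x, solution: StaticSolution) -> np.ndarray:
    """phi*_k(x) for exterior point(s) x, shape (..., N).

    ``x`` is an (..., 2) array of points with |x| > 1, away from the arcs.
    """
    config = solution.config
    x = np.asarray(x, dtype=float)
    centers = config.centers
    gs = np.stack(
        [
            laplace_surface_green(x, centers[j], solution.gauge)
            for j in range(config.n_receptors)
        ],
        axis=-1,
    )
    weights = config.nu[:, None] * solution.A  # (j, k)
    phi = -np.pi * np.tensordot(gs, weights, axes=([-1], [0])) + solution.phi_bar
    return phi


def leading_order_splitting(N: int) -> np.ndarray:
    """Vanishing-receptor-size limit: all splitting probabilities equal 1/N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return np.full(N, 1.0 / N)
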