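"""Source localization from receptor arrival statistics.

Estimators, in decreasing order of machinery they presume of the cell:

* multinomial maximum likelihood over the cumulative fractional signals
  ``q_k(x; t)`` (negative log-likelihood landscape ``L = -sum c_k log q_k``,
  minimized over candidate source positions);
* the noise-free cross-entropy landscape ``L* = -sum q_k(x0) log q_k(x)``,
  whose sublevel sets show what the likelihood can resolve at best;
* algebraic triangulation: least-squares matching of eventual-capture
  fractions to the asymptotic splitting probabilities (identifiable for
  N >= 3 receptors);
* polar averaging of receptor angles over batches of early arrivals;
* extreme-value statistics of the very first arrival: Gumbel law of the
  minimum arrival time and the asymptotically normal first-arrival angle.

The extreme-value layer uses the short-time survival expansion
``1 - P(t) ~ A t^q exp(-B/t)``; for the homogenized Robin cell
``q = 3/2, A = 4 kappa sqrt(D/(pi R))/(R-1)^2, B = (R-1)^2/(4D)``, and for a
perfectly absorbing cell (kappa = inf) the same integration gives
``q = 1/2, A = 2 sqrt(D/(pi R))/(R-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import kve, lambertw
from scipy.stats import kstest

from .geometry import CountTable, ReceptorConfig, wrap_angle
from .greens import _k_ratios
from .simulate import ArrivalTable
from .static import StaticSolution, solve_static, splitting_probability
from .talbot import TalbotContour

__all__ = [
    "Landscape",
    "CumulativeSignal",
    "mle_landscape",
    "exact_landscape",
    "triangulate_source",
    "polar_average",
    "PolarAverageSeries",
    "ks_uniformity_pvalue",
    "GumbelParams",
    "extreme_params",
    "extreme_mean",
    "extreme_time_mean_large_M",
    "extreme_angle_variance",
    "default_grid",
]

_EULER_GAMMA = 0.5772156649015328606


def default_grid(r_min: float = 1.05, r_max: float = 40.0, n_r: int = 64,
                 n_theta: int = 256):
    """Log-spaced radii and uniform angles for landscape evaluation.

    Landscapes are elongated in the radial direction, so logarithmic radial
    gridding covers the plausible source distances efficiently.
    """
    radii = np.geomspace(r_min, r_max, n_r)
    angles = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    return radii, angles


class CumulativeSignal:
    """q_k as a function of a hypothetical source location.

    For ``t = inf`` the signals are the splitting probabilities; for finite
    ``t`` they are cumulative fractional fluxes, evaluated by caching one LU
    factorization of the strength system per Talbot node and re-solving for
    many candidate source positions at once.
    """

    def __init__(self, config: ReceptorConfig, t: float, D: float = 1.0,
                 n_nodes: int = 64, tol: float = 1e-10):
        self.config = config
        self.t = float(t)
        self.D = float(D)
        self.tol = tol
        self._static = solve_static(config)
        if np.isfinite(t):
            from scipy.linalg import lu_factor

            from .greens import HelmholtzEvalParams, surface_green_matrix

            contour = TalbotContour.for_time(t, n_nodes=n_nodes)
            s_nodes, ds_nodes = contour.upper_nodes()
            self._nodes = []
            self.n_nodes = n_nodes
            for s, ds in zip(s_nodes, ds_nodes):
                if (s * t).real < -690.0:
                    continue
                p = HelmholtzEvalParams(s=s, D=D, tol=tol)
                gh = surface_green_matrix(config, p)
                mat = (np.eye(config.n_receptors)
                       + np.pi * D * gh * config.nu[None, :])
                self._nodes.append((s, ds, lu_factor(mat), p.alpha))

    def _bulk_coeffs(self, radii: np.ndarray, alpha: complex,
                     m_max: int) -> np.ndarray:
        """(P, m_max+1) array of K_m(alpha*r)/(alpha*K_m'(alpha))."""
        r = np.asarray(radii, dtype=float)
        t_a = _k_ratios(alpha, m_max + 2)
        u = (kve(0, alpha * r) / kve(0, alpha)) * np.exp(-alpha * (r - 1.0))
        t1 = kve(1, alpha * r) / kve(0, alpha * r)
        out = np.empty((r.size, m_max + 1), dtype=complex)
        out[:, 0] = -u / (alpha * t_a[1])
        t_prev = t1
        for m in range(1, m_max + 1):
            u = u * t_prev / t_a[m]
            out[:, m] = u * (-2.0 / (alpha * (1.0 / t_a[m] + t_a[m + 1])))
            t_prev = 2.0 * m / (alpha * r) + 1.0 / t_prev
        return out

    def _m_max(self, r_min: float) -> int:
        m = int(np.ceil(-np.log(self.tol) / np.log(max(r_min, 1.0 + 1e-6))))
        return min(max(m, 16), 20_000)

    def q_points(self, points) -> np.ndarray:
        """q_k at candidate source points, shape (..., N)."""
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(-1, 2)
        if not np.isfinite(self.t):
            q = splitting_probability(flat, self._static)
            return q.reshape(pts.shape[:-1] + (self.config.n_receptors,))
        r = np.hypot(flat[:, 0], flat[:, 1])
        th = np.arctan2(flat[:, 1], flat[:, 0])
        cum = self._cumulative(r, th)
        C = cum.sum(axis=1, keepdims=True)
        q = np.where(C > 1e-14, cum / np.where(C == 0, 1.0, C),
                     1.0 / self.config.n_receptors)
        return q.reshape(pts.shape[:-1] + (self.config.n_receptors,))

    def _cumulative(self, r: np.ndarray, th: np.ndarray) -> np.ndarray:
        """Cumulative captures per receptor for P candidate sources, (P, N)."""
        from scipy.linalg import lu_solve

        n = self.config.n_receptors
        D = self.D
        nu = self.config.nu
        rec = self.config.angles
        m_arr_cache = {}
        acc = np.zeros((r.size, n))
        for s, ds, lu, alpha in self._nodes:
            m_max = self._m_max(float(r.min()))
            coeffs = self._bulk_coeffs(r, alpha, m_max)
            m = np.arange(1, m_max + 1)
            # cos(m(theta_k - theta_x)) = cos m th_k cos m th_x + sin.. sin..
            ck = np.cos(np.outer(m, rec))
            sk = np.sin(np.outer(m, rec))
            cx = coeffs[:, 1:] * np.cos(np.outer(th, m))
            sx = coeffs[:, 1:] * np.sin(np.outer(th, m))
            g0 = (-coeffs[:, [0]] / 2.0 - (cx @ ck + sx @ sk)) / (np.pi * D)
            A = lu_solve(lu, g0.T)  # (N, P)
            jhat = np.pi * D * nu[:, None] * A
            w = np.exp(s * self.t) * ds / s
            acc += (w * jhat.T).imag
        return 2.0 * acc / self.n_nodes

    def q_grid(self, radii, angles) -> np.ndarray:
        """q_k on a polar grid, shape (n_r, n_theta, N).

        Exploits the product structure: Bessel coefficients depend only on
        the radius and the angular part only on the angle, so each Talbot
        node costs two small matrix products.
        """
        radii = np.asarray(radii, dtype=float)
        angles = np.asarray(angles, dtype=float)
        n = self.config.n_receptors
        if not np.isfinite(self.t):
            pts = np.stack(
                [
                    np.outer(radii, np.cos(angles)),
                    np.outer(radii, np.sin(angles)),
                ],
                axis=-1,
            )
            return self.q_points(pts)
        D, nu, rec = self.D, self.config.nu, self.config.angles
        from scipy.linalg import lu_solve

        acc = np.zeros((radii.size, angles.size, n))
        for s, ds, lu, alpha in self._nodes:
            m_max = self._m_max(float(radii.min()))
            coeffs = self._bulk_coeffs(radii, alpha, m_max)  # (n_r, m+1)
            m = np.arange(1, m_max + 1)
            dmat = np.cos(
                m[:, None, None] * (rec[None, :, None] - angles[None, None, :])
            )  # (m, N, n_theta)
            series = np.tensordot(coeffs[:, 1:], dmat, axes=([1], [0]))
            g0 = (-coeffs[:, [0], None] / 2.0 - series) / (np.pi * D)
            # solve for all (r, theta) right-hand sides at once
            rhs = g0.transpose(1, 0, 2).reshape(n, -1)
            A = lu_solve(lu, rhs)
            jhat = np.pi * D * nu[:, None] * A
            w = np.exp(s * self.t) * ds / s
            acc += (w * jhat).imag.T.reshape(radii.size, angles.size, n,
                                             order="C")
        cum = 2.0 * acc / self.n_nodes
        C = cum.sum(axis=-1, keepdims=True)
        return np.where(C > 1e-14, cum / np.where(C == 0, 1.0, C), 1.0 / n)


@dataclass(frozen=True)
class Landscape:
    """A likelihood (or cross-entropy) surface over candidate sources."""

    radii: np.ndarray
    angles: np.ndarray
    values: np.ndarray
    x_hat: np.ndarray
    x_hat_grid: np.ndarray
    level_fractions: tuple = ()
    source: np.ndarray | None = None

    def sublevel_mask(self, fraction: float) -> np.ndarray:
        """Grid mask of points within ``fraction`` of the minimum value."""
        vmin = np.nanmin(self.values)
        return self.values <= vmin * (1.0 + fraction)


def _neg_log_likelihood(weights: np.ndarray, q: np.ndarray) -> np.ndarray:
    """-sum_k w_k log q_k with +inf where any weighted q vanishes."""
    bad = (q <= 0.0) & (weights > 0.0)
    safe = np.where(q > 0.0, q, 1.0)
    vals = -(weights * np.log(safe)).sum(axis=-1)
    vals = np.where(bad.any(axis=-1), np.inf, vals)
    return vals


def _landscape(weights, signal: CumulativeSignal, radii, angles, refine,
               levels, source=None) -> Landscape:
    if radii is None or angles is None:
        d_radii, d_angles = default_grid()
        radii = d_radii if radii is None else np.asarray(radii, float)
        angles = d_angles if angles is None else np.asarray(angles, float)
    q = signal.q_grid(radii, angles)
    vals = _neg_log_likelihood(weights, q)
    i, j = np.unravel_index(np.nanargmin(vals), vals.shape)
    x0 = radii[i] * np.array([np.cos(angles[j]), np.sin(angles[j])])
    x_hat = x0
    if refine:
        def objective(z):
            r = np.exp(z[0])
            if not 1.0 + 1e-6 < r < 1e4:
                return np.inf
            pt = r * np.array([np.cos(z[1]), np.sin(z[1])])
            return float(
                _neg_log_likelihood(weights, signal.q_points(pt[None, :]))[0]
            )

        res = minimize(objective, np.array([np.log(radii[i]), angles[j]]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 400})
        r_hat = np.exp(res.x[0])
        x_hat = r_hat * np.array([np.cos(res.x[1]), np.sin(res.x[1])])
    return Landscape(radii=radii, angles=angles, values=vals, x_hat=x_hat,
                     x_hat_grid=x0, level_fractions=tuple(levels),
                     source=source)


def mle_landscape(counts: CountTable, signal: CumulativeSignal,
                  radii=None, angles=None, refine: bool = True) -> Landscape:
    """Negative log-likelihood landscape L(x; t) = -sum_k c_k log q_k(x; t).

    The returned ``x_hat`` maximizes the multinomial likelihood of the
    observed counts (grid minimum of L, then derivative-free refinement).
    """
    if counts.counts.sum() == 0:
        raise ValueError("at least one arrival is required for MLE")
    return _landscape(counts.counts.astype(float), signal, radii, angles,
                      refine, levels=())


def exact_landscape(source_point, signal: CumulativeSignal, radii=None,
                    angles=None, refine: bool = True,
                    levels=(0.00125, 0.0025, 0.005, 0.01)) -> Landscape:
    """Cross-entropy landscape L*(x; x0, t) = -sum_k q_k(x0) log q_k(x).

    By Gibbs' inequality L*(x) >= L*(x0); the sublevel fractions (0.125% ..
    1%) delimit the region statistically indistinguishable from the source.
    """
    x0 = np.asarray(source_point, dtype=float)
    q0 = signal.q_points(x0[None, :])[0]
    return _landscape(q0, signal, radii, angles, refine, levels, source=x0)


def triangulate_source(counts: CountTable, solution: StaticSolution,
                       radii=None, angles=None) -> np.ndarray:
    """Least-squares source estimate from eventual-capture fractions.

    Matches ``c_k/M`` against the asymptotic splitting probabilities
    ``phi*_k(x)`` over a polar search grid with local refinement.  Requires
    N >= 3 receptors (below that the splitting system is not identifiable).
    """
    n = solution.config.n_receptors
    if n < 3:
        raise ValueError("source triangulation requires N >= 3 receptors")
    frac = counts.fractions
    if radii is None or angles is None:
        d_radii, d_angles = default_grid()
        radii = d_radii if radii is None else np.asarray(radii, float)
        angles = d_angles if angles is None else np.asarray(angles, float)
    pts = np.stack(
        [np.outer(radii, np.cos(angles)), np.outer(radii, np.sin(angles))],
        axis=-1,
    )
    phi = splitting_probability(pts, solution)
    resid = ((phi - frac) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(resid), resid.shape)

    def objective(z):
        r = np.exp(z[0])
        if not 1.0 + 1e-6 < r < 1e4:
            return np.inf
        pt = r * np.array([np.cos(z[1]), np.sin(z[1])])
        return float(((splitting_probability(pt, solution) - frac) ** 2).sum())

    res = minimize(objective, np.array([np.log(radii[i]), angles[j]]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 400})
    r_hat = np.exp(res.x[0])
    return r_hat * np.array([np.cos(res.x[1]), np.sin(res.x[1])])


@dataclass(frozen=True)
class PolarAverageSeries:
    """Batched polar-average direction estimates over sorted arrivals."""

    theta_pa: np.ndarray
    batch_end_times: np.ndarray
    complete: np.ndarray  # False for a trailing partial batch
    batch_size: int


def polar_average(table: ArrivalTable, M_s: int,
                  config: ReceptorConfig) -> PolarAverageSeries:
    """Count-weighted circular mean of receptor angles per arrival batch.

    Arrivals are sorted by time and grouped into consecutive batches of
    ``M_s``; each batch yields the circular mean (atan2 of summed unit
    vectors) of the receptor angles of its arrivals.  The circular mean is
    used instead of the literal arithmetic average, which is ill-defined
    across the +-pi cut; for sources near angle zero the two coincide.
    """
    if M_s < 1:
        raise ValueError("M_s must be >= 1")
    tab = table.sorted_by_time()
    sel = ~tab.censored
    ids = tab.receptor_ids[sel]
    times = tab.times[sel]
    ang = config.angles[ids]
    n_batches = int(np.ceil(ang.size / M_s))
    theta = np.empty(n_batches)
    t_end = np.empty(n_batches)
    complete = np.empty(n_batches, dtype=bool)
    for b in range(n_batches):
        chunk = slice(b * M_s, min((b + 1) * M_s, ang.size))
        a = ang[chunk]
        theta[b] = np.arctan2(np.sin(a).sum(), np.cos(a).sum())
        t_end[b] = times[chunk][-1]
        complete[b] = (chunk.stop - chunk.start) == M_s
    return PolarAverageSeries(theta_pa=theta, batch_end_times=t_end,
                              complete=complete, batch_size=M_s)


def ks_uniformity_pvalue(samples) -> float:
    """One-sample KS p-value of angles against Uniform(-pi, pi)."""
    samples = wrap_angle(np.asarray(samples, dtype=float))
    if samples.size < 5:
        raise ValueError("need at least 5 samples")
    res = kstest(samples, "uniform", args=(-np.pi, 2.0 * np.pi))
    return float(res.pvalue)


# ----------------------------------------------------------------------
# extreme-value (first arrival) statistics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GumbelParams:
    """Gumbel law of the fastest of M independent arrivals.

    ``(t_a - b_M)/a_M`` converges to the Gumbel minimum law
    ``P(X > x) = exp(-e^x)``; the parameters derive from the short-time
    survival expansion ``1 - P(t) ~ A t^q exp(-B/t)`` via the principal
    Lambert W value ``W_M = W((B/q) (A M)^{1/q})``.
    """

    M: int
    R: float
    kappa: float
    D: float
    q: float
    A: float
    B: float
    W_M: float
    a_M: float
    b_M: float


def extreme_params(M: int, R: float, kappa: float, D: float = 1.0) -> GumbelParams:
    """Gumbel location/scale for the first of M arrivals.

    ``kappa`` is the Robin permeability of the homogenized cell surface;
    ``kappa = inf`` selects the perfectly absorbing cell.
    """
    if M < 2:
        raise ValueError("extreme-value asymptotics need M >= 2")
    if not R > 1.0:
        raise ValueError("R must exceed the cell radius (R > 1)")
    if not (kappa > 0.0) or D <= 0.0:
        raise ValueError("kappa and D must be positive")
    B = (R - 1.0) ** 2 / (4.0 * D)
    if np.isinf(kappa):
        q = 0.5
        A = 2.0 * np.sqrt(D / (np.pi * R)) / (R - 1.0)
    else:
        q = 1.5
        A = 4.0 * kappa * np.sqrt(D / (np.pi * R)) / (R - 1.0) ** 2
    arg = (B / q) * (A * M) ** (1.0 / q)
    if arg <= 0.0:
        raise ValueError(f"Lambert-W argument must be positive, got {arg}")
    W = float(lambertw(arg).real)
    b_M = B / (q * W)
    a_M = b_M / (q * (1.0 + W))
    return GumbelParams(M=int(M), R=float(R), kappa=float(kappa), D=float(D),
                        q=q, A=float(A), B=float(B), W_M=W, a_M=float(a_M),
                        b_M=float(b_M))


def extreme_mean(params: GumbelParams) -> tuple[float, float]:
    """Mean and variance of the extreme arrival time.

    ``E[t_a] = b_M - gamma_e a_M`` and ``Var[t_a] = pi^2 a_M^2 / 6``.
    """
    mean = params.b_M - _EULER_GAMMA * params.a_M
    var = np.pi ** 2 * params.a_M ** 2 / 6.0
    return float(mean), float(var)


def extreme_time_mean_large_M(params: GumbelParams) -> float:
    """Large-M closed form of E[t_a] for the Robin cell (q = 3/2):

        E[t_a] ~ (R-1)^2 / (6 D W_M) * [1 - 2 gamma_e / (3 (1 + W_M))].
    """
    if params.q != 1.5:
        raise ValueError("large-M form applies to the Robin cell (q = 3/2)")
    W = params.W_M
    return float(
        (params.R - 1.0) ** 2 / (6.0 * params.D * W)
        * (1.0 - 2.0 * _EULER_GAMMA / (3.0 * (1.0 + W)))
    )


def angular_gain(R: float) -> float:
    """g(R) = (R-1)^2/(3R); the R-dependence of the first-arrival angle
    variance (zero when the source touches the membrane)."""
    if R < 1.0:
        raise ValueError("R must be >= 1")
    return (R - 1.0) ** 2 / (3.0 * R)


def extreme_angle_variance(M: int, R: float, kappa: float,
                           D: float = 1.0) -> float:
    """Variance of the first-arrival angle about the source direction.

    The first arrival occurs near the Gumbel mode t = b_M, when the angular
    flux profile is Gaussian with variance 2*D*t/R, so

        sigma^2_theta = 2 D b_M / R,

    which for the Robin cell (q = 3/2) equals g(R)/W_M with
    g(R) = (R-1)^2/(3R).  Decreasing in M; ~ R (1 - 1/R)^2 / log M for
    large M.
    """
    p = extreme_params(M, R, kappa, D)
    return float(2.0 * D * p.b_M / R)
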