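"""Effective Robin (partially absorbing) surface model.

For N >> 1 equally spaced, equally sized receptors the patchy boundary of
the cell can be replaced by a uniform Robin condition
``D dp/dn = kappa p`` with permeability

    D / kappa = -(2/N) * log(eps*N/4),

valid while eps*N < 4 (the receptors cannot over-cover the cell).  The
Laplace transform of the homogenized surface flux density at angle theta is
the cosine-mode series

    Jhat(theta, s) = chi_0(alpha)/(2 pi) + (1/pi) sum_m chi_m(alpha) cos m(theta-theta0),
    chi_m(alpha)   = K_m(alpha R) / (K_m(alpha) - (D/kappa) alpha K_m'(alpha)),

with ``alpha = sqrt(s/D)`` and source distance R.  ``chi_0`` transforms the
total capture rate, so the capture CDF is the inverse transform of
``chi_0/s``.  All Bessel factors are evaluated with scaled/ratio recurrences
so large |alpha R| cannot overflow.

Short times (``eps << sqrt(D t) << 1``) admit a boundary-layer moment
description: the flux density is asymptotically Gaussian in angle, centred on
the source direction, with variance 2*D*t/R — the basis of the package's
extreme-arrival statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import kve

from .greens import TruncationError, _k_ratios
from .talbot import TalbotContour, talbot_invert

__all__ = [
    "HomogenizedModel",
    "ShortTimeMoments",
    "homogenized_permeability",
    "robin_flux_mode",
    "homogenized_flux_density",
    "survival",
    "capture_cdf",
    "mode_ratio",
    "short_time_moments",
    "gaussian_approx",
]


def homogenized_permeability(N: int, eps: float, D: float = 1.0) -> float:
    """Effective permeability kappa = -N*D / (2*log(eps*N/4)).

    ``eps`` is the common angular extent (arclength on the unit cell) of each
    of the N equally spaced receptors; requires eps*N < 4.
    """
    if N < 1 or eps <= 0.0 or D <= 0.0:
        raise ValueError("need N >= 1, eps > 0, D > 0")
    x = eps * N / 4.0
    if x >= 1.0:
        raise ValueError(
            f"homogenization requires eps*N < 4 (got eps*N = {eps * N:g})"
        )
    return -N * D / (2.0 * np.log(x))


@dataclass(frozen=True)
class HomogenizedModel:
    """Robin-surface cell: permeability kappa, source distance R, diffusivity D."""

    kappa: float
    R: float
    D: float = 1.0
    theta0: float = 0.0
    m_modes: int = 256

    def __post_init__(self):
        if not (self.kappa > 0.0):
            raise ValueError("kappa must be positive (use np.inf for Dirichlet)")
        if not self.R > 1.0:
            raise ValueError("source must lie outside the cell (R > 1)")
        if self.D <= 0.0:
            raise ValueError("D must be positive")

    @property
    def dk(self) -> float:
        """The Robin length D/kappa (0 for a perfectly absorbing surface)."""
        return 0.0 if np.isinf(self.kappa) else self.D / self.kappa


def robin_flux_mode(m: int, alpha: complex, model: HomogenizedModel) -> complex:
    """Mode transform chi_m(alpha) = K_m(aR)/(K_m(a) - (D/kappa) a K_m'(a))."""
    return _chi_modes(alpha, model, m_max=m)[m]


def _chi_modes(alpha: complex, model: HomogenizedModel, m_max: int) -> np.ndarray:
    """chi_0..chi_{m_max} via overflow-free Bessel ratio chains."""
    alpha = complex(alpha)
    R, dk = model.R, model.dk
    t_a = _k_ratios(alpha, m_max + 2)
    t_aR = _k_ratios(alpha * R, m_max + 2)
    u = (kve(0, alpha * R) / kve(0, alpha)) * np.exp(-alpha * (R - 1.0))
    out = np.empty(m_max + 1, dtype=complex)
    # K_m'(a)/K_m(a): -t_1 for m=0, -(1/t_m + t_{m+1})/2 for m >= 1
    out[0] = u / (1.0 + dk * alpha * t_a[1])
    for m in range(1, m_max + 1):
        u = u * t_aR[m] / t_a[m]
        kp_over_k = -0.5 * (1.0 / t_a[m] + t_a[m + 1])
        out[m] = u / (1.0 - dk * alpha * kp_over_k)
    return out


def _auto_m_modes(model: HomogenizedModel, times, tol: float = 1e-10,
                  n_nodes: int = 64) -> int:
    """Truncation so |chi_M/chi_0| < tol at the largest contributing |alpha|."""
    t_min = float(np.min(times))
    contour = TalbotContour.for_time(t_min, n_nodes=n_nodes)
    s_nodes, _ = contour.upper_nodes()
    # largest |alpha| among nodes that contribute at t_min
    keep = [s for s in s_nodes if (s * t_min).real >= -690.0]
    alpha = max((np.sqrt(s / model.D) for s in keep), key=abs) if keep else 1.0 + 0j
    m = 8
    while m < 100_000:
        chi = _chi_modes(alpha, model, m)
        if abs(chi[m]) < tol * max(abs(chi[0]), 1e-300):
            return m
        m *= 2
    raise TruncationError("mode series for the Robin flux did not converge")


def capture_cdf(t, model: HomogenizedModel, n_nodes: int = 64):
    """Fraction of particles captured by time t: L^-1[chi_0(alpha)/s]."""
    def transform(s):
        return _chi_modes(np.sqrt(s / model.D), model, 0)[0] / s
    return talbot_invert(transform, t, n_nodes=n_nodes)


def survival(t, model: HomogenizedModel, n_nodes: int = 64):
    """Probability a particle remains free at time t (1 - capture CDF)."""
    return 1.0 - np.asarray(capture_cdf(t, model, n_nodes=n_nodes))


def homogenized_flux_density(theta, t, model: HomogenizedModel,
                             m_modes: int | None = None,
                             n_nodes: int = 64) -> np.ndarray:
    """Surface flux density J(theta, t) of the Robin model.

    Inverts the cosine-mode series termwise; returns an array of shape
    ``(len(theta), len(t))`` (scalar axes squeezed).
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if m_modes is None:
        m_modes = _auto_m_modes(model, t_arr, n_nodes=n_nodes)
    modes = np.empty((m_modes + 1, t_arr.size))
    for q in range(m_modes + 1):
        def transform(s, q=q):
            return _chi_modes(np.sqrt(s / model.D), model, q)[q]
        modes[q] = np.atleast_1d(talbot_invert(transform, t_arr, n_nodes=n_nodes))
    weights = np.cos(
        np.outer(theta_arr - model.theta0, np.arange(1, m_modes + 1))
    ) / np.pi
    out = modes[0] / (2.0 * np.pi) + weights @ modes[1:]
    if np.ndim(theta) == 0 and np.ndim(t) == 0:
        return float(out[0, 0]) if out.ndim == 2 else float(out[0])
    return out


def mode_ratio(t, model: HomogenizedModel, n_nodes: int = 64):
    """Directional-information diagnostic L^-1[chi_1] / L^-1[chi_0].

    Decays to zero as the free-particle cloud loses memory of the source
    angle and the surface flux becomes radially symmetric.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))

    def tr0(s):
        return _chi_modes(np.sqrt(s / model.D), model, 0)[0]

    def tr1(s):
        return _chi_modes(np.sqrt(s / model.D), model, 1)[1]

    num = np.atleast_1d(talbot_invert(tr1, t_arr, n_nodes=n_nodes))
    den = np.atleast_1d(talbot_invert(tr0, t_arr, n_nodes=n_nodes))
    out = np.where(np.abs(den) < 1e-14, np.nan, num / np.where(den == 0, 1, den))
    return out if np.ndim(t) else float(out[0])


@dataclass(frozen=True)
class ShortTimeMoments:
    """Gaussian-regime moments of the angular flux density."""

    t: float
    M0: float
    variance: float
    kurtosis: float


def short_time_moments(t: float, model: HomogenizedModel) -> ShortTimeMoments:
    """Closed-form short-time moments of J(theta, t).

    Total flux (uniform in the relative size of kappa*t and R-1):

        M0(t) = kappa (R-1) exp(-(R-1)^2/(4Dt)) / (sqrt(pi D t R) (2 kappa t + R - 1))

    angular variance 2*D*t/R and kurtosis 3 (Gaussian).  Valid for
    D*t << 1 with D/kappa << 1; a warning is issued outside that regime.
    """
    R, D, kappa = model.R, model.D, model.kappa
    if D * t >= 1.0:
        warnings.warn(
            f"short-time moment formulas assume D*t << 1 (got D*t = {D * t:g})",
            RuntimeWarning,
        )
    if np.isinf(kappa):
        # Dirichlet limit of the uniform factor: kappa/(2 kappa t + R - 1) -> 1/(2t)
        m0 = (R - 1.0) * np.exp(-((R - 1.0) ** 2) / (4.0 * D * t)) / (
            2.0 * t * np.sqrt(np.pi * D * t * R)
        )
    else:
        m0 = (
            kappa
            * (R - 1.0)
            * np.exp(-((R - 1.0) ** 2) / (4.0 * D * t))
            / (np.sqrt(np.pi * D * t * R) * (2.0 * kappa * t + R - 1.0))
        )
    return ShortTimeMoments(t=t, M0=float(m0), variance=2.0 * D * t / R,
                            kurtosis=3.0)


def gaussian_approx(theta, t: float, model: HomogenizedModel):
    """Short-time Gaussian flux density M0 * N(theta0, 2Dt/R)."""
    mom = short_time_moments(t, model)
    sig2 = mom.variance
    theta_arr = np.asarray(theta, dtype=float)
    val = mom.M0 * np.exp(-((theta_arr - model.theta0) ** 2) / (2.0 * sig2)) / (
        np.sqrt(2.0 * np.pi * sig2)
    )
    return val if val.ndim else float(val)
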