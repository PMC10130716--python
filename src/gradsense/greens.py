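"""Green's functions for the exterior of the unit disc.

Two families are needed:

* the *surface* Green's function of the Laplacian with a reflecting (Neumann)
  boundary and a unit point flux at a boundary point ``xi``; on the unit disc
  it has the closed form ``G_s(x; xi) = -(1/pi) log|x - xi| + (1/2pi) log|x|``
  (fixed only up to an additive constant; we take the gauge constant C = 0,
  and every downstream splitting computation is gauge-invariant);

* Green's functions of the modified Helmholtz operator ``D*Lap - s`` (the
  Laplace-transformed diffusion equation, ``alpha = sqrt(s/D)``), both for a
  source on the boundary (Fourier--Bessel series in ``K_m``) and for a source
  in the bulk at radius ``R > 1``.

The boundary-source series has terms ``K_m(alpha)/(alpha K_m'(alpha)) + 1/m``
which decay only algebraically (like ``alpha^2/(2 m^3)``).  We accelerate it
by splitting off the uniform large-order approximation
``1/m - 1/sqrt(m^2 + alpha^2)``, whose cosine series has a closed form through
``-log(2 sin(|d|/2))`` and a rapidly convergent Poisson (Schloemilch) image
sum of ``K_0``; the remainder decays like ``m^{-4}`` and is summed directly.
All Bessel evaluations use overflow-free ratio recurrences, so arbitrarily
large orders and |alpha| are safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import kv, kve

__all__ = [
    "SingularEvaluationError",
    "TruncationError",
    "HelmholtzEvalParams",
    "laplace_surface_green",
    "laplace_surface_regular_part",
    "helmholtz_surface_green",
    "helmholtz_surface_regular_part",
    "helmholtz_bulk_green",
    "surface_green_matrix",
    "bulk_green_vector",
]

_EULER_GAMMA = 0.5772156649015328606


class SingularEvaluationError(ValueError):
    """Evaluation requested at the singular point of a Green's function."""


class TruncationError(RuntimeError):
    """A Fourier--Bessel series failed to meet its tail tolerance."""


# ----------------------------------------------------------------------
# static (Laplace) surface Green's function, gauge C = 0
# ----------------------------------------------------------------------

def laplace_surface_green(x, xi, gauge: float = 0.0):
    """Surface Green's function of the Laplacian, exterior unit disc.

    ``G_s(x; xi) = -(1/pi) log|x - xi| + (1/2pi) log|x| + gauge`` for a unit
    point flux at the boundary point ``xi`` (|xi| = 1) and reflecting boundary
    elsewhere.  ``x`` may be an (..., 2) array of exterior points.
    """
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    diff = np.linalg.norm(x - xi, axis=-1)
    if np.any(diff == 0.0):
        raise SingularEvaluationError("G_s is singular at x = xi")
    r = np.linalg.norm(x, axis=-1)
    val = -np.log(diff) / np.pi + np.log(r) / (2.0 * np.pi) + gauge
    return val if val.ndim else float(val)


def laplace_surface_regular_part(xi, gauge: float = 0.0) -> float:
    """Regular part R_s(xi) = lim_{x->xi} [G_s + (1/pi) log|x-xi|].

    On the unit circle the (1/2pi) log|x| term vanishes at the boundary, so
    R_s equals the gauge constant (0 by default).
    """
    xi = np.asarray(xi, dtype=float)
    return float(np.log(np.linalg.norm(xi, axis=-1)) / (2.0 * np.pi)) + gauge


# ----------------------------------------------------------------------
# modified Helmholtz machinery
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HelmholtzEvalParams:
    """Evaluation parameters for the transform-domain Green's functions.

    ``s`` is the (complex) Laplace variable, ``D`` the diffusivity;
    ``alpha = sqrt(s/D)`` uses the principal square root, so Re(alpha) > 0
    for any ``s`` off the negative real axis.  ``m_max`` caps the series
    order and ``tol`` is the absolute tail tolerance.
    """

    s: complex
    D: float = 1.0
    m_max: int = 200_000
    tol: float = 1e-12

    def __post_init__(self):
        if self.m_max < 1:
            raise ValueError("m_max must be >= 1")
        if self.D <= 0.0:
            raise ValueError("D must be positive")
        alpha = np.sqrt(complex(self.s) / self.D)
        if alpha.real <= 0.0:
            raise ValueError(
                f"s={self.s} lies on the negative real axis (Re(alpha) <= 0)"
            )
        object.__setattr__(self, "s", complex(self.s))

    @property
    def alpha(self) -> complex:
        return complex(np.sqrt(complex(self.s) / self.D))


def _k_ratios(z: complex, m_max: int) -> np.ndarray:
    """Ratios t[m] = K_m(z)/K_{m-1}(z) for m = 1..m_max (t[0] unused).

    Upward recurrence t_{m+1} = 2m/z + 1/t_m, stable for K and overflow-free.
    """
    t = np.empty(m_max + 1, dtype=complex)
    t[0] = np.nan
    t[1] = kve(1, z) / kve(0, z)
    for m in range(1, m_max):
        t[m + 1] = 2.0 * m / z + 1.0 / t[m]
    return t


def _k_over_zkprime(t: np.ndarray, z: complex, m: np.ndarray) -> np.ndarray:
    """K_m(z)/(z K_m'(z)) for m >= 1 from the ratio table ``t``.

    Uses K_m' = -(K_{m-1} + K_{m+1})/2.
    """
    return -2.0 / (z * (1.0 / t[m] + t[m + 1]))


def _poisson_k0_sum(delta: np.ndarray, alpha: complex) -> np.ndarray:
    """sum_{n in Z} K_0(alpha*|delta + 2*pi*n|) for delta in [-pi, pi].

    Image terms decay like exp(-2*pi*n*Re(alpha)); the loop runs until the
    last term is negligible (n ~ 1/Re(alpha) images for small alpha).
    """
    total = np.zeros(delta.shape, dtype=complex)
    n_cap = int(45.0 / (2.0 * np.pi * max(alpha.real, 1e-12))) + 3
    if n_cap > 200_000:
        raise TruncationError(
            f"Poisson image sum impractical at alpha={alpha} (Re alpha ~ 0)"
        )
    for n in range(n_cap + 1):
        if n == 0:
            term = kv(0, alpha * np.abs(delta))
        else:
            term = kv(0, alpha * np.abs(delta + 2.0 * np.pi * n)) + kv(
                0, alpha * np.abs(delta - 2.0 * np.pi * n)
            )
        total += term
        if np.max(np.abs(term)) < 1e-17:
            break
    return total


def _slow_series(delta: np.ndarray, alpha: complex) -> np.ndarray:
    """Closed form of sum_{m>=1} (1/m - 1/sqrt(m^2+alpha^2)) cos(m*delta).

    Equals -log(2 sin(|delta|/2)) - sum_n K_0(alpha |delta+2 pi n|) + 1/(2 alpha)
    for delta != 0 (mod 2 pi); the delta -> 0 limit is
    log(alpha/2) + gamma_e + 1/(2 alpha) - 2 sum_{n>=1} K_0(2 pi n alpha).
    """
    delta = np.mod(delta + np.pi, 2.0 * np.pi) - np.pi
    out = np.empty(delta.shape, dtype=complex)
    zero = np.abs(delta) < 1e-14
    if np.any(zero):
        img = 0.0
        n_cap = int(45.0 / (2.0 * np.pi * max(alpha.real, 1e-12))) + 3
        if n_cap > 200_000:
            raise TruncationError(
                f"Poisson image sum impractical at alpha={alpha}"
            )
        for n in range(1, n_cap + 1):
            term = kv(0, 2.0 * np.pi * n * alpha)
            img += term
            if abs(term) < 1e-17:
                break
        out[zero] = (
            np.log(alpha / 2.0) + _EULER_GAMMA + 0.5 / alpha - 2.0 * img
        )
    if np.any(~zero):
        d = delta[~zero]
        out[~zero] = (
            -np.log(2.0 * np.abs(np.sin(0.5 * d)))
            - _poisson_k0_sum(d, alpha)
            + 0.5 / alpha
        )
    return out


def _slow_series_2(delta: np.ndarray, alpha: complex) -> np.ndarray:
    """Closed form of (alpha^2/2) * sum_{m>=1} cos(m*delta)/(m^2+alpha^2)^2.

    Poisson summation with the Fourier transform of (x^2+a^2)^{-2}, which is
    (pi/(2 a^3)) (1 + a|w|) exp(-a|w|).
    """
    delta = np.mod(delta + np.pi, 2.0 * np.pi) - np.pi
    n_cap = int(45.0 / (2.0 * np.pi * max(alpha.real, 1e-12))) + 3
    if n_cap > 200_000:
        raise TruncationError(f"Poisson image sum impractical at alpha={alpha}")
    total = np.zeros(delta.shape, dtype=complex)
    pref = np.pi / (2.0 * alpha**3)
    for n in range(n_cap + 1):
        if n == 0:
            w = np.abs(delta)
            term = pref * (1.0 + alpha * w) * np.exp(-alpha * w)
        else:
            w1 = np.abs(delta + 2.0 * np.pi * n)
            w2 = np.abs(delta - 2.0 * np.pi * n)
            term = pref * ((1.0 + alpha * w1) * np.exp(-alpha * w1)
                           + (1.0 + alpha * w2) * np.exp(-alpha * w2))
        total += term
        if np.max(np.abs(term)) < 1e-17 * abs(pref):
            break
    return 0.5 * alpha**2 * (0.5 * (total - 1.0 / alpha**4))


def _bracket_series(delta: np.ndarray, params: HelmholtzEvalParams) -> np.ndarray:
    """sum_{m>=1} [K_m(a)/(a K_m'(a)) + 1/m] cos(m*delta) for a = alpha.

    Two orders of the uniform large-order asymptotics are split off in
    closed form: 1/m - 1/sqrt(m^2+a^2) (via :func:`_slow_series`) and
    a^2/(2 (m^2+a^2)^2) (via :func:`_slow_series_2`); the remainder decays
    like a^2/(2 m^5) and is truncated adaptively (floor m=50).
    """
    alpha = params.alpha
    abs_a = abs(alpha)
    delta = np.atleast_1d(np.asarray(delta, dtype=float))

    if abs_a < 0.05:
        # terms ~ alpha^2/(2 m^3): direct summation is cheap and avoids the
        # K_0 image sums, which need ~1/alpha terms at small alpha
        return _bracket_series_direct(delta, params)

    m_floor = max(50, int(2.0 * abs_a) + 10)
    m_guess = min(params.m_max, max(m_floor, int(4.0 * abs_a) + 200))
    t = _k_ratios(alpha, m_guess + 1)

    m_stop = None
    coeffs = []
    m = 1
    small_run = 0
    while m <= params.m_max:
        if m + 1 >= t.size:
            new_size = min(params.m_max + 2, 2 * t.size)
            t2 = np.empty(new_size, dtype=complex)
            t2[: t.size] = t
            for mm in range(t.size - 1, new_size - 1):
                t2[mm + 1] = 2.0 * mm / alpha + 1.0 / t2[mm]
            t = t2
        s2 = m * m + alpha * alpha
        c = (-2.0 / (alpha * (1.0 / t[m] + t[m + 1])) + 1.0 / np.sqrt(s2)
             - 0.5 * alpha * alpha / (s2 * s2))
        coeffs.append(c)
        # m^-5 decay => tail ~ |c_m| * m / 4
        if m >= m_floor and abs(c) * m / 4.0 < params.tol:
            small_run += 1
            if small_run >= 2:
                m_stop = m
                break
        else:
            small_run = 0
        m += 1
    if m_stop is None:
        raise TruncationError(
            f"surface Helmholtz series did not reach tol={params.tol} "
            f"within m_max={params.m_max} terms (alpha={alpha})"
        )
    c_arr = np.asarray(coeffs)
    m_arr = np.arange(1, m_stop + 1)
    fast = np.cos(np.outer(delta, m_arr)) @ c_arr
    return _slow_series(delta, alpha) + _slow_series_2(delta, alpha) + fast


def _bracket_series_direct(delta: np.ndarray,
                           params: HelmholtzEvalParams) -> np.ndarray:
    """Plain summation of the bracket series, efficient for small |alpha|."""
    alpha = params.alpha
    t = _k_ratios(alpha, 256)
    coeffs = []
    m = 1
    while m <= params.m_max:
        if m + 1 >= t.size:
            t2 = np.empty(min(params.m_max + 2, 2 * t.size), dtype=complex)
            t2[: t.size] = t
            for mm in range(t.size - 1, t2.size - 1):
                t2[mm + 1] = 2.0 * mm / alpha + 1.0 / t2[mm]
            t = t2
        b = -2.0 / (alpha * (1.0 / t[m] + t[m + 1])) + 1.0 / m
        coeffs.append(b)
        # m^-3 decay => tail ~ |b_m| * m / 2
        if m >= 50 and abs(b) * m / 2.0 < params.tol:
            break
        m += 1
    else:
        raise TruncationError(
            f"surface Helmholtz series (direct) did not converge, alpha={alpha}"
        )
    c_arr = np.asarray(coeffs)
    m_arr = np.arange(1, c_arr.size + 1)
    return np.cos(np.outer(delta, m_arr)) @ c_arr


def helmholtz_surface_regular_part(delta_theta, params: HelmholtzEvalParams):
    """Regular part R_h of the boundary-source Helmholtz Green's function.

    For boundary points separated by angle ``delta_theta``,

        R_h = (1/(pi D)) * [ -K_0(a)/(2 a K_0'(a))
                              - sum_{m>=1} (K_m(a)/(a K_m'(a)) + 1/m) cos(m d) ]

    with a = alpha.  Vectorized over ``delta_theta``.
    """
    alpha = params.alpha
    delta = np.atleast_1d(np.asarray(delta_theta, dtype=float))
    t1 = kve(1, alpha) / kve(0, alpha)
    # K_0/(a K_0') = -K_0/(a K_1) = -1/(a t_1)
    lead = 0.5 / (alpha * t1)
    out = (lead - _bracket_series(delta, params)) / (np.pi * params.D)
    return out if np.ndim(delta_theta) else complex(out[0])


def helmholtz_surface_green(theta, theta_p, params: HelmholtzEvalParams):
    """Boundary-source Helmholtz Green's function between boundary angles.

    ``G_h = -(1/(pi D)) log|x - xi| + R_h`` with ``|x - xi| = 2|sin(d/2)|``.
    Symmetric in its two angular arguments.
    """
    delta = np.atleast_1d(np.asarray(theta, dtype=float) - np.asarray(theta_p, float))
    chord = 2.0 * np.abs(np.sin(0.5 * delta))
    if np.any(chord == 0.0):
        raise SingularEvaluationError("G_h is singular at coincident points")
    out = -np.log(chord) / (np.pi * params.D) + helmholtz_surface_regular_part(
        delta, params
    )
    return out if np.ndim(theta) or np.ndim(theta_p) else complex(out[0])


def helmholtz_bulk_green(theta, R: float, theta0: float,
                         params: HelmholtzEvalParams):
    """Helmholtz Green's function, bulk source at radius R, evaluated on r=1.

        G_h(theta; R, theta0, s) = -(1/(2 pi D)) K_0(aR)/(a K_0'(a))
            - (1/(pi D)) sum_{m>=1} K_m(aR)/(a K_m'(a)) cos m(theta - theta0)

    Terms decay geometrically like R^{-m}; truncation is adaptive with the
    geometric tail bound.  Vectorized over ``theta``.
    """
    if not R > 1.0:
        raise ValueError(f"bulk source must satisfy R > 1, got R={R}")
    alpha = params.alpha
    D = params.D
    delta = np.atleast_1d(np.asarray(theta, dtype=float) - theta0)

    # u_m = K_m(alpha R)/K_m(alpha), built from ratio chains at both arguments
    u0 = (kve(0, alpha * R) / kve(0, alpha)) * np.exp(-alpha * (R - 1.0))
    m_guess = max(60, int(np.ceil(-np.log(max(params.tol, 1e-300)) / np.log(R))) + 20)
    m_guess = min(m_guess, params.m_max)
    tR = _k_ratios(alpha * R, m_guess + 1)
    ta = _k_ratios(alpha, m_guess + 1)

    lead = -u0 * (-1.0 / (alpha * (kve(1, alpha) / kve(0, alpha))))  # -K0(aR)/(aK0'(a))
    total = np.full(delta.shape, 0.5 * lead / (np.pi * D), dtype=complex)

    u = u0
    m = 1
    while m <= params.m_max:
        if m + 1 >= tR.size:
            new = min(params.m_max + 2, 2 * tR.size)
            tR2 = np.empty(new, complex); tR2[: tR.size] = tR
            ta2 = np.empty(new, complex); ta2[: ta.size] = ta
            for mm in range(tR.size - 1, new - 1):
                tR2[mm + 1] = 2.0 * mm / (alpha * R) + 1.0 / tR2[mm]
                ta2[mm + 1] = 2.0 * mm / alpha + 1.0 / ta2[mm]
            tR, ta = tR2, ta2
        u = u * tR[m] / ta[m]
        coef = u * (-2.0 / (alpha * (1.0 / ta[m] + ta[m + 1])))  # K_m(aR)/(a K_m'(a))
        term = -coef * np.cos(m * delta) / (np.pi * D)
        total += term
        # geometric tail bound: remaining sum < |coef| * (1/R) / (1 - 1/R)
        if abs(coef) / (R - 1.0) / (np.pi * D) < params.tol and m >= 10:
            break
        m += 1
    else:
        raise TruncationError(
            f"bulk Helmholtz series did not converge within m_max={params.m_max}"
        )
    return total if np.ndim(theta) else complex(total[0])


# ----------------------------------------------------------------------
# assembly helpers for the flux solver
# ----------------------------------------------------------------------

def surface_green_matrix(config, params: HelmholtzEvalParams) -> np.ndarray:
    """N x N matrix [G_h]_{ij} = G_h(x_i; x_j, s), diagonal R_h(x_i; s).

    Evaluates the regular-part series once per distinct angular separation.
    """
    ang = config.angles
    n = ang.size
    delta = ang[:, None] - ang[None, :]
    flat = delta.ravel()
    uniq, inv = np.unique(np.round(np.mod(np.abs(flat), 2.0 * np.pi), 14),
                          return_inverse=True)
    rh = helmholtz_surface_regular_part(uniq, params)
    mat = np.asarray(rh)[inv].reshape(n, n).astype(complex)
    off = ~np.eye(n, dtype=bool)
    chord = 2.0 * np.abs(np.sin(0.5 * delta[off]))
    mat[off] += -np.log(chord) / (np.pi * params.D)
    return mat


def bulk_green_vector(config, source, params: HelmholtzEvalParams) -> np.ndarray:
    """g0 vector: bulk Green's function from the source to each receptor."""
    return np.asarray(
        helmholtz_bulk_green(config.angles, source.R, source.theta0, params)
    )
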