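"""Receptor geometry on the unit circle.

A cell is the unit disc; ``N`` surface receptors are disjoint boundary arcs
with centres ``theta_k`` and arclengths ``extents[k]`` (the product of a small
parameter and an O(1) shape factor).  The strength of each small arc in the
2-D matched-asymptotic theory is its logarithmic capacitance
``nu_k = -1/log(extent_k/4)``.

All lengths are measured in units of the cell radius, which is fixed to 1;
user data must be pre-scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "ReceptorConfig",
    "SourceSpec",
    "CountTable",
    "receptor_capacitance",
    "build_config",
    "three_receptor_config",
    "uniform_config",
    "wrap_angle",
]


class InvalidGeometryError(ValueError):
    """Raised for receptor layouts the asymptotic theory cannot represent."""


def wrap_angle(theta):
    """Map angles to the convention (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    out = np.mod(-theta + np.pi, 2.0 * np.pi)
    out = np.pi - out
    return out if out.ndim else float(out)


def receptor_capacitance(extent):
    """Logarithmic capacitance nu = -1/log(extent/4) of a boundary arc.

    Parameters
    ----------
    extent : float or array_like
        Arclength of the receptor arc, 0 < extent < 4 (unit cell radius).

    Returns
    -------
    nu : float or ndarray
        Positive, strictly increasing in ``extent``; nu(4/e) = 1.
    """
    extent_arr = np.asarray(extent, dtype=float)
    if np.any(extent_arr <= 0.0) or np.any(extent_arr >= 4.0):
        raise InvalidGeometryError(
            f"receptor extent must lie in (0, 4), got {extent!r}"
        )
    nu = -1.0 / np.log(extent_arr / 4.0)
    return nu if nu.ndim else float(nu)


@dataclass(frozen=True)
class ReceptorConfig:
    """Disjoint receptor arcs on the boundary of the unit disc.

    Attributes
    ----------
    angles : ndarray
        Arc centres theta_k in (-pi, pi].
    extents : ndarray
        Arclengths of the arcs (each in (0, 4), summing to < 2*pi).
    nu : ndarray
        Logarithmic capacitances, derived from ``extents``.
    """

    angles: np.ndarray
    extents: np.ndarray
    nu: np.ndarray = field(default=None)
    cell_radius: float = 1.0

    def __post_init__(self):
        angles = wrap_angle(np.atleast_1d(np.asarray(self.angles, dtype=float)))
        extents = np.atleast_1d(np.asarray(self.extents, dtype=float))
        if angles.shape != extents.shape or angles.ndim != 1:
            raise InvalidGeometryError("angles and extents must be equal-length 1-D")
        if angles.size == 0:
            raise InvalidGeometryError("at least one receptor is required")
        if float(np.sum(extents)) >= 2.0 * np.pi:
            raise InvalidGeometryError("total receptor arclength must be < 2*pi")
        nu = np.asarray(receptor_capacitance(extents))
        _check_disjoint(angles, extents)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "extents", extents)
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "cell_radius", 1.0)

    @property
    def n_receptors(self) -> int:
        return self.angles.size

    @property
    def centers(self) -> np.ndarray:
        """Cartesian receptor centres x_k on the unit circle, shape (N, 2)."""
        return np.column_stack([np.cos(self.angles), np.sin(self.angles)])

    def arc_bounds(self) -> np.ndarray:
        """(N, 2) array of [lower, upper] angular endpoints (unwrapped)."""
        half = 0.5 * self.extents
        return np.column_stack([self.angles - half, self.angles + half])

    def locate(self, theta) -> np.ndarray:
        """Receptor index containing each boundary angle, or -1 if reflecting.

        Arc membership is closed; an angle on a shared endpoint goes to the
        lower-index receptor (deterministic simulator bookkeeping).
        """
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        out = np.full(theta.shape, -1, dtype=np.int64)
        for k in range(self.n_receptors - 1, -1, -1):
            delta = wrap_angle(theta - self.angles[k])
            inside = np.abs(delta) <= 0.5 * self.extents[k] + 1e-15
            out[inside] = k
        return out


def _check_disjoint(angles: np.ndarray, extents: np.ndarray) -> None:
    n = angles.size
    if n == 1:
        return
    order = np.argsort(angles)
    lo = angles[order] - 0.5 * extents[order]
    hi = angles[order] + 0.5 * extents[order]
    for i in range(n):
        j = (i + 1) % n
        gap = (lo[j] - hi[i]) if j > i else (lo[j] + 2.0 * np.pi - hi[i])
        if gap <= 0.0:
            raise InvalidGeometryError(
                f"receptor arcs {order[i]} and {order[j]} overlap on the circle"
            )


@dataclass(frozen=True)
class SourceSpec:
    """Point source of signalling molecules outside the cell.

    ``R`` is the radial distance of the source (> 1 in cell radii), ``theta0``
    its polar angle and ``D`` the molecular diffusivity (length^2/time).
    """

    R: float
    theta0: float = 0.0
    D: float = 1.0

    def __post_init__(self):
        if not self.R > 1.0:
            raise ValueError(f"source must lie outside the unit cell, got R={self.R}")
        if not self.D > 0.0:
            raise ValueError(f"diffusivity must be positive, got D={self.D}")
        object.__setattr__(self, "theta0", float(wrap_angle(self.theta0)))
        object.__setattr__(self, "R", float(self.R))
        object.__setattr__(self, "D", float(self.D))

    @property
    def position(self) -> np.ndarray:
        return self.R * np.array([np.cos(self.theta0), np.sin(self.theta0)])


@dataclass(frozen=True)
class CountTable:
    """Per-receptor arrival counts c_k observed up to time ``t``.

    ``total`` is the number of particles released; uncaptured particles make
    up the difference ``total - sum(counts)``.  ``t = inf`` denotes the
    eventual-capture (splitting probability) regime.
    """

    counts: np.ndarray
    total: int
    t: float = np.inf

    def __post_init__(self):
        counts = np.atleast_1d(np.asarray(self.counts, dtype=np.int64))
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() > self.total:
            raise ValueError("sum of counts exceeds the number of particles")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total", int(self.total))
        object.__setattr__(self, "t", float(self.t))

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.total


def build_config(angles, extents) -> ReceptorConfig:
    """Validated :class:`ReceptorConfig` from arc centres and arclengths."""
    return ReceptorConfig(angles=np.asarray(angles, float),
                          extents=np.asarray(extents, float))


def three_receptor_config(eps: float) -> ReceptorConfig:
    """Three-receptor validation layout.

    Centres at [pi/4, pi, 3pi/2] with arclengths eps*[pi/3, pi/3, 2pi/3]; a
    deliberately asymmetric minimal layout (N = 3 is the smallest receptor
    number that can triangulate a source).
    """
    angles = np.array([np.pi / 4.0, np.pi, 1.5 * np.pi])
    lc = np.array([np.pi / 3.0, np.pi / 3.0, 2.0 * np.pi / 3.0])
    return build_config(angles, eps * lc)


def uniform_config(N: int, eps: float, lc: float = 1.0) -> ReceptorConfig:
    """N equally spaced receptors of common arclength ``eps * lc``.

    Centres at theta_k = 2*pi*k/N, k = 1..N.  The boundary fraction covered
    is N*eps*lc/(2*pi).
    """
    k = np.arange(1, N + 1)
    return build_config(2.0 * np.pi * k / N, np.full(N, eps * lc))
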