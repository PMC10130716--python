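"""Independent numerical oracles used only by the test suite.

The modified-Helmholtz Green's functions are checked against brute-force
finite-difference solutions of the per-mode radial boundary-value problems.
These solves use no Bessel functions at all (plain second-order FD on the
radial ODE), so they are independent of the special-function route in the
package.
"""

import numpy as np
from scipy.linalg import solve_banded


def _fd_mode_solve(m, s, D, flux_at_wall, source_radius=None,
                   source_strength=0.0, n_grid=24_000):
    """Solve D(G'' + G'/r - m^2 G/r^2) - s G = rhs on [1, r_max].

    Boundary conditions: D*G'(1) = -flux_at_wall (one-sided, 2nd order) and
    G(r_max) = 0 with r_max chosen from the exponential/algebraic decay.
    A bulk point source of strength ``source_strength`` may be placed at
    ``source_radius`` (delta function collocated on the grid).
    """
    alpha = np.sqrt(s / D)
    scale = np.sqrt(abs(alpha) ** 2 + m * m)
    r_max = 1.0 + min(60.0 / max(scale.real if np.iscomplexobj(scale) else scale,
                                 1e-3), 80.0)
    if source_radius is not None:
        r_max = max(r_max, source_radius + 30.0 / max(float(np.real(alpha)), 0.5))
    r = np.linspace(1.0, r_max, n_grid)
    h = r[1] - r[0]
    ab = np.zeros((3, n_grid), dtype=complex)
    rhs = np.zeros(n_grid, dtype=complex)
    # interior rows
    i = np.arange(1, n_grid - 1)
    ab[0, i + 1] = D / h**2 + D / (2.0 * r[i] * h)      # superdiag
    ab[1, i] = -2.0 * D / h**2 - (m * m * D / r[i] ** 2 + s)
    ab[2, i - 1] = D / h**2 - D / (2.0 * r[i] * h)      # subdiag
    # wall flux condition: (-3G0 + 4G1 - G2)/(2h) = -flux/D
    # banded storage cannot hold G2 on row 0, so eliminate it using the
    # interior equation at i=1 written for G2.
    a2 = D / h**2 + D / (2.0 * r[1] * h)
    b1 = -2.0 * D / h**2 - (m * m * D / r[1] ** 2 + s)
    c0 = D / h**2 - D / (2.0 * r[1] * h)
    # G2 = (rhs1 - c0*G0 - b1*G1)/a2
    ab[1, 0] = -3.0 / (2.0 * h) - (1.0 / (2.0 * h)) * (-c0 / a2)
    ab[0, 1] = 4.0 / (2.0 * h) - (1.0 / (2.0 * h)) * (-b1 / a2)
    rhs[0] = -flux_at_wall / D
    # Dirichlet at r_max
    ab[1, -1] = 1.0
    rhs[-1] = 0.0
    if source_radius is not None:
        j = int(round((source_radius - 1.0) / h))
        rhs[j] += -source_strength / (r[j] * h)
    sol = solve_banded((1, 1), ab, rhs)
    return r, sol


def fd_surface_mode_value(m, s, D=1.0, n_grid=24_000):
    """G_m(1) for a boundary flux source: D G'(1) = -(1/2pi) or -(1/pi)."""
    coef = 1.0 / (2.0 * np.pi) if m == 0 else 1.0 / np.pi
    _, g = _fd_mode_solve(m, s, D, flux_at_wall=coef, n_grid=n_grid)
    return g[0]


def fd_surface_regular_part(delta, s, D=1.0, m_modes=70, n_grid=24_000):
    """R_h(delta) by FD mode solves: subtracts the log singularity mode-wise."""
    total = fd_surface_mode_value(0, s, D, n_grid)
    for m in range(1, m_modes + 1):
        gm = fd_surface_mode_value(m, s, D, n_grid)
        total += (gm - 1.0 / (np.pi * D * m)) * np.cos(m * delta)
    return total


def fd_bulk_green_value(theta, R, theta0, s, D=1.0, m_modes=40,
                        n_grid=24_000):
    """Bulk-source Green's function on the wall by FD mode solves."""
    total = 0.0 + 0.0j
    for m in range(m_modes + 1):
        coef = 1.0 / (2.0 * np.pi) if m == 0 else 1.0 / np.pi
        _, g = _fd_mode_solve(m, s, D, flux_at_wall=0.0, source_radius=R,
                              source_strength=coef, n_grid=n_grid)
        total += g[0] * np.cos(m * (theta - theta0))
    return total
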