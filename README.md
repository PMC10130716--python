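# gradsense

Tools for the upstream physics of cellular gradient sensing: how the
diffusive arrival of signalling molecules at membrane receptors encodes —
and eventually loses — information about the location of their source.

A cell is modelled as a reflecting unit disc whose boundary carries `N`
small absorbing arcs (receptors) with centres `θ_k` and arclengths `εℓ_k`.
Molecules are released at an exterior point `x₀ = R e^{iθ₀}` and diffuse
with diffusivity `D`.  The package computes, analytically where possible
and numerically otherwise:

* **Splitting probabilities** `φ_k(x)` — the chance the molecule is caught
  by receptor `k` first — via the "sums-of-logs" matched-asymptotic linear
  system built on the logarithmic capacitance `ν_k = −1/log(εℓ_k/4)` and
  the surface Green's function of the disc exterior.
* **Dynamic receptor fluxes** `J_k(t)`, cumulative captures and fractional
  signals `q_k(t) = ∫₀ᵗJ_k / ∫₀ᵗρ` — by solving the Laplace-transformed
  (modified Helmholtz) problem `(I + πD·G_h·V)A(s) = g₀` at complex
  frequencies and inverting on a Talbot contour.
* A **homogenized Robin surface**: for `N ≫ 1` equally spaced receptors the
  patchy boundary is equivalent to `D ∂p/∂n = κp` with
  `D/κ = −(2/N) log(εN/4)`, whose flux modes
  `χ_m(α) = K_m(αR)/(K_m(α) − (D/κ)αK_m′(α))` give survival curves,
  angular flux profiles, and the timescale at which directional
  information is erased.
* A **particle simulator** (exact harmonic-measure hopping for eventual
  counts; adaptive Euler–Maruyama with bridge corrections for
  time-resolved arrivals) used to validate all of the above and to
  generate noisy data for inference experiments.
* **Source localization**: multinomial maximum-likelihood landscapes over
  candidate source positions, algebraic triangulation from splitting
  probabilities (needs `N ≥ 3`), polar averaging of early arrivals, and
  extreme-value statistics of the very first arrival — Gumbel law
  `t_a ~ Gumbel(b_M, a_M)` and normal arrival angle with variance
  `σ²_θ = g(R)/W_M`, `g(R) = (R−1)²/(3R)`, `W_M` a Lambert-W value.

## Worked example

```python
import numpy as np
from gradsense import (three_receptor_config, SourceSpec, solve_static,
                       splitting_probability, flux_time_series)

cell = three_receptor_config(eps=0.1)       # receptors at pi/4, pi, -pi/2
source = SourceSpec(R=2.0, theta0=0.0, D=1.0)

phi = splitting_probability(np.array([2.0, 0.0]), solve_static(cell))
print(np.round(phi, 4))
# [0.4143 0.2246 0.361 ]

fs = flux_time_series(cell, source, [1.0, 10.0, 1e3])
print(np.round(fs.C, 4))
# [0.0706 0.2845 0.5674]
```

The first line says a molecule released at distance 2 in front of the cell
ends up at the front receptor 41% of the time — far from the 1/3 split
that would hold for vanishing receptors, which is why finite receptor size
is essential for 2-D source inference.  The capture fractions show how
slowly the counts equilibrate: after `t = 10³` (in cell-radius² / D units)
only 57% of molecules have been captured.

The same objects drive the command line, e.g.

```bash
gradsense homog --n 100 --eps 0.0314159265 --r 5 --times 10:10000:25 -o homog.csv
gradsense repro-table1 --seed 7 -m 10000
```

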