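# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Model and geometry

The cell is the closed unit disc; all lengths are in units of the cell
radius and times in units of radius²/diffusivity unless stated.  The
boundary carries `N` disjoint absorbing arcs (receptors) of arclength
`εℓ_k` centred at angles `θ_k ∈ (−π, π]`; the rest of the boundary
reflects.  Molecules perform planar Brownian motion with diffusivity `D`
from a point source at distance `R > 1`.  Planar diffusion is recurrent,
so every molecule is captured eventually, but the *mean* capture time is
infinite — all time-resolved quantities equilibrate logarithmically, which
is a recurring theme below.

Arc membership is closed, with ties at shared endpoints resolved to the
lower-index receptor, so simulator bookkeeping is deterministic.

## Static splitting probabilities

The small-receptor limit is singular in 2-D: each receptor enters the
outer problem only through its logarithmic capacitance
`ν_k = −1/log(εℓ_k/4)`, and naive expansions in `1/|log ε|` converge too
slowly to be useful.  We therefore solve the "sums-of-logs" system, which
is accurate to all orders in `1/|log ε|` simultaneously: an
`(N+1)×(N+1)` linear system for the strengths `A_jk` and the far-field
constants `φ̄_k`, assembled from the surface Green's function of the
Laplacian in the disc exterior,

    G_s(x; ξ) = −(1/π) log|x − ξ| + (1/2π) log|x| + C.

`G_s` is defined only up to the constant `C`; we fix the gauge `C = 0`.
The no-monopole constraint `Σ_j ν_j A_jk = 0` makes every observable
gauge-invariant, which the tests verify for `C ∈ {−5, 1, 100}`.  The
closed form itself is verified in the tests by finite differences
(harmonicity, reflecting boundary, unit flux through a half-circle at the
source point).  The operator is factorized once and reused for all `N`
right-hand sides.

Accuracy is `O(ε)` beyond the log orders: against an ε-exact spectral
reference (below), the three-receptor validation cell has max error
3×10⁻³ at `ε = 0.3` shrinking monotonically to 6×10⁻⁴ at `ε = 0.05`.

## Transform-domain fluxes and Talbot inversion

Laplace transforming the diffusion problem yields a modified Helmholtz
problem with `α = sqrt(s/D)` (principal branch, so `Re α > 0` off the
negative real axis).  The receptor strengths solve
`(I + πD·G_h·V) A(s) = g₀`, with the boundary-source Green's function

    G_h = −(1/πD) log|x−ξ| + R_h,
    R_h = (1/πD) [ −K₀(α)/(2αK₀′(α)) − Σ_m (K_m(α)/(αK_m′(α)) + 1/m) cos mΔ ],

and a bulk-source analogue whose terms decay geometrically like `R^{−m}`.
Numerical choices:

* All Bessel factors are computed from the ratio recurrence
  `t_{m+1} = 2m/α + 1/t_m`, `t_1 = K₁/K₀` (via scaled `kve`), so no
  overflow occurs at any order or argument.
* The `R_h` series decays only like `α²/(2m³)`.  Two orders of the uniform
  large-order asymptotics are split off in closed form — the brackets equal
  `(1/m − 1/√(m²+α²)) + α²/(2(m²+α²)²) + O(α²/m⁵)` — using
  `Σ cos(mΔ)/m = −log(2 sin|Δ|/2)` and Poisson (Schlömilch) image sums of
  `K₀` and of `(π/2α³)(1+α|ω|)e^{−α|ω|}`.  The residual series is summed
  to an adaptive tail bound (absolute tolerance 10⁻¹², floor 50 terms);
  for very small `|α| < 0.05` plain summation is cheaper and used instead.
  The split was validated against 30-digit brute-force summation.
* The implementation is cross-checked in the tests against a Bessel-free
  finite-difference solve of the per-mode radial two-point boundary value
  problems (agreement ≲ 10⁻⁵).

Time-domain quantities use the Talbot contour
`s(θ) = μ(θ cot θ + iβθ)`, midpoint rule over 64 nodes (32 evaluated, the
rest by conjugate symmetry), with `μ = 0.15·64/t` and `β = 0.9`.  The
constants were fixed once against transforms with known originals
(`1/s`, `1/(s+1)`, `1/√s`, `e^{−√s}`, `1/(s+1)²` over `t ∈ [10⁻², 10⁶]`,
worst relative error 2.8×10⁻⁹).  Nodes whose weight `e^{st}` underflows
contribute exactly zero and are skipped; deep-tail nodes relax the series
tolerance in proportion to their weight.  Inside `flux_time_series`,
times are grouped per half-decade and share one contour anchored at the
group's largest time (accuracy degrades for `μt` above, not below, the
calibrated value), so the linear solves are done once per node.

Cumulative captures invert `Ĵ_k(s)/s` directly rather than integrating
`J_k(t)`, avoiding quadrature error from the short-time spike.  Fractional
signals `q_k` at times where the capture fraction is numerically zero are
reported as `1/N` and flagged (`q_degenerate`); times below the squared
receptor extent are flagged as outside the boundary-layer asymptotic
regime (`ε²s ≪ 1`), not suppressed.

Tiny negative cumulative values (inversion noise within 10⁻⁶) are clipped
to zero after an explicit tolerance check.

## Homogenization

For `N` equally spaced receptors of common extent the patchy boundary is
replaced by the Robin condition `D ∂p/∂n = κp` with
`D/κ = −(2/N) log(εN/4)`, valid while `εN < 4`.  The surface-flux
transform is the cosine-mode series in
`χ_m(α) = K_m(αR)/(K_m(α) − (D/κ)αK_m′(α))`, evaluated with the same
ratio recurrences.  Mode truncation stops when `|χ_M/χ₀|` falls below
10⁻¹⁰ at the largest contributing contour `|α|`.

The discrete→Robin convergence is kept as a test: for uniform cells at
fixed coverage, the discrete Fourier coefficients
`χ̄_q = πDν Σ_j A_j(s) cos q(θ_j−θ₀)` of the strength vector approach
`χ_q(α)` as `N` doubles from 16 to 128, and the sine parts vanish.

Short times (`ε ≪ √(Dt) ≪ 1`) admit a moment description: total flux

    M₀(t) = κ(R−1) e^{−(R−1)²/4Dt} / ( √(πDtR) (2κt + R − 1) ),

angular variance `2Dt/R`, kurtosis `3` — an angular Gaussian centred on
the source direction.  The printed variance is the only reading consistent
with the first-arrival angle variance `g(R)/W_M` below.  Comparing `M₀`
with the numerically inverted `χ₀` is only meaningful where the original
is representable: at `Dt ≤ 10⁻³` the value is below ~10⁻¹⁰⁰ and *no*
Talbot quadrature (double precision or 80-digit mpmath) can reach the
`e^{−B/t}` saddle; the tests compare at `Dt ∈ {4·10⁻³, 10⁻², 2·10⁻²}`
(agreement ≤ 5%, dominated by the `O(Dt)` truncation of the expansion).

A note on one published number: for the half-covered 100-receptor cell
(`κ = 206.98`, `R = 5`), the capture CDF at `t = 10³` is 0.5955 — about
60% *captured*, 40% free.  This is confirmed independently by an ε-exact
collocation solve of the mixed transform problem and by brute-force Monte
Carlo; descriptions placing ~60% of particles still free at that time
swap the two fractions, and the package reports the computed value.

## Particle simulator

Two modes, sharing one PCG64 generator per seed (bit-identical reruns):

* *Time-free splitting*: the first boundary hit from any exterior point
  follows the Poisson kernel (wrapped Cauchy with `ρ = 1/r`), sampled by
  inverse CDF — exact.  Hits on reflecting gaps re-inject the particle a
  distance `min(gap/2, 0.0025)` off the wall and resample.  The only bias
  is this re-injection offset; at the default cap it is below the Monte
  Carlo noise of 2×10⁵-particle runs when compared against the spectral
  reference.
* *Time-resolved arrivals*: adaptive Euler–Maruyama with step rule
  `√(2D·dt) = distance/5` (distance to the wall and, near it, to the
  nearest arc edge), floor `dt = 10⁻⁶`, exact mirror reflection at the
  crossing point, and a Brownian-bridge touch correction
  `p = exp(−d₀d₁/(D·dt))` for steps that stay outside.  Defaults were
  fixed once against the ε-exact collocation solution (capture-fraction
  bias below the binomial noise of 10⁴-particle runs) and, for the
  all-absorbing cell, against the exact transform `K₀(αR)/(sK₀(α))`.
  Statistics living on timescales shorter than the geometric step rule
  resolves (e.g. minima over 10⁴ walkers) need the explicit `max_dt`
  bound; the Gumbel tests use `max_dt = horizon/150`.
* Censoring at `T_max` is flagged, never dropped; the mean arrival time is
  infinite, so a horizon is mandatory.

What the simulator does *not* emulate: receptor binding/unbinding
kinetics, receptor mobility, crowding, or any downstream signalling —
agreement of tests with theory shows the solvers and the sampler describe
the same idealized diffusion problem, not that real chemotaxis data will
match either.

## Inference layer

The likelihood landscape is the multinomial negative log-likelihood
`L(x) = −Σ_k c_k log q_k(x;t)`; we *minimize* `L` (equivalently maximize
the likelihood — sources describing the estimator as an arg max of `L`
conflict with their own use of the minimum).  Candidate sources are
scanned on a log-radial grid (`r ∈ [1.05, 40]`, 64 radii × 256 angles by
default — landscapes are radially elongated) and refined with Nelder–Mead
in `(log r, θ)`.  For finite `t` the `q` evaluation reuses one LU
factorization per Talbot node and solves for all grid points at once;
grid evaluation additionally factorizes the radius/angle structure into
two small matrix products per node.  Grid points where some `q_k = 0`
meets `c_k > 0` are excluded (infinite `L`) rather than clamped.

Triangulation solves the same geometry algebraically: least squares of
`c_k/M` against `φ*_k(x)`, identifiable for `N ≥ 3`.

Polar averaging uses the circular mean (atan2 of summed unit vectors) of
receptor angles per batch of `M_s` sorted arrivals.  The literal
arithmetic count-weighted sum is ill-defined across the ±π cut; for
sources near angle zero the two coincide.  A trailing partial batch is
flagged.  Uniformity of late batches is scored by a one-sample KS test
against Uniform(−π, π] with the asymptotic p-value (tested against a
10⁴-draw resampling null within 0.02 at n = 1001).

### Extreme arrivals

With short-time survival `1 − P(t) ~ A t^q e^{−B/t}`, the minimum of `M`
independent arrival times is asymptotically Gumbel with

    b_M = B/(q W_M),  a_M = b_M/(q(1+W_M)),  W_M = W((B/q)(AM)^{1/q}),

`W` the principal Lambert-W branch.  For the Robin cell, integrating
`M₀(t)` gives `q = 3/2`, `A = 4κ√(D/πR)/(R−1)²`, `B = (R−1)²/4D`; for the
perfectly absorbing cell (`κ = ∞`) the same integration gives `q = 1/2`,
`A = 2√(D/πR)/(R−1)`, which is what the all-absorbing simulation
experiments require.  The first-arrival angle is asymptotically normal
about the source direction with variance `2Db_M/R`; for the Robin
constants this is exactly `g(R)/W_M` with `g(R) = (R−1)²/(3R)` (the
consistent placement of `g` inside the Lambert-W argument is
`W([2κ²M²g(R)/(9πD²)]^{1/3})`, which makes it the same `W_M` as above).
The Laplace-method constant `√(2π)/e ≈ 0.922` arising in the angle
density is normalized to unity; the unnormalized value is exposed by the
constant itself in the tests.

At `M = 10⁴` the Gumbel location/scale ratio is ~13%, so the asymptotics
are visibly approximate: the exact minimum CDF (from `(1−F)^M` with the
exact single-arrival `F`) differs from the Gumbel fit by KS distance
≈ 0.06.  The simulation tests therefore use 100 replicates (KS critical
value 0.136 at 5%), which is the scale at which the theory is the correct
description of honest simulations.

## Problem sizes used in the tests

Chosen to exercise each claim at the precision the assertions need: one
shared 10⁴-particle time-resolved table and one 10⁴-particle splitting
run for the three-receptor cell; 10⁵ draws for the harmonic-measure χ²
test; 100×10⁴ walkers for the Gumbel minima; 1000×10⁴ walkers for the
first-arrival angle variance and kurtosis; discrete→Robin convergence up
to `N = 128`; spectral-reference sweeps down to `ε = 0.05`.

## Known limitations

* All asymptotics assume well-separated receptors on a unit circle;
  non-circular cells and the half-plane geometry are out of scope.
* The flux solver is `O(ε)` accurate; it is not a substitute for the
  collocation reference at large `ε`.
* Fluxes at `t = O(ε²)` are outside the boundary-layer regime and only
  flagged, not corrected.
* The homogenization formula applies to equally spaced, equal receptors.
* Equilibration of `q_k(t)` to the splitting probabilities is
  logarithmic; at `t = 10⁶` the residual is still ~3×10⁻² for the
  validation cell, and tests assert the monotone trend rather than an
  unreachable tolerance.
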