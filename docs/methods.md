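# Methods

This note records the model conventions, numerical schemes, default
parameters and design choices behind `infolength`, and what the test suite
does and does not establish.

## Model and conventions

All densities are one-dimensional with k_B = 1. A Gaussian state is
parameterized by its mean y and inverse temperature β, with variance
σ² = 1/(2β); β_s = γ/(2D) is the stationary inverse temperature of the
Ornstein–Uhlenbeck (O-U) process dx/dt = −γ(t)(x − v(t)) + ξ,
⟨ξξ′⟩ = 2D(t)δ. The confining potential is V = γ(x − v)²/2, so D plays the
role of an effective bath temperature.

The information rate is computed in the amplitude form
Γ² = 4∫(∂t√p)² dx rather than ∫(∂tp)²/p dx: the two are identical for
positive densities, but the amplitude form stays finite where p → 0 and
needs no density floor in the tails. The squared-L² convention is canonical
for `l2_distance` (the rooted variant is exposed separately); the
Kullback–Leibler divergence returns an explicit `inf` when the first
density has support where the second vanishes (absolute floor 1e-300
distinguishing true zeros from underflow), and tiny negative quadrature
results (> −1e-10) are clamped to zero since Gibbs' inequality guarantees
K ≥ 0. The Wootters inner product is clipped to [0, 1] before the arccos.

## Quadrature and differentiation

All spatial integrals use the composite trapezoid rule on a uniform grid;
all time derivatives of sampled series use second-order central differences
with second-order one-sided stencils at the ends. Sampled trajectories must
have a time step uniform to 1%, which keeps the stencil's convergence order
predictable; the Γ stencil is verified to be second order (halving Δt moves
Γ by < 0.3%). Default grids place 2048 nodes over ±8σ of every state they
must cover, which keeps Gaussian tail-truncation errors below 1e-10.

## Exact O-U propagation

Constant-coefficient cases use the closed forms for y(t) and σ²(t)
(exponential relaxation of the mean toward v, of the variance toward D/γ;
for a ramp v = ut the mean approaches ut − u/γ). Time-dependent γ(t), D(t),
v(t) are handled by integrating the exact first/second-moment ODEs
ẏ = −γ(y − v), dσ²/dt = −2γσ² + 2D with DOP853 at rtol 1e-11 — these ODEs
are equivalent to the decay-kernel quadrature formulas, and the unit tests
check them against independent Gauss–Kronrod quadrature of those kernels to
1e-8. The same ODE identities supply exact derivatives (ẏ, σ̇) at any
propagated state, which the closed-form Γ and thermodynamic series use so
that no finite-difference noise enters the analytic route.

## Fokker–Planck solver

Conservative finite-volume discretization in flux form with
exponentially-fitted (Chang–Cooper) face weights and Crank–Nicolson time
stepping; boundaries are zero-flux (reflecting). The face weight of the
upstream node is δ(w) = 1 + 1/(e^w − 1) − 1/w with w = fΔx/D (series
½ + w/12 for small w, upwind limits for |w| → ∞). This choice makes the
discrete zero-flux state satisfy p_{i+1}/p_i = e^w exactly, and since the
O-U drift is linear, the discrete stationary state coincides with the exact
Gaussian at the nodes: the equilibrium fixed-point test holds at 1e-14. The
scheme conserves the discrete node mass to round-off by construction
(column sums of the generator vanish), is second order in Δx and Δt, and
clips negative excursions below −1e-12 only after raising if they exceed
−1e-9 (naming the offending step size). On the default relaxation scenario
the dominant error is spatial: ~3e-4 relative in the variance at 2048
nodes, ~7e-5 at 4096 nodes; oracle-triangle comparisons therefore run at
4096 nodes. The probability current J = fp − D∂ₓp is diagnosed with central
differences, whose own O(Δx²) floor (~1e-6 at 8192 nodes) dominates the
equilibrium |J| checks.

The dichotomous two-component system solves two such equations coupled by a
symmetric exchange term r(P₂ − P₁) in a single Crank–Nicolson step on an
interleaved pentadiagonal system; each component's mass (½ each, the
symmetric configuration) is conserved to round-off, and with equal drifts
the total P₁+P₂ reproduces the analytic O-U mixture.

## Monte Carlo

Euler–Maruyama with fixed step dt = min(1e-3, 0.01/γ_max) and per-step
noise variance 2D·dt, seeded through `numpy.random.default_rng([seed, 0])`
for bit-reproducibility. The O(dt) weak bias of the scheme (~5e-4 relative
on the mean over a few relaxation times) is well inside the 4-standard-error
bands used for comparisons at the default ensemble size of 1e5 paths.

## Thermodynamic pipeline

The numeric route takes grid snapshots plus the generating drift/diffusion:
Ṡ_T = ∫J²/(Dp) (integrand evaluated only where p > 1e-14), Ṡ_m = ∫Jf/D,
Q̇ = ∫Jf, U = ⟨V⟩, Ẇ = ⟨∂tV⟩, with closure residuals Ṡ = Ṡ_T − Ṡ_m and
U̇ = Ẇ − Q̇ monitored (< 1e-6 and < 1e-5 on the reference runs). F = U − DS
treats the constant D as the effective temperature; a time-varying D makes
F ill-defined in this convention, so the free-energy outputs raise rather
than silently misreport. The stationary reference p_s is the
frozen-parameter Gaussian centered on v(t) with β_s; its free energy F_s is
constant whenever β_s is (the convention adopted for the irreversible-work
rate Ẇ_irr = DṠ_T + D·dK/dt), and the identity F − F_s = D·K[p|p_s] closes
to 1e-8 on grid trajectories.

## Geodesics and control

The information metric of the Gaussian family, Γ²dt² = (ẏ² + 2σ̇²)/σ² dt²,
equals twice the Poincaré upper-half-plane metric in (z, σ) = (y/√2, σ).
Geodesics are solved constructively, not by root-finding: endpoints map to
the half-plane, the unique circle centered on the real axis through both
points gives the center z_c and radius R, the hyperbolic length gives
L = √2·arccosh[1 + (Δz² + Δσ²)/(2σ₀σ_F)] and the constant rate Γ = L/T,
and the solution constants follow as α = 2Γ², |c| = Γ/(2R) with the sign of
Δz, and the apex time A from the boundary condition. The parametrization is
σ = R sech θ, z = z_c + sR tanh θ, θ = (Γ/√2)(t − A); hyperbolic arc length
equals Δθ, which makes endpoint matching and constant speed automatic. A
displacement |Δz|/max(√α, 1) < 1e-12 switches to the vertical branch
β(t) = β₀e^(±√α t) (pure variance change, L = √2|ln(σ_F/σ₀)|); identical
endpoints return a flagged zero-length solution. All four structural
invariants (βẏ = c, the β̇² ODE, constant Γ, the circle equation) are
asserted at ~1e-10 in the tests rather than assumed.

Controls at constant γ invert the moment dynamics: v = y + ẏ/γ,
D = γσ² + σσ̇. Feasibility requires D ≥ 0, i.e. γ ≥ max_t(−σ̇/σ); an
infeasible request raises with that threshold. The reference control
scenario uses endpoints y: 0 → 2 with β₀ = β_F ∈ {0.3, 3} over T = 3 at
γ = 1 — T is a free choice of the experiment, and T = 3 keeps the narrow
(β₀ = 3) protocol safely inside the feasibility region (at T = 2 it would
require γ > 1.14). Variational minimality is checked against 200 random
smooth endpoint-preserving sine-mode perturbations (amplitude 0.05) and a
time-reparametrized traversal, which keeps L but raises ∫Γ²dt — the
Cauchy–Schwarz equality case singling out constant speed.

## Coordinate invariance

Γ is invariant under strictly monotone time-independent transforms
y = h(x). The check builds p_y = p_x(h⁻¹(y))/|h′| on a uniform y-grid
(h inverted by dense monotone interpolation) and recomputes Γ from local
amplitude triplets with half-width dt = 1e-3. Because a strongly nonlinear
h stretches the support very non-uniformly, the y-grid uses 65536 nodes so
the narrowest image of the density stays resolved; with analytic Gaussian
snapshots the cubic transform h = x + x³ then agrees to ~4e-10, far inside
the 1% tolerance asserted.

## Scenario defaults (the study conditions)

- Default relaxation: γ = 1, D = 0.5, x₀ = 5, β₀ = 0.3, grid
  [−10, 15] × 2048, Δt = 1e-3, window [0, 5].
- Driven suite: γ = 1, D = 0.5, ramp u = 1, equilibrium start
  (β₀ = β_s = 1); values read at t = ln 2, limits at t = 20.
- Relaxation sweep: x₀ ∈ {1,…,10} with equilibrium initial variance, so
  L_∞ = x₀/σ_s exactly and the fitted slope times σ_s is the headline
  number.
- Dichotomous sweep: γ = 1, D = 0.5, switching rate r = 1,
  x₀ ∈ {1,…,8}, both components at equilibrium variance, 1536-node grid,
  horizon T = 10 with 0.01 output steps. r and the horizon are not pinned
  by theory; r = 1 (comparable to γ) produces strong inter-component
  correlation, which is the regime the qualitative signature describes.
- Monte Carlo: 1e5 paths for the oracle triangle.

## What the synthetic data do and do not show

Every test input is generated from the model itself (Gaussian initial
conditions, known drifts); passing tests therefore demonstrate the
correctness and internal consistency of the estimators and solvers under
exactly known ground truth. They do not address estimation of p(x, t) from
finite observational samples (kernel/histogram bias, boundary effects),
non-Gaussian or multimodal families beyond what the Fokker–Planck solver
produces, multivariate state spaces, or underdamped dynamics — all outside
the package's scope. The histogram densities produced by the Monte-Carlo
route are suitable for moment comparisons, not for feeding the Γ estimator
at small Δt (shot noise in ∂t√p grows as 1/(Δt√n)).

## Known limitations

- The Fokker–Planck solver assumes the density is negligible (< ~1e-12) at
  the domain boundary; reflecting walls otherwise bias the solution (a
  warning fires on a bad initial condition).
- Γ from sampled snapshots needs Δt well below 1/Γ; the default 1e-3 gives
  0.5%-level fidelity for rates up to ~4 in the reference scenarios.
- The free-energy block requires constant D by design.
- Control synthesis is validated for constant γ only; time-varying γ is
  accepted by the propagator but no geodesic controller is provided for it.
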