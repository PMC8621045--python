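# infolength

Information geometry for time-dependent stochastic processes: how far, in
units of statistical distinguishability, does a probability density travel as
it evolves — and what does that distance cost thermodynamically?

The package is aimed at researchers studying non-equilibrium dynamics
(relaxation, driven systems, self-organization, population control) who work
with time-dependent probability density functions p(x, t), whether produced
by a model or inferred from data.

## The quantities at the core

For an evolving density p(x, t), the **information rate**

    Γ(t)² = ∫ dx p(x,t) (∂t ln p(x,t))² = 4 ∫ dx (∂t √p)²

is the root-mean-square rate of change of the log-density; 1/Γ is the
characteristic time on which the distribution becomes statistically
distinguishable from itself. Its time integral, the **information length**

    L(t) = ∫₀ᵗ Γ(t′) dt′,

counts the number of distinguishable states traversed. Unlike any two-PDF
distance (Wootters angle, Kullback–Leibler divergence, Jensen divergence,
L² norm — all provided), L is *path-dependent*: it knows what happened in
between. For small time steps, 2K[p(t+dt)|p(t)]/dt² → Γ², which connects L
to the Fisher–Rao metric; Γ is invariant under time-independent changes of
variables, and fluctuation-normalized parameter velocities are bounded by Γ
(Cramér–Rao-type bounds).

The workhorse model is the non-autonomous Ornstein–Uhlenbeck process

    dx/dt = −γ(t) (x − v(t)) + ξ,   ⟨ξ(t)ξ(t′)⟩ = 2 D(t) δ(t−t′),

which keeps a Gaussian density Gaussian, with mean y(t) and inverse
temperature β(t) = 1/(2σ²) obeying closed-form dynamics. For this family

    Γ² = 2β ẏ² + β̇²/(2β²) = (ẏ² + 2σ̇²)/σ².

Three independent routes to trajectories — the exact Gaussian propagator, a
conservative Chang–Cooper/Crank–Nicolson Fokker–Planck solver, and an
Euler–Maruyama Monte-Carlo ensemble — cross-check each other, plus a
two-component system coupled by dichotomous (telegraph) switching.

The thermodynamics module ties Γ to the entropy budget: the entropy
production rate Ṡ_T = ∫ J²/(Dp) dx (J = fp − D∂ₓp the probability current),
entropy flow, heat Q̇, work Ẇ, the non-equilibrium free energy F = U − DS,
the dissipated power Ẇ_D = DṠ_T ≥ 0, and the relative entropy K[p|p_s] to
the frozen stationary state with D·K = F − F_s. The exact split
Γ² = (D/σ²)Ṡ_T + Ṡ² and the Schwartz-inequality bounds on Ṡ, Q̇ and Ṡ_T are
verified numerically in the test suite.

Finally, the geodesic module finds minimum-L paths between Gaussian states.
In coordinates (z, σ) = (y/√2, σ) the information metric is twice the
Poincaré upper-half-plane metric, so geodesics are circular arcs centered on
the σ = 0 axis traversed at constant Γ, with

    L_geo = √2 · arccosh[1 + (Δz² + Δσ²)/(2σ₀σ_F)].

Given a fixed damping γ, the controls D(t) = γσ² + σσ̇ and v(t) = y + ẏ/γ
drive the O-U process exactly along the geodesic — an optimal protocol in
the sense of least accumulated statistical change.

## Worked example

```python
import numpy as np
from infolength import *

spec  = ProcessSpec(gamma=1.0, D=0.5)      # O-U relaxation toward x = 0
init  = GaussianState(5.0, 0.3)            # displaced, broad initial Gaussian
grid  = Grid1D(-10, 15, 2048)
times = np.linspace(0.0, 5.0, 5001)

traj = PDFTrajectory.from_states(ou_propagate(spec, init, times), grid)
info = information_rate_numeric(traj)
print(f"Gamma(0)  = {info.gamma[0]:.4f} 1/time")
print(f"L(5)      = {info.L_final:.4f}")

ser = thermo_numeric(traj, spec)
print(f"peak entropy production = {ser.ST_dot.max():.4f}")

sol = solve_geodesic(GeodesicBC(0.0, 0.5, 2.0, 0.5, 0.0, 1.0))
print(f"geodesic: L = {sol.L:.6f}, Gamma = {sol.Gamma:.6f}, R = {sol.R:.6f}")
```

prints

```
Gamma(0)  = 3.9975 1/time
L(5)      = 5.6330
peak entropy production = 51.6333
geodesic: L = 1.862460, Gamma = 1.862460, R = 1.224745
```

Reading: the relaxing density initially moves at ~4 distinguishable states
per unit time and traverses ~5.6 states in total before settling into the
stationary density (L saturates because Γ → 0). The strongly displaced start
dissipates heavily at first (Ṡ_T(0) = (ẏ² + σ̇²)/D ≈ 51.6). Moving a unit
Gaussian two standard deviations at fixed width along a geodesic costs
L = √2·arccosh(2) ≈ 1.8625, traversed on a half-plane circle of radius
√(3/2) at constant rate.

A command-line interface mirrors the library:

```bash
infolength simulate --model ou --config cfg.yaml --out traj.csv
infolength info-length --input traj.csv --output info.csv
infolength distances --p1 a.csv --p2 b.csv
infolength thermo --traj traj.csv --config cfg.yaml --out thermo.csv
infolength geodesic --y0 0 --beta0 0.5 --yf 2 --betaf 0.5 --tf 1 --out sol.json
infolength scenario fig1_relaxation --out-dir out/
```

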