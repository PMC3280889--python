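# Methods

## The model

`nfdelay` analyses neural field equations with space-dependent propagation
delays,

    dV_i/dt(t, r) = -l_i V_i(t, r)
                    + Σ_j ∫_Ω J_ij(r, r') S[σ_j (V_j(t - τ(r, r'), r') - h_j)] dr'
                    + I_i^ext(t, r),

the mean-membrane-potential description of p interacting neural populations
over a bounded piece of cortex Ω.  The leak rates l_i > 0 pull each potential
back to rest, the kernel J couples locations through a bounded sigmoidal
firing rate S, and the delay τ(r, r') = c·d(r, r') accounts for the finite
propagation speed of axonal signals (c is the *inverse* speed; axons are
treated as straight lines, so τ is proportional to distance).  Solving the
equation requires the voltage history on [-τ_m, 0], τ_m = max τ.

### The reference ring

All quantitative anchors use the scalar (p = 1) homogeneous model on the ring
of circumference 2π: Ω = [-π, π) with periodic boundary conditions,

    J(x, y) = J(x - y) = -1 + 1.5 cos(2(x - y)),      l = 1,
    τ(x, y) = c · d_ring(x, y),                        τ_m = cπ,

with d_ring the ring (saw-like, when plotted against x - y) distance, and a
centered sigmoid (S0(0) = 0) so that V ≡ 0 is always a stationary state.
The eigenfunctions of every convolution operator on this ring are cos(kx),
sin(kx), k ∈ ℕ, and the kernel coefficients are Ĵ_k = ∫ J(z) cos(kz) dz,
here Ĵ_0 = -2π, Ĵ_2 = 1.5π, all others zero.

The circumference and the delay profile were fixed by a consistency check
rather than convention: among the candidate readings of the ring geometry
(period π with even modes; period 2π with a π-periodic saw delay; period 2π
with the ring-distance delay) only the last places the fold-Hopf point near
c* ≈ 3.7 (see below); the others put it near 2.45.  The package therefore
uses the 2π ring with τ = c·d_ring throughout, and the closed-form test
oracles (σ0 = 8/(3π), τ_m = cπ, Ĵ_2 = 1.5π) are derived under that
convention.

### Sigmoid normalization

The base sigmoid is a rescaled logistic S(x) = 1/(1 + e^{-4 s1 x}) with
`s1` its slope at the origin (default 1/4, the plain logistic); `centered`
subtracts 1/2.  Exposing s1 keeps every slope normalization representable;
all linear-stability quantities depend on gain and slope only through the
product γ = σ·s1, so diagrams in (c, σ) simply rescale with s1 (verified:
the fold-Hopf c* is invariant under s1 → 1).

## Simulation

Space is discretized on the uniform ring grid with periodic-trapezoid
weights (spectrally accurate for smooth periodic integrands; exact for
trigonometric polynomials the grid resolves).  Time stepping is explicit
RK4 with fixed step dt; the delayed values V(t_s - τ(r, r'), r') at stage
times are read from a 4-point Lagrange cubic on the uniform history buffer.
Vanishing delays (τ(r, r) = 0) make the scheme formally implicit; the
integrator instead evaluates the cubic beyond its last committed node (an
extrapolation of at most one step, O(dt⁴) locally).  The scheme is
convergent; its observed self-convergence order on the reference model is
measured in the test suite (the suite asserts order > 1; measured ≈ 2-3,
limited by the frozen-history stage evaluation, not by RK4).  A step above
τ_m/4 triggers a warning; the state is aborted with the first bad time when
its norm exceeds 100·max(R, 1).

Random initial conditions are uniform in [-a, a] per node, constant in time
(a = 0.1 by default, seed recorded in all outputs).

All trajectories are ultimately bounded by
R = (√(p|Ω|)·‖J‖_{L2(Ω²)} + ‖I^ext‖_{L2})/min l_i (the firing rate is
bounded by 1); R ≈ 22.96 for the reference kernel.  The exact constant in
the underlying estimate is not the point — the *property* is: a seeded
ensemble is checked against 1.05·R after the transient, including at
linearly unstable parameter points.

## Spectral stability

Stationary states solve the delay-independent fixed-point equation and are
found by damped Newton from multiple starts (deduplicated, sorted by norm).
Linearization about V^f gives the effective kernel
J̃(r, r') = J(r, r')·σ S'(σ(V^f(r') - h)), and the spectrum of the
linearized delay operator splits into the essential spectrum {-l_i} — an
accumulation set — plus countably many characteristic values (CVs), with
finitely many to the right of -min l_i.  Stability of V^f is equivalent to a
negative spectral abscissa over the CVs.  Two independent computations:

**Per-mode characteristic equation** (homogeneous ring).  Mode k
contributes Δ_k(λ) = λ + l - γ G_k(λ) with
G_k(λ) = ∫_Ω J(z) e^{-λ c d(z)} cos(kz) dz.  G_k is evaluated by
Gauss–Legendre on half the ring (the integrand is smooth there; the node
count grows with |λ|cπ to resolve the oscillation).  Roots come from damped
complex Newton off a rectangular grid of starts (default region
Re ∈ [-l-1, 2], ω_max = max(20, 10/(τ_m + 0.1)); upper half-plane only,
conjugates implied), polished to |Δ| < 1e-9 relative to an explicit
conditioning factor e^{max(0, -Re λ)cπ} that accounts for the growth of the
delay factor left of the axis, and deduplicated within 1e-6 (multiplicities
are reported as distinct nearby roots, never resolved).  An
argument-principle contour count over rectangles serves as an independent
root-count oracle in the tests.

**Generator matrix A_N.**  The history segment u(θ, x), θ ∈ [-τ_m, 0], is
collocated at M+1 Chebyshev–Gauss–Lobatto points tensored with the spatial
grid.  Interior rows apply the spectral differentiation matrix in θ (the
generator acts as d/dθ); the θ = 0 row applies
-L₀u(0) + ∫ J̃(x, y) u(-τ(x, y), y) dy with the delayed argument evaluated
by barycentric interpolation in θ.  For homogeneous ring models the
boundary integral uses Gauss panels split at the delay kink (d is not
differentiable at coincident and antipodal points) with trigonometric
interpolation in space; this keeps the discretization spectrally accurate —
the rightmost eigenvalues agree with the mode-Newton roots to ~1e-12 at
N = 48, M = 24.  Tabulated (inhomogeneous) kernels fall back to the
periodic trapezoid row, O(N⁻²) because of the kink.  τ_m = 0 degenerates to
the non-delayed operator -L₀ + J̃.

`assemble_spectrum` runs either or both methods, reconciles the rightmost
roots (disagreement beyond 1e-4 is an error, not a warning), attaches the
essential points and issues a three-valued verdict (stable / marginal /
unstable) with a 1e-6 marginality band, so bifurcation points are never
over-claimed.

**Eigenvalue accumulation.**  The CV sequence accumulates at -l: high ring
modes feel almost no coupling (Ĵ_k → 0), so each contributes a root near
-l.  Observing this in A_N requires enough *spatial* modes: with N spatial
nodes only ~N eigenvalues can sit near the accumulation point.  The
accumulation check therefore uses N = 192, M = 16 (a 3264² dense matrix,
about a minute of eig time), for which the trailing 50 of the 200 rightmost
eigenvalues have median real part -1.003 and essentially zero imaginary
parts.  At small N the same ranks are occupied by per-mode root chains
(Re λ ≈ -l - (2/cπ) log ω), which is a property of the operator, not a
discretization artifact — but it is not the accumulation point.

## Sufficient bounds

Two certified conditions avoid eigenvalue computations altogether.

**Delay-independent:** ‖J̃‖_{L2(Ω²)} < l.  The Hilbert–Schmidt norm is the
certified quantity (it dominates the operator norm, which is also reported:
on the ring they are γ·‖J‖_{L2} and max_k |γ Ĵ_k|).  When it holds, the
state is stable for every delay function.

**Delay-dependent:** writing the linearized equation as the non-delayed
part plus the delayed-feedback mismatch and integrating by parts in time
(so only V, never V', is estimated), the mismatch term
W(t) = ∫ J̃(r, r') ∫_{t-τ}^t V(u, r') du dr' obeys, by Cauchy–Schwarz in
time and a β-split of the kernel against τ,

    ‖W(t)‖ ≤ τ_m^{1-β} · ‖J̃ τ^β‖_{L2(Ω²)} · sup_{u ∈ [t-τ_m, t]} ‖V(u)‖,
    β ∈ (0, 1/2]

(the time Cauchy–Schwarz forces the τ^{1/2} budget, hence the β range).
If the non-delayed semigroup decays, ‖e^{t(-L₀+J̃)}‖ ≤ M_ε e^{-εt} with
ε > 0 — self-adjoint on the ring, so M_ε = 1 and ε = l - max(0, max_k γĴ_k),
vanishing exactly at the pitchfork gain — the variation-of-parameters
identity gives the contraction constant

    K(β) = τ_m^{1-β} · ‖J̃ τ^β‖_{L2(Ω²)} · (1 + M_ε ‖A₀‖/ε),

with ‖A₀‖ the norm of the non-delayed operator, and K(β) < 1 certifies
asymptotic stability.  K is scanned over a geometric β grid (default 40
points in [1e-3, 1/2]); on the ring K is *linear* in c, so the condition
converts directly into an admissible delay scale c < c_ref/K(c_ref) — in
particular it is strictly positive whenever ε > 0: small delays can never
destabilize a state that is stable without delays.  Both bounds are
deliberately conservative (the certified regions sit well inside the
CV-stable region); their value is cheapness and certainty, not sharpness.

For two-dimensional domains the related inverse-power delay weights
τ^{-β} are square-integrable iff β < 1; the package checks this by the
radial reduction of the disk pair integral through the disk-overlap area
A(s) = 2 acos(s/2) - (s/2)√(4-s²), integrated on a log grid with shrinking
inner cutoffs; the decade-increment ratio (→ 10^{-(2-2β)}) classifies
convergence, placing the divergence threshold at β = 1.

## Bifurcation tracing

The pitchfork line is closed-form: Δ_k(0) is delay-independent (e^0 = 1),
so σ0 = l/(s1·max_k Ĵ_k), vertical in c, with the zero root verified along
c to 1e-10.  For the Hopf curve, Δ_k(iω) = 0 splits into
l = γ C_k(ω) and ω = -γ S_k(ω); the gain enters linearly and is eliminated,
leaving the scalar equation ω C_k(ω) + l S_k(ω) = 0 (with C_k > 0), solved
per mode by dense bracketing and Brent refinement — exact for the
homogeneous ring and cheaper and more robust than two-dimensional Newton
continuation, with the generator matrix available as a spot check.  The
curve retains the minimal gain per c; no Hopf point exists at c = 0 (both
transforms are then constant in ω: the non-delayed ring flow is
gradient-like).  The fold-Hopf point solves σ_H(c*) = σ0 by bracketing and
bisection; for the reference kernel c* ≈ 3.65, ω* ≈ 0.47, carried by the
spatially uniform mode k = 0 on top of the k = 2 zero root.  Normal-form
coefficients are not computed; "Hopf curve" means the locus of purely
imaginary CVs.

The stability map evaluates, per grid cell, the mode-root abscissa and both
bound verdicts; cells where any computation fails are flagged, not fatal.
Probe points for the three dynamical regimes are chosen by region
membership: (c, σ) = (1, 0.5) below all curves (decay), (1, 1.1) past the
pitchfork only (stationary pattern), (6, 0.84) past the Hopf curve only
(sustained oscillation — the band between σ_H(c) and σ0 is narrow at large
c, about 0.02 in σ).

## What the synthetic inputs do and do not show

All inputs are generated programmatically: the reference model from its
printed parameters, histories from seeded uniform noise.  The fixtures
exercise a scalar, homogeneous, one-dimensional ring with a linear-in-
distance delay; passing tests therefore demonstrate correctness of the
machinery (quadrature, root finding, collocation, the contraction bound) on
that geometry, not fidelity to any particular cortical dataset, multi-
population model, or two-dimensional domain.  The general (tabulated-kernel)
code paths are tested against the ring closed forms, not against an
independent inhomogeneous reference.

## Numerical choices and limitations

* Problem sizes: unit tests use N = 16–64, M ≤ 24; the accumulation check
  uses N = 192, M = 16; regime simulations use N = 48, dt = 0.05, t = 200.
* Tolerances: stationary residual 1e-10; root residual 1e-9 (conditioned),
  dedup 1e-6; cross-method reconciliation 1e-4; marginality 1e-6.
* Ties and degenerate cases: multiplicities are reported as nearby distinct
  roots; σ = 0 gives the pure-leak spectrum; τ_m = 0 collapses the
  generator to the non-delayed operator; an all-negative kernel has no
  pitchfork (returns absent).
* The delay matrix is shared across populations (τ depends on space only);
  higher-order synaptic dynamics, two-dimensional cortices (beyond the norm
  computations), adaptive or implicit time stepping, and computation of the
  bifurcating orbits themselves are out of scope.
* The contraction constant is one member of a family of valid bounds; its
  constant factor affects only how conservative the certified region is,
  never the sufficiency, small-delay, or monotonicity properties, which are
  the tested guarantees.
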