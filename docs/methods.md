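# Methods

## Model class and the auxiliary-operator reduction

The package analyzes fully observed parabolic problems

u_t = L[A]u + f(x, u; B),  L[A] = d Δ + b·∇ + c,  𝓑u = 0,  u(·, 0) = u0,

on the interval (0, ℓ) or the torus, under the single structural
assumption that the operator and reaction are **linear in their
parameters**: L[A₁] + L[A₂] = L[A₁ + A₂] and likewise for f in B. Two
parameter points are called *indistinguishable with respect to u0* when
their solution flows from u0 coincide on the whole space–time cylinder;
the model is *identifiable from u0* on a parameter set when no two
distinct points in it are indistinguishable.

If two points did share a solution, subtracting their equations leaves the
auxiliary elliptic equation L[A]u = 0 for the difference point
A = A₁ − A₂ (roles swapped so the diffusivity difference d ≥ 0). Hence
everything reduces to the kernel of L[A] restricted by the boundary
condition:

1. **Step 1** — form A (module `linear.auxiliary_point`).
2. **Step 2** — A belongs to the potentially dangerous set 𝒜 iff
   ker L[A] ≠ {0}; since L[A] = L₁[A] + c with L₁ the drift–diffusion
   part, this holds iff c is an eigenvalue of −L₁[A], and the kernel
   dimension is the geometric multiplicity (`spectral.kernel_dimension`).
   Everything outside 𝒜 (the set ℛ) is unconditionally distinguishable.
3. **Step 3** — within 𝒜, indistinguishability additionally needs
   u0 ∈ ker L[A] and, when drift is present, the ratio constraint
   d₁/d₂ = b₁/b₂ (drift differences pointing the wrong way cannot be
   compensated). When both hold, the separated solution

   u(x, t) = c₀ e^{μt} φₙ(x),   μ = c₁ − (d₁/d) λₙ(d, b),

   solves both parabolic problems simultaneously and is returned as the
   witness. The exponent is derived by substituting the ansatz and using
   the collinearity (d₁, b₁) ∥ (d, b); for b = 0 it reduces to the
   homogeneity form μ = c₁ − d₁ λ̄ₙ with λ̄ₙ the unit-diffusivity
   eigenvalue, i.e. the invariant c − d(nπ/ℓ)² familiar from the Dirichlet
   case.
4. **Step 4** — when the measured quantity is a density, only kernels with
   a sign-definite mode matter: the first Dirichlet/Robin mode, or the
   constant Neumann/periodic mode (`linear.step4_filter`).

`linear.classify` packages the three verdicts (`distinguishable_R`,
`distinguishable_AI`, `indistinguishable_ANI`) and is symmetric in the
pair by construction.

## Spectral machinery

The eigenproblem −(dφ″ + bφ′) = λφ is solved by substituting
φ = e^{−βx}w, β = b/2d, which reduces it to w″ = qw with
q = β² − λ/d. The fundamental pair cq = cosh(√q x), sq = sinh(√q x)/√q is
entire in q, so a single formula covers oscillatory, degenerate, and
boundary-layer modes:

* **Dirichlet**: λₙ = b²/4d + d(nπ/ℓ)², φₙ = e^{−bx/2d} sin(nπx/ℓ). The
  sine factor is fixed by the boundary condition (φ(ℓ) = 0), and the
  operator-residual tests confirm it.
* **Neumann**: the same eigenvalue sequence plus λ₀ = 0 with constant
  eigenfunction (constants satisfy the drifted equation at λ = 0 for every
  b); eigenfunctions use the slope-free fundamental solution.
* **Periodic** (torus, b = 0): λₙ = d(2πn/ℓ_c)², multiplicity two for
  n ≥ 1 (cos and sin), multiplicity one at zero. Drifted periodic spectra
  are complex and out of scope; the code raises rather than guesses.
* **Robin**: transcendental characteristic equation
  2σ·cq(ℓ) + (1 − σ²λ/d)·sq(ℓ) = 0 (after removing positive factors),
  solved by a sign-change scan plus Brent refinement to |f| ≤ 1e−12.
  For σ > 0 the quadratic form is positive semi-definite, so the scan
  starts just below zero; σ < 0 admits boundary-layer modes near −d/σ² and
  the window is widened accordingly. For q > 0 the characteristic function
  is rescaled by e^{−√qℓ} to avoid overflow deep below the spectrum.

**Robin convention.** For d > 0 the boundary operator is the
outward-normal form u + σ ∂u/∂ν = 0 (so u − σu_x = 0 at x = 0 and
u + σu_x = 0 at x = ℓ); this is the convention under which the Robin
spectrum interlaces between Neumann (σ → ±∞) and Dirichlet (σ → 0), which
the tests verify. The degenerate d = 0 operator L₀ = b∂ + c instead uses
the one-sided form u + σu_x = 0 at both endpoints, under which the
exponential e^{−x/σ} satisfies the boundary condition identically and
spans the kernel exactly when c = b/σ. The two conventions agree at x = ℓ
and differ at x = 0; the degenerate family (and its witness solution with
exponent d₁/σ² − b₁/σ + c₁) is only consistent with the one-sided form, so
both are kept, each where it is coherent.

Eigenfunctions are normalized to unit supremum with a positive first lobe
(so sign-definiteness can be read off, and the no-drift Dirichlet modes
are exactly sin(nπx/ℓ)). Kernel queries match c against eigenvalues with
relative tolerance 1e−8 (configurable); when a user-supplied tolerance
matches several eigenvalues the lowest index is used and a warning issued.

Kernel membership of an initial condition is tested by projecting onto the
kernel basis in the weighted inner product with weight e^{bx/d}, which
symmetrizes the drifted operator and makes the projection orthogonal; the
default relative-residual tolerance is 1e−6 on a 2001-point trapezoid
quadrature.

## ODE analogue

For Ẋ = M₁X the same subtraction argument is pure linear algebra: M₂ =
M₁ + M reproduces the trajectory iff M is singular, commutes with M₁, and
annihilates X₀. The commutant is computed as the null space of the
vectorized commutator I⊗M₁ − M₁ᵀ⊗I; singular members are found by a
determinant sign-change scan over coefficient directions. Trajectories are
compared through matrix exponentials rather than time stepping, so
integrator error never enters the verdict; round-off still grows like
e^{λmax T}, which the tests account for with scale-aware tolerances.

## Forward solvers

* `solve_linear_analytic`: exact eigen-expansion
  Σ Cₙ e^{(c−λₙ)t} φₙ(x); the temporal exponent uses the spatial
  eigenvalue of −L₁, which is what separation of variables dictates.
* `solve_mol`: second-order central differences (Dirichlet by unknown
  elimination, Neumann/Robin by second-order ghost nodes, periodic by
  wrap-around), stiff adaptive integration (LSODA, rtol 1e−8 / atol 1e−10,
  201 nodes by default), with a sup-norm blow-up guard at 1e8. Refinement
  tests confirm second-order convergence against the analytic solution.

## Nonlinear reactions

For u_t − d₁Δu = f(x, u; B) with logistic-type f, the auxiliary problem is
itself nonlinear: −dΔψ = f(x, ψ; B_diff). Identifiability follows when its
solution set is a single point or discrete, because a shared solution
would have to be steady, contradicting temporal variation in the data
(checked on a forward solve as sup|Δu/Δt| > 1e−8; steady data return an
explicit `inconclusive-steady` verdict).

Steady profiles are enumerated by shooting: the free left datum (slope for
Dirichlet/Robin, value for Neumann) sweeps a log-spaced grid over
±[1e−3, 1e2] (41 starts by default), right-boundary residual sign changes
are refined by Brent, blow-up cells are shrunk toward their finite end
before bracketing, and profiles are deduplicated at 1e−6 sup-norm. "Unique
/ discrete / continuous" is operationalized as the deduplicated solution
count, with a vanishing reaction flagged as the degenerate continuum. By
default only nonnegative profiles are retained: a shared solution of two
density models is itself a nonnegative profile, so sign-changing steady
states (which do exist, e.g. the negative branch for subcritical growth)
are not admissible witnesses; `nonnegative=False` enumerates them all, and
the ψ ↦ −ψ, b ↦ −b symmetry is verified on those.

For the heterogeneous logistic reaction m(x)u − bu² with constant m and
d = 0, the nonzero algebraic root of mψ − bψ² is ψ = m/b, and that is what
the code returns.

## Two-species construction

Given a scalar indistinguishable pair (d₁, c₁) ~ (d₂, c₂) with shared
solution u₁, the trajectory (u, v) = (κ_u u₁, κ_v u₁) solves the coupled
system with d_u = d₁, a₁₁ = c₁ + δ₁, a₁₂ = δ₁κ_u/κ_v, d_v = d₂,
a₂₂ = c₂ + δ₂, a₂₁ = δ₂κ_v/κ_u for *any* δᵢ > max(0, −cᵢ) (the lower bound
keeps all interaction rates positive, as the model requires). The
verification is belt-and-braces: closed-form PDE residuals (machine zero)
*and* method-of-lines integration from the shared initial condition under
different δ-sets (agreement at the discretization level, second-order in
the mesh). Perturbing the initial condition by 1% of the second eigenmode
breaks the coincidence, confirming the family is a knife-edge of the
initial condition, not of the solver.

## Synthetic experiment and profile likelihood

The practical pipeline emulates a fully observed 1-D experiment on the
unit Dirichlet domain with truth (c, d) = (1, 0.05):

* **Initial conditions**: a Gaussian bump centred at x = 1/2 with width
  ω ∈ {0.1, 0.2, 0.3}, translated to vanish at the boundary, scaled to 1
  at the centre, then truncated to its first N = 8 sine coefficients
  (adaptive quadrature). Truncation is applied last, so the centre value
  differs from 1 by the (small) truncation error; the truncated series
  *is* the data-generating initial condition.
* **Observations**: the exact expansion solution on the 11 × 21 grid
  x ∈ {0, 0.1, …, 1}, t ∈ {0, 0.1, …, 2}, plus Gaussian noise with
  per-slice covariance σ²e^{−η|Δx|} (σ = 0.3, η = 10, treated as known),
  independent across slices, drawn via a Cholesky factor per slice with a
  seeded generator. Boundary observations are pure noise and are retained;
  the stated grid includes them.
* **Profiling**: at fixed (c, d) the model is linear in the coefficients,
  so the profile maximizer is the generalized-least-squares solution of
  the slice-whitened stacked design e^{(c−dn²π²)t} sin(nπx) — exact, fast,
  and verified against a quasi-Newton optimizer. Nearly collinear designs
  (large d annihilates all modes) fall back to a tiny ridge with a
  warning. The surface is normalized to a zero maximum and the 95% region
  is {profile ≥ −χ²₀.₉₅(2)/2} = {≥ −2.9957…} (conventionally quoted
  ≈ 2.997). The default (c, d) grid is linear on [0, 4] × logarithmic on
  [1e−3, 1] (41 × 41; tests and examples use 21 × 21), the log scale
  reflecting that d can fail to be identified across orders of magnitude.

What the generator does *not* emulate: temporal noise correlation,
partial observation, measurement-grid irregularity, or model error. Tests
passing on these data show the inferential machinery is correct and that
structural indistinguishability translates into elongated confidence
regions; they do not certify coverage for real experiments. The measured
coverage of the 95% region at ω = 0.1 is ≈ 0.91 over 100 replicates —
slightly below nominal, as expected when profiling 8 nuisance parameters
from 231 correlated observations — and the replicate test bounds it with a
one-sided binomial allowance.

## Numerical choices and degenerate inputs

* Eigenvalue–c matching: relative 1e−8; kernel projection residual: 1e−6;
  PDE-residual witness check: 1e−10 scale; steady-profile dedup: 1e−6.
* d = 0 auxiliary operators are routed per boundary condition (Dirichlet:
  distinguishable unless b = c = 0; Neumann: constants iff c = 0; Robin:
  span{e^{−x/σ}} iff c = b/σ); the zero operator (b = c = 0) reports an
  infinite-dimensional kernel sentinel.
* Identical parameter points are rejected (`points must be distinct`), as
  are identically-zero initial conditions.
* Internal eigenvalue cutoff for kernel queries:
  n ≤ max(50, ⌈ℓ√(|c|/d)/π⌉ + 5), sufficient because λₙ grows like n².

## Known limitations

* One spatial dimension (interval/torus) only; spatially varying
  diffusion, drifted periodic spectra, and parameter-dependent boundary
  operators are out of scope.
* Continuous solution families of nonlinear auxiliary problems are
  detected only via the vanishing-reaction degenerate case; a genuine
  nonlinear continuum (should one exist outside the logistic class) would
  be reported as discrete with however many members the multistart finds.
* Noise parameters (σ, η) are treated as known in the profile analysis;
  joint estimation is not implemented.
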