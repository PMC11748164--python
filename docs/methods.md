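# Methods

## Scope and model assumptions

The package implements two first-order MECI searches — the constant-gap
("tube") minimization and the coupling-based gradient-projection method —
for a pair of adiabatic electronic states, plus diagnostics that certify
what kind of crossing was found. Electronic structure is abstracted behind
a single contract: an evaluation returns the two energies, their
gradients, and (when available) the gap-scaled interstate coupling. Two
backends satisfy it:

* **analytic diabatic models** — real symmetric 2×2 Hamiltonians with
  polynomial entries up to quadratic order. Eigenvalues, Hellmann–Feynman
  gradients, eigenvectors and the coupling
  h = ⟨ψ_lower|∇H|ψ_upper⟩ are closed-form. The gap factor in the
  derivative coupling cancels its 1/(E_m−E_n) divergence, so h is finite
  on the seam; at an *exact* degeneracy the eigenbasis is arbitrary and
  the evaluation is flagged instead (coupling and eigenvectors absent,
  both state gradients falling back to the well-defined mean gradient).
* **external engines** — a JSON request/response file exchange carrying
  energies (eV) and gradients (eV/Å) only, so engine-backed searches are
  tube-mode only. Model units map one-to-one onto eV/Å.

Everything is optimized in the surface's native coordinates. Internal or
redundant coordinate systems, second-order (Hessian/Lagrange–Newton)
searches, three-state intersections and spin–orbit coupling are out of
scope.

## Composite gradients

With gap Δ = E_upper − E_lower ≥ 0, unit difference gradient ĝ and target
ε ≥ 0:

* tube:  G = 2(Δ − ε)ĝ + (1 − ĝĝᵀ)∇E_upper
* gradient projection:  G = 2Δĝ + (1 − ûûᵀ − v̂v̂ᵀ)∇E_upper,
  with (û, v̂) the Gram–Schmidt basis of span{g, h}.

The two terms are orthogonal by construction; the first restores the
constraint, the second minimizes the upper energy tangentially. The unit
vector ĝ (rather than raw g) in the first term makes the two contributions
commensurate in energy/length units and the constraint-restoring step
scale-free; the prefactor 2 comes from viewing the first term as
∇(Δ − ε)²/‖g‖. When g and h are nearly parallel (angle < 10⁻⁶ rad) or h
vanishes — the glancing-intersection situation — the branching plane
degrades to the single direction ĝ with a warning, keeping behavior
continuous across that limit.

## Optimizer

The composite vector is not the gradient of any scalar, so there is no
merit function; the driver is plain BFGS on G with three safeguards:

* **curvature guard** — the inverse-Hessian secant update is applied only
  when s·y > 10⁻¹² ‖s‖‖y‖; otherwise it is skipped, or (default) the
  inverse Hessian is reset to an identity scaled to the current
  step/gradient ratio. Curvature failure is legitimate here, not an error.
* **step cap and norm-descent backtracking** — steps are capped at
  `max_step` (default 0.3 length units) and halved, up to 25 times, while
  they would increase ‖G‖; if every halving fails the smallest trial is
  taken anyway, so a strict local minimum of ‖G‖ that is not a zero cannot
  freeze the iteration. Monotone norm descent is the standard quasi-Newton
  root-finding globalization; here it additionally makes the iteration
  *contract onto the gap minimum when the constraint is infeasible* (an
  avoided crossing with minimum gap > ε), where the first term of G flips
  sign across the minimum and can never vanish — the diagnostically useful
  outcome is precisely that the gap settles at its minimum while the
  constraint-failure flag is raised.
* **stationary-gap escape** — where ‖g‖ < 10⁻¹² (exact degeneracy, or an
  avoided-crossing minimum hit head-on) G is undefined; the iterate is
  nudged by 10⁻⁶·`max_step` in a seeded pseudo-random direction, at most
  three times, then the run aborts with its partial trajectory. One
  exception: a degenerate point whose mean gradient already passes the
  gradient-projection convergence test is a seam stationary point and is
  accepted as converged — this makes the exact MECI a fixed point of the
  gp search.

The initial inverse Hessian is the identity scaled by `max_step`/‖G₀‖, so
the first step has length `max_step` regardless of units. Convergence
requires both ‖G‖ ≤ `tol_grad` (default 10⁻⁶) and the constraint residual
— |Δ − ε| in tube mode, Δ in gp mode — within `tol_gap` (default 10⁻⁸),
with inclusive comparisons. The two-phase behavior (descend to the
isosurface, then slide along it) is emergent, not coded. Identical inputs
and seed give bit-identical trajectories.

**Continuation.** A decreasing ε schedule is run stage by stage,
warm-starting both the geometry and the inverse Hessian from the previous
stage (the curvature information near the tube transfers well between
nearby tubes; the paired-run test shows the warm start does not cost
iterations at the median and typically saves them). A non-converged stage
aborts the chain, returning all results including the partial one.

## Fixture generators (what the synthetic surfaces emulate)

`conical_fixture(seed, N)` builds V11−V22 = 2α·x₁, V12 = β·x₂ with a
common diagonal bowl s(x₃..x_N) = e₀ + ½(t−t₀)ᵀA(t−t₀):

* cone slopes α, β ~ U(1.5, 2.5) — order-unity eV/Å, the magnitude of g
  and h at organic-molecule intersections;
* A random SPD with eigenvalues in [0.5, 2] (well-conditioned seam
  curvature), t₀ ~ U(−2, 2), e₀ ~ U(0, 0.5).

This makes the seam exactly {x₁ = x₂ = 0}, the gap an exact elliptic cone,
the MECI (0, 0, t₀) with upper energy e₀, and the ε-MECI set the ellipse
α²x₁² + β²x₂² = ε²/4 at t₀ with upper energy e₀ + ε/2 — all closed-form,
and verified numerically at build time (10⁻¹⁰) and against a brute-force
seam minimization in the tests. The linear-intersection fixture sets
V12 ≡ 0 (gap lifted in one direction only; h ≡ 0), the avoided-crossing
fixture V12 ≡ c₀ > 0 (minimum gap 2c₀, no intersection).

What these models deliberately do **not** emulate: seam curvature in the
branching-plane coordinates (the diagonals depend on x₁, x₂ only through
the tuning term), anharmonicity beyond quadratic, state crowding, and the
numerical noise of real electronic-structure gradients. Passing tests
therefore certify the *algorithmic* claims — constraint satisfaction,
ε → 0 collapse, method agreement, certificate correctness — not the
robustness of any particular quantum-chemistry backend.

## Diagnostics

* **Geometric phase** — the real lower eigenvector is transported around a
  discretized loop in the positive-overlap gauge; an odd number of sign
  flips means phase π. The discretization is doubled until the answer is
  stable twice; loops passing within 10⁻¹⁰ of a degeneracy are rejected.
  Valid as a yes/no certificate for real symmetric two-state models.
* **Cone scan** — gap sampled on branching-plane circles; a conical point
  has radius-stable mean gap/r (agreement threshold 1%) and a strictly
  positive minimum directional ratio (floor 5% of the mean), which the
  glancing case fails. The scan plane is estimated from the principal
  directions of normalized difference gradients sampled around the center
  (coupling-free), or can be given explicitly.
* **Cross-section** — gap(r, θ) = ε solved radially by bracketed Brent
  iteration at machine precision; a centered conic Ax² + Bxy + Cy² = 1 is
  fit by least squares; semi-axes are eigenvalue-derived and the rms
  conic residual measures ellipticity (it decays with ε when quadratic
  terms distort the cone). Angles with no radial solution are masked.
* **Brute-force oracle** — dense grid (N ≤ 4, default 41 points/axis)
  plus penalty refinement minimizing E_upper + μ(Δ − ε)² with μ ramped
  ×10 from 10² over five rounds; candidate acceptance requires
  |Δ − ε| ≤ 10⁻⁵. Emptiness of the isosurface is decided by minimizing
  the squared gap inside the box. The oracle shares no code path with the
  projected-gradient machinery.

## Numerical choices and edge cases

* Degeneracy flag only at exactly zero half-gap; near-degenerate points
  are evaluated normally (the formulas are stable there).
* Finite-difference evaluations warn when the gap is below the stencil
  resolution (state ordering can swap inside the stencil).
* Eigenvalue ordering is strictly by value; no diabatic-following.
* Inclusive tolerance comparisons throughout; all pseudo-randomness is
  seeded and all trajectories are reproducible bit-for-bit.
* Problem sizes used in tests and in the acceptance script — fixtures of
  dimension 3–6, 41-point-per-axis oracle grids, 36-angle scans, 10-seed
  suites — keep every closed-form comparison meaningful while the whole
  verification completes in seconds.

## Known limitations

* The tube search can converge to an avoided crossing whenever ε exceeds
  the local gap minimum; that is inherent to gap-targeting methods, and
  the geometric-phase certificate exists precisely to detect it.
* On an isotropic cone the ε-MECI is a whole circle; which point is
  returned depends on the start (the optimizer reports one minimizer, as
  any local method does on a degenerate minimum set).
* The gp mode requires couplings and is therefore unavailable on
  engine-backed surfaces; the tube mode with a small-ε continuation is the
  intended substitute.
* The ε-MECI upper energy exceeds the MECI energy by exactly ε/2 on a
  symmetric double cone; energy comparisons between the two methods must
  account for that offset or use ε small enough that it is negligible.
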