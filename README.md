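# seamtube

Locating **minimum-energy conical intersections (MECIs)** by minimizing the
upper-state energy on hypersurfaces of constant energy gap — the *tube
algorithm* — together with the classic gradient-projection method as a
reference, a geometric-phase intersection certificate, and analytic
two-state model surfaces with closed-form answers to verify everything
against.

## Who this is for

Photochemists and method developers who need MECI searches with electronic-
structure methods that do **not** provide nonadiabatic coupling vectors, or
that misbehave at exact degeneracies (coupled cluster methods can produce
complex energies and convergence failures on the seam). The tube algorithm
needs only energies and gradients of the two states and, by construction,
never steps onto the degeneracy itself.

## The method

For two adiabatic states with energies $E_m \ge E_n$ of a molecule with
$N$ internal degrees of freedom, the crossing seam
$\{\,\mathbf{x} : E_m(\mathbf{x}) = E_n(\mathbf{x})\,\}$ is
$(N-2)$-dimensional; the degeneracy is lifted linearly in the branching
plane spanned by

$$\mathbf{g}_{nm} = \nabla(E_m - E_n), \qquad
  \mathbf{h}_{nm} = \langle\psi_n|\nabla\psi_m\rangle\,(E_m - E_n).$$

**Gradient projection** (needs $\mathbf h$): drive to zero the composite

$$\mathbf{G} = 2\,(E_m - E_n)\,\hat{\mathbf g}
  \;+\; \mathbf{P}\,\nabla E_m,
  \qquad \mathbf{P} = \mathbf{1} - \hat{\mathbf u}\hat{\mathbf u}^T
                                 - \hat{\mathbf v}\hat{\mathbf v}^T,$$

with $\hat{\mathbf u},\hat{\mathbf v}$ an orthonormal basis of
$\mathrm{span}\{\mathbf g,\mathbf h\}$: the first term closes the gap, the
second minimizes $E_m$ along the seam.

**Tube algorithm** (needs only $\mathbf g$): fix a small $\varepsilon > 0$
and minimize $E_m$ on the $(N-1)$-dimensional isosurface
$E_m - E_n = \varepsilon$, which *envelops* the seam — in the branching
plane it is an ellipse, swept along the seam into a tube. Its zero
condition uses

$$\mathbf{G}^{\varepsilon} = 2\,(E_m - E_n - \varepsilon)\,\hat{\mathbf g}
  \;+\; \mathbf{P}^{\varepsilon}\,\nabla E_m,
  \qquad \mathbf{P}^{\varepsilon} = \mathbf{1} - \hat{\mathbf g}\hat{\mathbf g}^T,$$

because a level set of the gap is orthogonal to $\mathbf g$ alone — no
coupling vector enters. Converged structures are **ε-MECIs**; as
$\varepsilon \to 0$ the tube collapses onto the seam and the ε-MECI onto
the MECI (the ε-MECI upper energy sits exactly $\varepsilon/2$ above the
MECI energy on a symmetric double cone). In practice a *stepwise
continuation* is used: converge with a large ε, then restart with smaller
ε from the previous geometry.

Both searches are driven by a safeguarded BFGS iteration on the composite
vector (which is not the gradient of any scalar), with curvature-guarded
updates and norm-descent backtracking. A located point is certified as a
true intersection — rather than an avoided crossing — by the geometric
phase: the real electronic eigenvector transported around a loop enclosing
a conical intersection returns with its sign flipped (phase π).

Electronic structure enters only through energies and gradients, so the
optimizer runs on the built-in analytic diabatic models (2×2 polynomial
Hamiltonians with exactly known seams, MECIs and cone slopes) or on any
external engine via a JSON file-exchange protocol (tube mode only, since no
couplings are exchanged).

## Worked example

Find the ε-MECI of the textbook cone $V_{11}=x_1,\ V_{22}=-x_1,\ V_{12}=x_2$
(adiabatic energies $\pm r$, gap $2r$) with ε = 0.2 eV:

```bash
seamtube optimize --config examples/cone_run.yaml
# converged after 6 iterations: gap 2.000000e-01 eV, E_upper 0.1000000000 eV
```

The summary (`cone_meci.json`) reports the final point
`(0.08823529, 0.04705882)` — radius 0.1, i.e. exactly ε/2, where the gap
$2r$ equals ε and the upper energy $E_m = r$ is minimal on the isosurface;
on this isotropic cone every point of that circle is an ε-MECI. A full
iterate history goes to `cone_meci.csv`.

Stepwise continuation on a 3D model with a known MECI at upper energy
0.2116632245:

```bash
seamtube continuation --config examples/fixture_continuation.yaml
# converged after 27 iterations: gap 2.000000e-01 eV, E_upper 0.3116632218 eV
# converged after 4 iterations:  gap 1.999999e-02 eV, E_upper 0.2216632211 eV
# converged after 6 iterations:  gap 2.000000e-03 eV, E_upper 0.2126632245 eV
```

Each stage lands ε/2 above the MECI energy (0.1, 0.01, 0.001), converging
onto it as ε shrinks. `seamtube scan` and `seamtube phase` provide the
cone-topology and geometric-phase certificates; the same functionality is
available as a library (`seamtube.optimize`, `seamtube.continuation`,
`seamtube.diagnostics`).

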