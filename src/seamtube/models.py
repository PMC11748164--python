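"""Analytic two-state diabatic model surfaces.

A model is a real symmetric 2x2 electronic Hamiltonian whose entries are
polynomials (up to quadratic order) in the N internal coordinates:

    H(x) = [[V11(x), V12(x)],
            [V12(x), V22(x)]],   Vab(x) = c + l.x + x.Q.x/2

Its eigenvalues are the adiabatic energies

    E_pm = (V11 + V22)/2  +-  sqrt(((V11 - V22)/2)^2 + V12^2)

so energies, gradients (Hellmann-Feynman), eigenvectors and the gap-scaled
interstate coupling are all available in closed form.  These surfaces stand
in for an electronic-structure engine: they have crossing seams, minimum
energy conical intersections (MECIs) and cone slopes that are known exactly,
which is what makes the optimizer verifiable.

Energies are in model units (treated as eV at external interfaces),
coordinates in model lengths (treated as Angstrom externally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "PolyField",
    "DiabaticTwoStateModel",
    "SurfaceEvaluation",
    "FixtureSpec",
    "DegenerateEvaluationWarning",
    "StencilOrderingWarning",
    "evaluate",
    "evaluate_batch",
    "finite_difference_eval",
    "conical_fixture",
    "linear_intersection_fixture",
    "avoided_crossing_fixture",
    "isotropic_cone_model",
    "anisotropic_cone_model",
    "model_to_yaml",
    "model_from_yaml",
]

#: exact-degeneracy threshold for the half-gap; below this the adiabatic
#: eigenbasis is ill-defined and evaluations are flagged instead of raising
_DEGENERACY_EPS = 0.0


class DegenerateEvaluationWarning(UserWarning):
    """Evaluation at an exactly degenerate point (on the crossing seam)."""


class StencilOrderingWarning(UserWarning):
    """Finite-difference stencil may straddle the seam (state ordering can swap)."""


@dataclass(frozen=True)
class PolyField:
    """Scalar polynomial field  c + l.x + x.Q.x / 2  with symmetric Q."""

    constant: float
    linear: np.ndarray
    quadratic: np.ndarray

    def __post_init__(self):
        l = np.asarray(self.linear, dtype=float)
        q = np.asarray(self.quadratic, dtype=float)
        if q.shape != (l.size, l.size):
            raise ValueError(
                f"quadratic block has shape {q.shape}, expected {(l.size, l.size)}"
            )
        if not np.allclose(q, q.T, atol=1e-12, rtol=0.0):
            raise ValueError("quadratic coefficient matrix must be symmetric")
        object.__setattr__(self, "linear", l)
        object.__setattr__(self, "quadratic", 0.5 * (q + q.T))

    @classmethod
    def zeros(cls, n: int) -> "PolyField":
        return cls(0.0, np.zeros(n), np.zeros((n, n)))

    def value(self, x: np.ndarray) -> float:
        return float(self.constant + self.linear @ x + 0.5 * x @ self.quadratic @ x)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.linear + self.quadratic @ x

    def value_batch(self, xs: np.ndarray) -> np.ndarray:
        # xs: (n_points, N)
        quad = 0.5 * np.einsum("ni,ij,nj->n", xs, self.quadratic, xs)
        return self.constant + xs @ self.linear + quad


@dataclass(frozen=True)
class DiabaticTwoStateModel:
    """Polynomial 2x2 diabatic Hamiltonian in N coordinates."""

    dimension: int
    v11: PolyField
    v22: PolyField
    v12: PolyField
    label: str = ""

    def __post_init__(self):
        for name in ("v11", "v22", "v12"):
            f: PolyField = getattr(self, name)
            if f.linear.size != self.dimension:
                raise ValueError(
                    f"{name} is a field in {f.linear.size} coordinates, "
                    f"model dimension is {self.dimension}"
                )

    def evaluate(self, x) -> "SurfaceEvaluation":
        return evaluate(self, x)

    def evaluate_batch(self, xs: np.ndarray):
        return evaluate_batch(self, xs)


@dataclass(frozen=True)
class SurfaceEvaluation:
    """Adiabatic energies, gradients, eigenvectors and coupling at one point.

    ``coupling_h`` is the gap-scaled interstate coupling
    h = <psi_lower| grad H |psi_upper>; the factor (E_upper - E_lower) in
    h = <psi_l|grad psi_u>(E_u - E_l) cancels the denominator of the
    derivative coupling, so h stays finite on the seam.  At an exactly
    degenerate point the eigenbasis is arbitrary: ``degenerate`` is set,
    eigenvectors and coupling are ``None`` and both state gradients fall
    back to the well-defined mean gradient (the adiabatic surfaces have a
    conical kink there).
    """

    point: np.ndarray
    E_lower: float
    E_upper: float
    grad_lower: np.ndarray
    grad_upper: np.ndarray
    eigvec_lower: np.ndarray | None
    eigvec_upper: np.ndarray | None
    coupling_h: np.ndarray | None
    degenerate: bool = False

    @property
    def gap(self) -> float:
        return self.E_upper - self.E_lower

    @property
    def g_vector(self) -> np.ndarray:
        """Difference-gradient g = grad(E_upper - E_lower)."""
        return self.grad_upper - self.grad_lower


def _check_point(model: DiabaticTwoStateModel, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (model.dimension,):
        raise ValueError(f"point has shape {x.shape}, expected ({model.dimension},)")
    if not np.all(np.isfinite(x)):
        raise ValueError("point has non-finite components")
    return x


def evaluate(model: DiabaticTwoStateModel, x) -> SurfaceEvaluation:
    """Adiabatic evaluation of the 2x2 eigenproblem in closed form."""
    x = _check_point(model, x)
    v11, v22, v12 = model.v11.value(x), model.v22.value(x), model.v12.value(x)
    g11, g22, g12 = (
        model.v11.gradient(x),
        model.v22.gradient(x),
        model.v12.gradient(x),
    )
    mean = 0.5 * (v11 + v22)
    d = 0.5 * (v11 - v22)
    delta = np.hypot(d, v12)  # half-gap
    gmean = 0.5 * (g11 + g22)
    gd = 0.5 * (g11 - g22)

    if delta <= _DEGENERACY_EPS:
        warnings.warn(
            "evaluation at an exactly degenerate point; eigenvectors and "
            "coupling are undefined",
            DegenerateEvaluationWarning,
            stacklevel=2,
        )
        return SurfaceEvaluation(
            point=x,
            E_lower=mean,
            E_upper=mean,
            grad_lower=gmean.copy(),
            grad_upper=gmean.copy(),
            eigvec_lower=None,
            eigvec_upper=None,
            coupling_h=None,
            degenerate=True,
        )

    gdelta = (d * gd + v12 * g12) / delta
    grad_lower = gmean - gdelta
    grad_upper = gmean + gdelta

    evals, evecs = np.linalg.eigh(np.array([[v11, v12], [v12, v22]]))
    psi_l, psi_u = evecs[:, 0], evecs[:, 1]
    # h_k = psi_l . (dH/dx_k) . psi_u, expanded over the three fields
    coupling = (
        psi_l[0] * psi_u[0] * g11
        + psi_l[1] * psi_u[1] * g22
        + (psi_l[0] * psi_u[1] + psi_l[1] * psi_u[0]) * g12
    )
    return SurfaceEvaluation(
        point=x,
        E_lower=mean - delta,
        E_upper=mean + delta,
        grad_lower=grad_lower,
        grad_upper=grad_upper,
        eigvec_lower=psi_l,
        eigvec_upper=psi_u,
        coupling_h=coupling,
        degenerate=False,
    )


def evaluate_batch(model: DiabaticTwoStateModel, xs: np.ndarray):
    """Vectorized adiabatic energies at many points.

    Returns ``(E_lower, E_upper)`` arrays of shape ``(n_points,)``.  Used by
    grid-based diagnostics where eigenvectors are not needed.
    """
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    v11 = model.v11.value_batch(xs)
    v22 = model.v22.value_batch(xs)
    v12 = model.v12.value_batch(xs)
    mean = 0.5 * (v11 + v22)
    delta = np.hypot(0.5 * (v11 - v22), v12)
    return mean - delta, mean + delta


def finite_difference_eval(
    model: DiabaticTwoStateModel, x, step: float = 1e-5
) -> SurfaceEvaluation:
    """Central-difference gradients of both adiabatic energies.

    The numerical-differentiation path an engine without analytic gradients
    would use; here it serves as the oracle for the analytic gradients.  No
    coupling vector is produced.  When the gap at ``x`` is smaller than the
    energy change across the stencil the state ordering may swap inside it;
    a :class:`StencilOrderingWarning` is raised.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    x = _check_point(model, x)
    center = evaluate(model, x)
    slope = np.linalg.norm(center.g_vector)
    if center.gap < step * max(slope, 1.0):
        warnings.warn(
            f"gap {center.gap:.3e} is below the stencil resolution "
            f"(step {step:.1e}); adiabatic ordering may swap inside the stencil",
            StencilOrderingWarning,
            stacklevel=2,
        )
    n = model.dimension
    grad_lower = np.empty(n)
    grad_upper = np.empty(n)
    for k in range(n):
        dx = np.zeros(n)
        dx[k] = step
        lo_p, up_p = evaluate_batch(model, (x + dx)[None, :])
        lo_m, up_m = evaluate_batch(model, (x - dx)[None, :])
        grad_lower[k] = (lo_p[0] - lo_m[0]) / (2.0 * step)
        grad_upper[k] = (up_p[0] - up_m[0]) / (2.0 * step)
    return SurfaceEvaluation(
        point=x,
        E_lower=center.E_lower,
        E_upper=center.E_upper,
        grad_lower=grad_lower,
        grad_upper=grad_upper,
        eigvec_lower=center.eigvec_lower,
        eigvec_upper=center.eigvec_upper,
        coupling_h=None,
        degenerate=center.degenerate,
    )


# ---------------------------------------------------------------------------
# fixtures with analytically known seams and MECIs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Closed-form description of a conical fixture.

    The fixture has V11 - V22 = 2*alpha*x1, V12 = beta*x2 and a common
    diagonal seam potential s(x3..xN) = e0 + (t - t0).A.(t - t0)/2, so

      * the crossing seam is {x1 = 0, x2 = 0},
      * the gap is 2*sqrt(alpha^2 x1^2 + beta^2 x2^2) (an exact cone),
      * the MECI sits at (0, 0, t0) with upper energy e0,
      * the minimum upper energy on the gap = eps tube is e0 + eps/2,
        attained on the ellipse alpha^2 x1^2 + beta^2 x2^2 = eps^2/4
        at t = t0.
    """

    seed: int
    dimension: int
    alpha: float
    beta: float
    seam_matrix: np.ndarray  # A, SPD, (N-2)x(N-2)
    seam_center: np.ndarray  # t0, (N-2,)
    base_energy: float  # e0
    meci_point: np.ndarray = field(init=False)
    meci_upper_energy: float = field(init=False)

    def __post_init__(self):
        meci = np.zeros(self.dimension)
        meci[2:] = self.seam_center
        object.__setattr__(self, "meci_point", meci)
        object.__setattr__(self, "meci_upper_energy", float(self.base_energy))

    def eps_meci_upper_energy(self, epsilon: float) -> float:
        """Minimum upper-state energy on the gap = epsilon isosurface."""
        return self.base_energy + 0.5 * epsilon

    def distance_to_meci(self, x) -> float:
        return float(np.linalg.norm(np.asarray(x, dtype=float) - self.meci_point))

    def eps_meci_max_distance(self, epsilon: float) -> float:
        """Largest distance from the MECI over the set of epsilon-MECIs."""
        return 0.5 * epsilon / min(self.alpha, self.beta)


def _seam_potential(rng: np.random.Generator, n_seam: int):
    """Random SPD quadratic bowl: matrix A, center t0, eigenvalues in [0.5, 2]."""
    if n_seam == 0:
        return np.zeros((0, 0)), np.zeros(0)
    eigs = rng.uniform(0.5, 2.0, size=n_seam)
    q, _ = np.linalg.qr(rng.standard_normal((n_seam, n_seam)))
    a = (q * eigs) @ q.T
    a = 0.5 * (a + a.T)
    t0 = rng.uniform(-2.0, 2.0, size=n_seam)
    return a, t0


def _diag_fields(n: int, a: np.ndarray, t0: np.ndarray, e0: float):
    """Expand s(t) = e0 + (t-t0).A.(t-t0)/2 over the full N coordinates."""
    lin = np.zeros(n)
    quad = np.zeros((n, n))
    quad[2:, 2:] = a
    lin[2:] = -a @ t0
    const = e0 + 0.5 * float(t0 @ a @ t0)
    return const, lin, quad


def conical_fixture(seed: int, n: int) -> tuple[DiabaticTwoStateModel, FixtureSpec]:
    """Two-state model with an exactly conical seam and closed-form MECI.

    Cone slopes alpha, beta ~ U(1.5, 2.5) per seed (order-unity slopes, the
    magnitude of g/h vectors at organic-molecule intersections in eV/A); the
    seam potential is a random SPD quadratic in the N-2 seam coordinates.
    The stored analytic MECI is verified numerically at build time.
    """
    if n < 3:
        raise ValueError("conical fixture needs N >= 3 (seam must be nonempty)")
    rng = np.random.default_rng(seed)
    alpha, beta = rng.uniform(1.5, 2.5, size=2)
    a, t0 = _seam_potential(rng, n - 2)
    e0 = float(rng.uniform(0.0, 0.5))
    const, lin, quad = _diag_fields(n, a, t0, e0)

    lin11 = lin.copy()
    lin11[0] += alpha
    lin22 = lin.copy()
    lin22[0] -= alpha
    lin12 = np.zeros(n)
    lin12[1] = beta

    model = DiabaticTwoStateModel(
        dimension=n,
        v11=PolyField(const, lin11, quad),
        v22=PolyField(const, lin22, quad),
        v12=PolyField(0.0, lin12, np.zeros((n, n))),
        label=f"conical-fixture(seed={seed}, N={n})",
    )
    spec = FixtureSpec(
        seed=seed,
        dimension=n,
        alpha=float(alpha),
        beta=float(beta),
        seam_matrix=a,
        seam_center=t0,
        base_energy=e0,
    )
    # build-time verification of the stored analytic MECI
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateEvaluationWarning)
        ev = evaluate(model, spec.meci_point)
    grad_on_seam = model.v11.gradient(spec.meci_point)[2:]
    if ev.gap > 1e-10 or np.linalg.norm(grad_on_seam) > 1e-10:
        raise AssertionError("fixture self-check failed: stored MECI is not exact")
    return model, spec


def linear_intersection_fixture(seed: int, n: int) -> DiabaticTwoStateModel:
    """Glancing (linear) intersection: V12 = 0, gap = 2*alpha*|x1|.

    The degeneracy is lifted in one direction only, so the gap = eps set is
    a pair of parallel hyperplanes x1 = +-eps/(2*alpha), not a tube — though
    it still encloses the (N-1)-dimensional seam {x1 = 0}.  The coupling
    vector vanishes identically.
    """
    if n < 2:
        raise ValueError("linear intersection fixture needs N >= 2")
    rng = np.random.default_rng(seed)
    alpha = float(rng.uniform(1.5, 2.5))
    a, t0 = _seam_potential(rng, n - 1)
    const, lin, quad = _diag_fields(n + 1, a, t0, 0.0)
    # seam potential in x2..xN: shift the expansion left by one coordinate
    const = const
    lin = lin[1:]
    quad = quad[1:, 1:]
    lin11 = lin.copy()
    lin11[0] += alpha
    lin22 = lin.copy()
    lin22[0] -= alpha
    return DiabaticTwoStateModel(
        dimension=n,
        v11=PolyField(const, lin11, quad),
        v22=PolyField(const, lin22, quad),
        v12=PolyField.zeros(n),
        label=f"linear-intersection-fixture(seed={seed}, N={n})",
    )


def avoided_crossing_fixture(
    seed: int, n: int, c0: float
) -> DiabaticTwoStateModel:
    """Avoided crossing: V12 = c0 > 0, minimum gap 2*c0 on {x1 = 0}.

    There is no true intersection; the gap = eps isosurface is empty for
    eps < 2*c0 and a closed surface for eps > 2*c0.
    """
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if n < 2:
        raise ValueError("avoided crossing fixture needs N >= 2")
    rng = np.random.default_rng(seed)
    alpha = float(rng.uniform(1.5, 2.5))
    a, t0 = _seam_potential(rng, n - 1)
    const, lin, quad = _diag_fields(n + 1, a, t0, 0.0)
    lin = lin[1:]
    quad = quad[1:, 1:]
    lin11 = lin.copy()
    lin11[0] += alpha
    lin22 = lin.copy()
    lin22[0] -= alpha
    return DiabaticTwoStateModel(
        dimension=n,
        v11=PolyField(const, lin11, quad),
        v22=PolyField(const, lin22, quad),
        v12=PolyField(float(c0), np.zeros(n), np.zeros((n, n))),
        label=f"avoided-crossing-fixture(seed={seed}, N={n}, c0={c0})",
    )


def isotropic_cone_model() -> DiabaticTwoStateModel:
    """V11 = x1, V22 = -x1, V12 = x2: E_pm = +-r, gap = 2r (textbook cone)."""
    return anisotropic_cone_model(1.0, 1.0, label="isotropic-cone")


def anisotropic_cone_model(
    alpha: float, beta: float, label: str = ""
) -> DiabaticTwoStateModel:
    """Linear cone with slopes alpha (tuning) and beta (coupling), N = 2.

    gap = 2*sqrt(alpha^2 x1^2 + beta^2 x2^2); the gap = eps cross-section is
    an ellipse with semi-axes eps/(2*alpha) and eps/(2*beta).
    """
    lin11 = np.array([alpha, 0.0])
    lin12 = np.array([0.0, beta])
    return DiabaticTwoStateModel(
        dimension=2,
        v11=PolyField(0.0, lin11, np.zeros((2, 2))),
        v22=PolyField(0.0, -lin11, np.zeros((2, 2))),
        v12=PolyField(0.0, lin12, np.zeros((2, 2))),
        label=label or f"anisotropic-cone(alpha={alpha}, beta={beta})",
    )


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

_YAML_BLOCKS = ("v11", "v22", "v12")
_YAML_FIELD_KEYS = {"constant", "linear", "quadratic"}


def _field_to_dict(f: PolyField) -> dict:
    out = {}
    if f.constant != 0.0:
        out["constant"] = float(f.constant)
    if np.any(f.linear):
        out["linear"] = [float(v) for v in f.linear]
    if np.any(f.quadratic):
        out["quadratic"] = [[float(v) for v in row] for row in f.quadratic]
    return out


def _field_from_dict(d: dict | None, n: int, name: str) -> PolyField:
    d = d or {}
    unknown = set(d) - _YAML_FIELD_KEYS
    if unknown:
        raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")
    const = float(d.get("constant", 0.0))
    lin = np.asarray(d.get("linear", np.zeros(n)), dtype=float)
    quad = np.asarray(d.get("quadratic", np.zeros((n, n))), dtype=float)
    if lin.shape != (n,):
        raise ValueError(f"{name}.linear must be a length-{n} list")
    if quad.shape != (n, n):
        raise ValueError(f"{name}.quadratic must be an {n}x{n} nested list")
    return PolyField(const, lin, quad)


def model_to_yaml(model: DiabaticTwoStateModel, path) -> None:
    doc = {"dimension": int(model.dimension)}
    if model.label:
        doc["label"] = model.label
    for name in _YAML_BLOCKS:
        block = _field_to_dict(getattr(model, name))
        if block:
            doc[name] = block
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def model_from_yaml(path) -> DiabaticTwoStateModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: model file must be a YAML mapping")
    unknown = set(doc) - {"dimension", "label", *_YAML_BLOCKS}
    if unknown:
        raise ValueError(f"{path}: unknown keys: {sorted(unknown)}")
    if "dimension" not in doc:
        raise ValueError(f"{path}: missing required key 'dimension'")
    n = int(doc["dimension"])
    fields = {
        name: _field_from_dict(doc.get(name), n, name) for name in _YAML_BLOCKS
    }
    return DiabaticTwoStateModel(
        dimension=n, label=str(doc.get("label", "")), **fields
    )
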