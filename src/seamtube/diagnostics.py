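"""Certificates and independent oracles for located crossing points.

* :func:`geometric_phase` — the Berry-phase sign test: the real electronic
  eigenvector transported around a closed loop flips sign (phase pi) iff
  the loop encloses a true conical intersection; an avoided crossing or a
  non-enclosing loop gives phase 0.
* :func:`cone_scan` — samples the gap on branching-plane circles around a
  seam point; for a conical (linear-in-two-directions) intersection the
  mean of gap/r is radius-independent as r -> 0, while a glancing (linear)
  intersection shows near-zero gap directions.
* :func:`isosurface_cross_section` — solves gap = eps radially and fits the
  cross-section with a centered ellipse, the shape the constant-gap tube
  has in the branching plane of a linear cone.
* :func:`brute_force_constrained_min` — a dense-grid + penalty-refinement
  minimizer of the upper-state energy on the gap = eps set: slow, simple,
  and entirely independent of the projected-gradient machinery, which is
  exactly what makes it an oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .models import (
    DegenerateEvaluationWarning,
    DiabaticTwoStateModel,
    evaluate,
    evaluate_batch,
)

__all__ = [
    "LoopSpec",
    "ConeScan",
    "CrossSection",
    "BruteForceResult",
    "LoopTouchesSeamError",
    "geometric_phase",
    "branching_plane_estimate",
    "cone_scan",
    "isosurface_cross_section",
    "brute_force_constrained_min",
]


class LoopTouchesSeamError(ValueError):
    """A loop point is (numerically) on the seam; the phase is undefined."""


@dataclass(frozen=True)
class LoopSpec:
    """Closed circular path for the geometric-phase test."""

    center: np.ndarray
    plane_u: np.ndarray
    plane_v: np.ndarray
    radius: float
    n_points: int = 24

    def __post_init__(self):
        u = np.asarray(self.plane_u, dtype=float)
        v = np.asarray(self.plane_v, dtype=float)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "plane_u", u)
        object.__setattr__(self, "plane_v", v)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_points < 12:
            raise ValueError("need at least 12 loop points")
        gram = np.array([[u @ u, u @ v], [u @ v, v @ v]])
        if not np.allclose(gram, np.eye(2), atol=1e-10, rtol=0.0):
            raise ValueError("loop-plane vectors must be orthonormal")

    def points(self, n: int | None = None) -> np.ndarray:
        n = n or self.n_points
        thetas = 2.0 * np.pi * np.arange(n) / n
        return (
            self.center[None, :]
            + self.radius * np.cos(thetas)[:, None] * self.plane_u[None, :]
            + self.radius * np.sin(thetas)[:, None] * self.plane_v[None, :]
        )


def _phase_once(model: DiabaticTwoStateModel, loop: LoopSpec, n: int) -> float:
    pts = loop.points(n)
    vecs = []
    for p in pts:
        ev = evaluate(model, p)
        if ev.degenerate or ev.gap < 1e-10:
            raise LoopTouchesSeamError(
                f"loop point {p} has gap {ev.gap:.2e}; move or shrink the loop"
            )
        vecs.append(ev.eigvec_lower)
    sign = 1.0
    for k in range(n):
        ov = float(vecs[k] @ vecs[(k + 1) % n])
        if ov == 0.0:
            raise LoopTouchesSeamError(
                "consecutive eigenvectors orthogonal; refine the loop"
            )
        if ov < 0.0:
            sign = -sign
    return math.pi if sign < 0 else 0.0


def geometric_phase(
    model: DiabaticTwoStateModel, loop: LoopSpec, max_doublings: int = 8
) -> float:
    """Berry phase (0 or pi) of the lower adiabatic state around the loop.

    The real eigenvector is transported point-to-point with the positive-
    overlap gauge; an odd number of sign flips around the closed loop means
    phase pi, certifying an enclosed true intersection.  The discretization
    is doubled until the answer is stable twice in a row.
    """
    n = loop.n_points
    prev = _phase_once(model, loop, n)
    stable = 0
    for _ in range(max_doublings):
        n *= 2
        cur = _phase_once(model, loop, n)
        stable = stable + 1 if cur == prev else 0
        prev = cur
        if stable >= 2:
            return cur
    return prev


def branching_plane_estimate(
    model: DiabaticTwoStateModel, center, delta: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the branching plane at a (near-)seam point from g samples.

    Evaluates the difference gradient at +-delta displacements along every
    coordinate axis and takes the two leading principal directions.  Works
    without couplings and without assuming which coordinates span the
    plane; for a glancing intersection the second singular value is ~0 and
    the returned second direction is an arbitrary orthogonal complement.
    """
    center = np.asarray(center, dtype=float)
    n = center.size
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateEvaluationWarning)
        for k in range(n):
            for sgn in (+1.0, -1.0):
                x = center.copy()
                x[k] += sgn * delta
                ev = model.evaluate(x)
                if not ev.degenerate:
                    g = ev.g_vector
                    gn = np.linalg.norm(g)
                    if gn > 1e-12:
                        rows.append(g / gn)
    if not rows:
        raise ValueError("no usable difference gradients around the center")
    _, _, vt = np.linalg.svd(np.asarray(rows))
    u = vt[0]
    v = vt[1] if vt.shape[0] > 1 else None
    if v is None:  # N = 1 cannot happen for these models, but be safe
        raise ValueError("cannot span a plane in one dimension")
    return u, v


@dataclass(frozen=True)
class ConeScan:
    """Gap samples on branching-plane circles around a seam point."""

    center: np.ndarray
    radii: np.ndarray
    angles: np.ndarray
    gaps: np.ndarray  # shape (n_radii, n_angles)
    plane_u: np.ndarray
    plane_v: np.ndarray

    @property
    def mean_ratios(self) -> np.ndarray:
        """Per-radius mean of gap/r: constant in r for a true double cone."""
        return self.gaps.mean(axis=1) / self.radii

    def ratio_agreement(self) -> float:
        """Max relative spread of the mean gap/r ratios across radii."""
        r = self.mean_ratios
        return float((r.max() - r.min()) / r.max())

    def min_direction_ratio(self) -> float:
        """min over angles of gap/r at the smallest radius, relative to its
        mean: ~0 flags a direction in which the degeneracy is not lifted."""
        k = int(np.argmin(self.radii))
        row = self.gaps[k] / self.radii[k]
        return float(row.min() / row.mean())

    def is_conical(self, rtol: float = 0.01, direction_floor: float = 0.05) -> bool:
        """True when gap/r is radius-stable AND lifted in every direction.

        A glancing (linear) intersection fails the second test: the gap
        vanishes along the seam direction inside the scan plane.
        """
        return (
            self.ratio_agreement() <= rtol
            and self.min_direction_ratio() >= direction_floor
        )


def cone_scan(
    model: DiabaticTwoStateModel,
    center,
    radii,
    n_angles: int = 36,
    plane: tuple | None = None,
) -> ConeScan:
    """Sample the gap on circles of the given radii in the branching plane.

    ``plane`` overrides the automatically estimated plane vectors (useful
    for scanning a glancing intersection in a chosen coordinate plane).
    """
    center = np.asarray(center, dtype=float)
    radii = np.asarray(sorted(radii), dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if plane is None:
        u, v = branching_plane_estimate(model, center, delta=float(radii.min()) / 10)
    else:
        u, v = (np.asarray(w, dtype=float) for w in plane)
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    circle = np.cos(angles)[:, None] * u[None, :] + np.sin(angles)[:, None] * v[None, :]
    gaps = np.empty((radii.size, n_angles))
    for i, r in enumerate(radii):
        pts = center[None, :] + r * circle
        lo, up = evaluate_batch(model, pts)
        gaps[i] = up - lo
    return ConeScan(
        center=center, radii=radii, angles=angles, gaps=gaps, plane_u=u, plane_v=v
    )


@dataclass(frozen=True)
class CrossSection:
    """Ellipse fit of the gap = eps set in the branching plane.

    ``semi_axes`` is sorted ascending; ``residual`` is the rms misfit of
    the centered-conic equation A x^2 + B xy + C y^2 = 1 over the solved
    boundary points; ``angle_mask`` marks angles where no radial bracket
    with gap = eps exists (non-conical topology).
    """

    center: np.ndarray
    epsilon: float
    semi_axes: np.ndarray
    residual: float
    angles: np.ndarray
    radii: np.ndarray
    angle_mask: np.ndarray
    plane_u: np.ndarray
    plane_v: np.ndarray

    @property
    def complete(self) -> bool:
        return bool(np.all(self.angle_mask))


def _gap_at(model, center, u, v, r, theta):
    p = center + r * (math.cos(theta) * u + math.sin(theta) * v)
    lo, up = evaluate_batch(model, p[None, :])
    return float(up[0] - lo[0])


def isosurface_cross_section(
    model: DiabaticTwoStateModel,
    center,
    epsilon: float,
    n_angles: int = 36,
    plane: tuple | None = None,
    r_init: float | None = None,
) -> CrossSection:
    """Radially solve gap(r, theta) = eps and fit a centered ellipse."""
    from scipy.optimize import brentq

    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    center = np.asarray(center, dtype=float)
    if plane is None:
        u, v = branching_plane_estimate(model, center)
    else:
        u, v = (np.asarray(w, dtype=float) for w in plane)
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    radii = np.full(n_angles, np.nan)
    mask = np.zeros(n_angles, dtype=bool)
    r0 = r_init if r_init is not None else epsilon
    for i, th in enumerate(angles):
        f = lambda r: _gap_at(model, center, u, v, r, th) - epsilon
        lo, hi = 1e-14, r0
        found = False
        for _ in range(60):  # geometric bracket expansion
            if f(lo) < 0 <= f(hi):
                found = True
                break
            if f(hi) < 0:
                hi *= 2.0
            else:
                hi *= 0.5
            if hi > 1e6 or hi < 1e-12:
                break
        if not found:
            continue
        radii[i] = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
        mask[i] = True
    good = mask.sum()
    if good < 5:
        raise ValueError(
            f"gap = {epsilon} solvable along only {good} of {n_angles} "
            "directions; topology is not conical around this center"
        )
    xs = radii[mask] * np.cos(angles[mask])
    ys = radii[mask] * np.sin(angles[mask])
    design = np.column_stack([xs**2, xs * ys, ys**2])
    coef, *_ = np.linalg.lstsq(design, np.ones(good), rcond=None)
    resid = float(np.sqrt(np.mean((design @ coef - 1.0) ** 2)))
    conic = np.array([[coef[0], coef[1] / 2.0], [coef[1] / 2.0, coef[2]]])
    eigs = np.linalg.eigvalsh(conic)
    if np.any(eigs <= 0):
        raise ValueError("cross-section fit is not an ellipse (topology?)")
    semi = np.sort(1.0 / np.sqrt(eigs))
    return CrossSection(
        center=center,
        epsilon=float(epsilon),
        semi_axes=semi,
        residual=resid,
        angles=angles,
        radii=radii,
        angle_mask=mask,
        plane_u=u,
        plane_v=v,
    )


@dataclass(frozen=True)
class BruteForceResult:
    """Outcome of the grid + penalty oracle."""

    feasible: bool
    point: np.ndarray | None
    upper_energy: float | None
    gap: float | None
    min_gap_found: float

    def __iter__(self):  # allows  point, energy = brute_force_constrained_min(...)
        return iter((self.point, self.upper_energy))


def brute_force_constrained_min(
    model: DiabaticTwoStateModel,
    epsilon: float,
    bounds,
    resolution: int = 41,
    n_candidates: int = 20,
    mu0: float = 1e2,
    mu_rounds: int = 5,
) -> BruteForceResult:
    """Minimize E_upper on gap = eps by dense grid + penalty refinement.

    The bounds box is scanned on a ``resolution``-per-axis grid; the best
    near-isosurface candidates are refined by minimizing
    E_upper + mu (gap - eps)^2 with mu ramped x10 over ``mu_rounds``
    rounds.  Completely independent of the projected-gradient path.  Grids
    are practical for N <= 4 only (the refinement itself is dimension-free).
    """
    bounds = [tuple(map(float, b)) for b in bounds]
    n = len(bounds)
    if n != model.dimension:
        raise ValueError("bounds must have one (lo, hi) pair per coordinate")
    if n > 4:
        raise ValueError("dense grid limited to N <= 4")
    axes = [np.linspace(lo, hi, resolution) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    lo_e, up_e = evaluate_batch(model, pts)
    gaps = up_e - lo_e
    min_gap = float(gaps.min())

    def penalty(mu):
        def fun(x):
            ev = _quiet_eval(model, x)
            c = ev.gap - epsilon
            val = ev.E_upper + mu * c * c
            grad = ev.grad_upper + 2.0 * mu * c * ev.g_vector
            return val, grad

        return fun

    def refine(x0):
        x = np.asarray(x0, dtype=float)
        for k in range(mu_rounds):
            res = minimize(
                penalty(mu0 * 10.0**k),
                x,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
            )
            x = res.x
        return x

    # feasibility: can the gap reach eps inside the box at all?
    near = np.abs(gaps - epsilon)
    if min_gap > epsilon:
        x_gap = refine_gap_minimum(model, pts[int(np.argmin(gaps))], bounds)
        ev = _quiet_eval(model, x_gap)
        if ev.gap > epsilon + 1e-10:
            return BruteForceResult(
                feasible=False,
                point=None,
                upper_energy=None,
                gap=None,
                min_gap_found=min(float(ev.gap), min_gap),
            )

    band = near <= max(epsilon / 10.0, np.partition(near, n_candidates)[n_candidates])
    cand_idx = np.where(band)[0]
    order = np.argsort(up_e[cand_idx])[:n_candidates]
    best_x, best_e = None, np.inf
    for idx in cand_idx[order]:
        x = refine(pts[idx])
        ev = _quiet_eval(model, x)
        if abs(ev.gap - epsilon) <= 1e-5 and ev.E_upper < best_e:
            best_x, best_e = x, float(ev.E_upper)
    if best_x is None:
        return BruteForceResult(
            feasible=False,
            point=None,
            upper_energy=None,
            gap=None,
            min_gap_found=min_gap,
        )
    ev = _quiet_eval(model, best_x)
    return BruteForceResult(
        feasible=True,
        point=best_x,
        upper_energy=float(ev.E_upper),
        gap=float(ev.gap),
        min_gap_found=min_gap,
    )


def _quiet_eval(model, x):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateEvaluationWarning)
        return evaluate(model, x)


def refine_gap_minimum(model, x0, bounds):
    """Minimize the squared gap inside the box (feasibility probe)."""

    def fun(x):
        ev = _quiet_eval(model, x)
        return ev.gap**2, 2.0 * ev.gap * ev.g_vector

    res = minimize(
        fun,
        np.asarray(x0, dtype=float),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-14},
    )
    return res.x
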