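"""Branching plane, seam/tube projectors and composite gradients.

Two constrained-search gradients are built here:

* gradient projection (Bearpark-style): drive the gap to zero while
  minimizing the upper-state energy inside the crossing seam,

      G = 2 (E_u - E_l) ghat  +  P_seam grad(E_u),
      P_seam = 1 - u u^T - v v^T   (u, v orthonormal basis of span{g, h})

  which needs the interstate coupling h to resolve the branching plane;

* tube: drive the gap to a fixed eps > 0 and minimize the upper-state
  energy on the gap = eps level set,

      G = 2 (E_u - E_l - eps) ghat  +  P_tube grad(E_u),
      P_tube = 1 - ghat ghat^T

  which needs only the difference gradient g — the level set of the gap is
  orthogonal to g alone, so h is never required.

In both, the first (gap) term vanishes on the constraint surface and the
second (seam) term is the projected upper-state gradient; the two terms are
orthogonal by construction.  The unit vector ghat (rather than raw g) keeps
the two terms commensurate in units and the constraint-restoring step
scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import SurfaceEvaluation

__all__ = [
    "BranchingPlane",
    "Projector",
    "CompositeGradient",
    "StationaryGapError",
    "CouplingUnavailableError",
    "DegenerateBranchingPlaneWarning",
    "branching_plane",
    "seam_projector",
    "tube_projector",
    "gp_gradient",
    "tube_gradient",
]

#: below this norm the difference gradient cannot be normalized
_G_NORM_FLOOR = 1e-12

#: sine of the g/h angle below which the plane degrades to one direction
_PARALLEL_SIN = 1e-6


class StationaryGapError(ValueError):
    """The difference gradient vanishes: the gap is stationary here and no
    branching-plane direction can be normalized."""


class CouplingUnavailableError(ValueError):
    """The surface supplies no interstate coupling; the gradient-projection
    mode cannot run.  Use the tube mode, which needs only g."""


class DegenerateBranchingPlaneWarning(UserWarning):
    """g and h are (near-)parallel; the branching plane degrades to a line."""


@dataclass(frozen=True)
class BranchingPlane:
    """Span of the difference gradient g and gap-scaled coupling h.

    ``v`` is ``None`` when no independent second direction exists (coupling
    absent, identically zero, or parallel to g — the glancing-intersection
    situation), in which case the plane degenerates to the single
    direction ``u``.
    """

    g: np.ndarray
    h: np.ndarray | None
    u: np.ndarray
    v: np.ndarray | None


@dataclass(frozen=True)
class Projector:
    """Symmetric idempotent N x N projector removing 1 or 2 directions."""

    matrix: np.ndarray
    removed_rank: int

    def __matmul__(self, w: np.ndarray) -> np.ndarray:
        return self.matrix @ w

    def apply(self, w: np.ndarray) -> np.ndarray:
        return self.matrix @ w


@dataclass(frozen=True)
class CompositeGradient:
    """gap_term + seam_term; the vector whose zero the optimizer seeks.

    ``epsilon`` is 0 in gradient-projection mode.  gap_term is parallel to
    g and seam_term orthogonal to it, so the two contributions never fight.
    """

    vector: np.ndarray
    gap_term: np.ndarray
    seam_term: np.ndarray
    epsilon: float

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))


def branching_plane(ev: SurfaceEvaluation) -> BranchingPlane:
    """Orthonormalize {g, h} into plane directions u (and v when it exists)."""
    g = ev.g_vector
    gnorm = np.linalg.norm(g)
    if gnorm < _G_NORM_FLOOR:
        raise StationaryGapError(
            f"difference gradient norm {gnorm:.2e} below {_G_NORM_FLOOR:.0e}; "
            "the energy gap is stationary at this point"
        )
    u = g / gnorm
    h = ev.coupling_h
    v = None
    if h is not None:
        hnorm = np.linalg.norm(h)
        if hnorm >= _G_NORM_FLOOR:
            v_raw = h - (h @ u) * u
            sin_angle = np.linalg.norm(v_raw) / hnorm
            if sin_angle < _PARALLEL_SIN:
                warnings.warn(
                    "g and h are nearly parallel; branching plane degrades "
                    "to a single direction",
                    DegenerateBranchingPlaneWarning,
                    stacklevel=2,
                )
            else:
                v = v_raw / np.linalg.norm(v_raw)
    return BranchingPlane(g=g, h=h, u=u, v=v)


def seam_projector(bp: BranchingPlane) -> Projector:
    """P = 1 - u u^T - v v^T: projector onto the seam tangent space
    (the orthogonal complement of the branching plane)."""
    n = bp.u.size
    p = np.eye(n) - np.outer(bp.u, bp.u)
    rank = 1
    if bp.v is not None:
        p -= np.outer(bp.v, bp.v)
        rank = 2
    return Projector(matrix=p, removed_rank=rank)


def tube_projector(g: np.ndarray) -> Projector:
    """P = 1 - ghat ghat^T: projector onto the tangent space of the
    constant-gap level set, which is orthogonal to g alone (h is NOT
    removed — the level set is (N-1)-dimensional)."""
    g = np.asarray(g, dtype=float)
    gnorm = np.linalg.norm(g)
    if gnorm < _G_NORM_FLOOR:
        raise StationaryGapError(
            f"difference gradient norm {gnorm:.2e} below {_G_NORM_FLOOR:.0e}"
        )
    ghat = g / gnorm
    return Projector(matrix=np.eye(g.size) - np.outer(ghat, ghat), removed_rank=1)


def _composite(ghat, gap_minus_target, projector, grad_upper, epsilon):
    gap_term = 2.0 * gap_minus_target * ghat
    seam_term = projector @ grad_upper
    return CompositeGradient(
        vector=gap_term + seam_term,
        gap_term=gap_term,
        seam_term=seam_term,
        epsilon=epsilon,
    )


def gp_gradient(ev: SurfaceEvaluation) -> CompositeGradient:
    """Gradient-projection composite: zero exactly at the MECI.

    Requires the interstate coupling to build the rank-2 seam projector.
    """
    if ev.coupling_h is None:
        raise CouplingUnavailableError(
            "surface evaluation carries no interstate coupling; "
            "gradient-projection mode needs it — use the tube mode instead"
        )
    bp = branching_plane(ev)
    proj = seam_projector(bp)
    return _composite(bp.u, ev.gap, proj, ev.grad_upper, 0.0)


def tube_gradient(ev: SurfaceEvaluation, epsilon: float) -> CompositeGradient:
    """Tube composite: zero exactly at the eps-MECI, coupling-free."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    g = ev.g_vector
    proj = tube_projector(g)
    ghat = g / np.linalg.norm(g)
    return _composite(ghat, ev.gap - epsilon, proj, ev.grad_upper, epsilon)
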