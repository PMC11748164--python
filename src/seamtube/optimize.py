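"""Quasi-Newton driver for the tube and gradient-projection searches.

The composite gradient G (see :mod:`seamtube.projection`) is not the
gradient of any scalar function, so there is no merit function to
line-search.  The driver therefore runs plain BFGS steps on G with two
safeguards:

* the inverse-Hessian secant update is skipped (and optionally reset) when
  the curvature product s.y is not positive — a legitimate occurrence for a
  non-conservative vector field;
* each step is capped at ``max_step`` and backtracked (halved, a few
  times) while it would increase ||G||.  Monotone norm descent is the
  standard globalization for quasi-Newton root finding; here it also makes
  the iteration contract onto the gap minimum when the gap = eps
  constraint is infeasible (an avoided crossing with minimum gap > eps),
  where the constraint-restoring term of G flips sign across the minimum
  and can never vanish.

Two phases emerge without being coded: far from the seam the gap term of G
dominates and the iterates descend toward the constraint surface; once
|gap - eps| is small the projected upper-state gradient takes over and the
iterates slide along the tube toward the minimum-energy crossing geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import EngineError
from .models import DegenerateEvaluationWarning, SurfaceEvaluation
from .projection import (
    CompositeGradient,
    StationaryGapError,
    gp_gradient,
    tube_gradient,
)

__all__ = [
    "OptimizationSettings",
    "TrajectoryRecord",
    "OptimizationResult",
    "EpsSchedule",
    "optimize",
    "optimize_gp",
    "continuation",
    "convergence_check",
    "write_trajectory_csv",
]

TUBE = "tube"
GRADIENT_PROJECTION = "gradient_projection"

#: curvature guard for the BFGS secant pair
_CURVATURE_FLOOR = 1e-12

#: relative size of the deterministic escape perturbation at stationary-gap
#: points, in units of max_step
_PERTURB_SCALE = 1e-6

_MAX_PERTURB = 3

#: step halvings allowed while the composite-gradient norm would increase
_MAX_BACKTRACKS = 25


@dataclass(frozen=True)
class OptimizationSettings:
    """Knobs of one optimization run.

    epsilon        target energy gap (tube mode); ignored in gp mode
    tol_grad       convergence threshold on ||G||           (energy/length)
    tol_gap        threshold on |gap - eps| (tube) or gap (gp)    (energy)
    max_iter       iteration budget
    max_step       trust-radius cap on the step length            (length)
    mode           "tube" or "gradient_projection"
    seed           seeds the deterministic escape perturbation
    """

    epsilon: float | None = None
    tol_grad: float = 1e-6
    tol_gap: float = 1e-8
    max_iter: int = 200
    max_step: float = 0.3
    mode: str = TUBE
    bfgs_reset_on_curvature_fail: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in (TUBE, GRADIENT_PROJECTION):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == TUBE and (self.epsilon is None or self.epsilon <= 0):
            raise ValueError("tube mode requires epsilon > 0")
        if self.tol_grad <= 0 or self.tol_gap <= 0 or self.max_step <= 0:
            raise ValueError("tolerances and max_step must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass(frozen=True)
class TrajectoryRecord:
    iteration: int
    point: np.ndarray
    E_lower: float
    E_upper: float
    gap: float
    grad_norm: float
    gap_term_norm: float
    seam_term_norm: float


@dataclass
class OptimizationResult:
    """Converged (or final) state of a run plus the full iterate history."""

    point: np.ndarray
    E_lower: float
    E_upper: float
    gap: float
    iterations: int
    converged: bool
    constraint_satisfied: bool
    trajectory: list[TrajectoryRecord]
    mode: str
    epsilon: float | None
    message: str = ""
    inv_hessian: np.ndarray | None = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.point.size
        rows = []
        for rec in self.trajectory:
            row = {"iter": rec.iteration}
            row.update({f"x_{k + 1}": rec.point[k] for k in range(n)})
            row.update(
                E_lower=rec.E_lower,
                E_upper=rec.E_upper,
                gap=rec.gap,
                grad_norm=rec.grad_norm,
                gap_term_norm=rec.gap_term_norm,
                seam_term_norm=rec.seam_term_norm,
            )
            rows.append(row)
        return pd.DataFrame(rows)


def write_trajectory_csv(result: OptimizationResult, path) -> None:
    """One row per iterate; floats in full-precision scientific notation."""
    df = result.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17e")


def convergence_check(
    gap: float, composite_gradient_norm: float, settings: OptimizationSettings
) -> tuple[bool, bool]:
    """(converged, constraint_satisfied); comparisons are inclusive."""
    if settings.mode == TUBE:
        constraint = abs(gap - settings.epsilon) <= settings.tol_gap
    else:
        constraint = gap <= settings.tol_gap
    converged = constraint and composite_gradient_norm <= settings.tol_grad
    return converged, constraint


class _ZeroGradientAbort(RuntimeError):
    pass


def _composite_for(ev: SurfaceEvaluation, settings: OptimizationSettings):
    if settings.mode == TUBE:
        return tube_gradient(ev, settings.epsilon)
    return gp_gradient(ev)


def _evaluate_guarded(surface, x, settings, rng):
    """Evaluate surface and composite gradient, escaping stationary-gap points.

    At a point where g vanishes (an exactly degenerate point, or an
    avoided-crossing gap minimum hit head-on) the composite gradient is
    undefined.  If the point already satisfies the gp convergence test with
    the well-defined mean gradient it is accepted as converged (``G`` is
    returned as ``None``); otherwise the point is nudged by a small
    deterministic pseudo-random displacement, at most three times.
    """
    for attempt in range(_MAX_PERTURB + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateEvaluationWarning)
            ev = surface.evaluate(x)
        try:
            if ev.degenerate:
                raise StationaryGapError("exactly degenerate evaluation")
            G = _composite_for(ev, settings)
            return x, ev, G
        except StationaryGapError:
            # a degenerate point with zero mean gradient is a seam
            # stationary point: in gp mode that is the converged answer
            fallback_norm = float(np.linalg.norm(ev.grad_upper))
            if settings.mode == GRADIENT_PROJECTION:
                converged, _ = convergence_check(ev.gap, fallback_norm, settings)
                if converged:
                    return x, ev, None
            if attempt == _MAX_PERTURB:
                raise _ZeroGradientAbort(
                    "difference gradient vanished and three deterministic "
                    "perturbations did not escape the stationary-gap point"
                )
            direction = rng.standard_normal(x.size)
            direction /= np.linalg.norm(direction)
            x = x + _PERTURB_SCALE * settings.max_step * direction


def _record(it: int, ev: SurfaceEvaluation, G: CompositeGradient | None):
    if G is None:  # degenerate-converged point: gap term is exactly zero
        norm = float(np.linalg.norm(ev.grad_upper))
        gap_n, seam_n = 0.0, norm
    else:
        norm = G.norm
        gap_n = float(np.linalg.norm(G.gap_term))
        seam_n = float(np.linalg.norm(G.seam_term))
    return TrajectoryRecord(
        iteration=it,
        point=ev.point.copy(),
        E_lower=ev.E_lower,
        E_upper=ev.E_upper,
        gap=ev.gap,
        grad_norm=norm,
        gap_term_norm=gap_n,
        seam_term_norm=seam_n,
    )


def _bfgs_update(h: np.ndarray, s: np.ndarray, y: np.ndarray) -> np.ndarray:
    rho = 1.0 / (s @ y)
    n = s.size
    left = np.eye(n) - rho * np.outer(s, y)
    return left @ h @ left.T + rho * np.outer(s, s)


def optimize(
    surface,
    x0,
    settings: OptimizationSettings,
    h0: np.ndarray | None = None,
) -> OptimizationResult:
    """Drive the composite gradient to zero from ``x0``.

    ``surface`` is anything with an ``evaluate(x) -> SurfaceEvaluation``
    method (an analytic model or an external-engine adapter).  ``h0`` warm-
    starts the inverse Hessian (used by :func:`continuation`).  Identical
    inputs and seed give bit-identical trajectories.
    """
    rng = np.random.default_rng(settings.seed)
    x = np.array(x0, dtype=float)

    def _final(traj, ev, converged, constraint, h, message=""):
        return OptimizationResult(
            point=traj[-1].point,
            E_lower=ev.E_lower,
            E_upper=ev.E_upper,
            gap=ev.gap,
            iterations=len(traj) - 1,
            converged=converged,
            constraint_satisfied=constraint,
            trajectory=traj,
            mode=settings.mode,
            epsilon=settings.epsilon if settings.mode == TUBE else None,
            message=message,
            inv_hessian=h,
        )

    trajectory: list[TrajectoryRecord] = []
    try:
        x, ev, G = _evaluate_guarded(surface, x, settings, rng)
    except _ZeroGradientAbort as exc:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateEvaluationWarning)
            ev = surface.evaluate(np.array(x0, dtype=float))
        trajectory.append(_record(0, ev, None))
        _, constraint = convergence_check(
            ev.gap, float(np.linalg.norm(ev.grad_upper)), settings
        )
        return _final(trajectory, ev, False, constraint, None, str(exc))
    except EngineError as exc:
        raise EngineError(f"surface evaluation failed at the start: {exc}") from exc

    trajectory.append(_record(0, ev, G))
    grad_norm = trajectory[-1].grad_norm
    converged, constraint = convergence_check(ev.gap, grad_norm, settings)
    if converged or G is None:
        return _final(trajectory, ev, converged, constraint, h0)

    h = h0 if h0 is not None else (settings.max_step / G.norm) * np.eye(x.size)
    message = ""

    for it in range(1, settings.max_iter + 1):
        d = -(h @ G.vector)
        dnorm = np.linalg.norm(d)
        if dnorm > settings.max_step:
            d *= settings.max_step / dnorm
        try:
            # backtrack while the step would increase ||G||; if every
            # halving fails, take the smallest trial anyway (G is not a
            # true gradient, so a strict local minimum of ||G|| that is
            # not a zero must not freeze the iteration)
            for _ in range(_MAX_BACKTRACKS + 1):
                x_new, ev_new, G_new = _evaluate_guarded(
                    surface, x + d, settings, rng
                )
                if G_new is None or G_new.norm <= G.norm:
                    break
                d = 0.5 * d
        except _ZeroGradientAbort as exc:
            message = str(exc)
            break
        except EngineError as exc:
            message = f"surface evaluation failed: {exc}"
            break

        trajectory.append(_record(it, ev_new, G_new))
        if G_new is None:  # degenerate point accepted as gp-converged
            ev, converged, constraint = ev_new, True, True
            x = x_new
            break

        s = x_new - x
        y = G_new.vector - G.vector
        sy = float(s @ y)
        if sy > _CURVATURE_FLOOR * np.linalg.norm(s) * np.linalg.norm(y):
            h = _bfgs_update(h, s, y)
        elif settings.bfgs_reset_on_curvature_fail:
            # reset to an identity scaled to the current step/gradient scale
            scale = max(float(np.linalg.norm(s)), 1e-12) / max(G_new.norm, 1e-300)
            h = scale * np.eye(x.size)

        x, ev, G = x_new, ev_new, G_new
        converged, constraint = convergence_check(ev.gap, G.norm, settings)
        if converged:
            break

    return _final(trajectory, ev, converged, constraint, h, message)


def optimize_gp(surface, x0, settings: OptimizationSettings) -> OptimizationResult:
    """Gradient-projection search for the exact MECI (needs couplings)."""
    if settings.mode != GRADIENT_PROJECTION:
        settings = replace(settings, mode=GRADIENT_PROJECTION, epsilon=None)
    return optimize(surface, x0, settings)


@dataclass(frozen=True)
class EpsSchedule:
    """Strictly decreasing positive gap targets for stepwise continuation."""

    values: tuple

    def __init__(self, values):
        vals = tuple(float(v) for v in values)
        if not vals:
            raise ValueError("schedule must be nonempty")
        if any(v <= 0 for v in vals):
            raise ValueError("schedule values must be positive")
        if any(b >= a for a, b in zip(vals, vals[1:])):
            raise ValueError("schedule must be strictly decreasing")
        object.__setattr__(self, "values", vals)

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)


def continuation(
    surface, x0, schedule, settings: OptimizationSettings
) -> list[OptimizationResult]:
    """Stepwise tube optimization over a decreasing eps schedule.

    A large eps locates an initial geometry cheaply and each converged
    geometry (and its inverse Hessian) warm-starts the next, smaller-eps
    stage.  A stage that fails to converge aborts the chain; its partial
    result is still returned.
    """
    if not isinstance(schedule, EpsSchedule):
        schedule = EpsSchedule(schedule)
    results: list[OptimizationResult] = []
    x = np.array(x0, dtype=float)
    h = None
    for eps in schedule:
        stage = replace(settings, mode=TUBE, epsilon=float(eps))
        result = optimize(surface, x, stage, h0=h)
        results.append(result)
        if not result.converged:
            break
        x = result.point
        h = result.inv_hessian
    return results
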