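"""Run configuration: YAML schema, validation, defaults.

A run config names exactly one surface source (an analytic model YAML file
or an external engine command), exactly one starting geometry (a plain
coordinate vector ``x0`` or an ``xyz`` file in molecular mode), a mode, a
gap target ``epsilon`` or a decreasing ``schedule``, and optimizer knobs.
Unknown keys are rejected, listing the offenders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .optimize import EpsSchedule, OptimizationSettings

__all__ = ["RunConfig", "ConfigError", "load_run_config"]


class ConfigError(ValueError):
    """Invalid run configuration."""


_ALLOWED_KEYS = {
    "model",
    "engine",
    "mode",
    "epsilon",
    "schedule",
    "x0",
    "xyz",
    "tol_grad",
    "tol_gap",
    "max_iter",
    "max_step",
    "seed",
    "out_prefix",
}

_MODES = {"tube", "gradient_projection", "gp"}


@dataclass(frozen=True)
class RunConfig:
    model: str | None = None
    engine: str | None = None
    mode: str = "tube"
    epsilon: float | None = None
    schedule: tuple | None = None
    x0: tuple | None = None
    xyz: str | None = None
    tol_grad: float = 1e-6
    tol_gap: float = 1e-8
    max_iter: int = 200
    max_step: float = 0.3
    seed: int = 0
    out_prefix: str = "seamtube_run"

    def __post_init__(self):
        if (self.model is None) == (self.engine is None):
            raise ConfigError(
                "exactly one surface source required: set 'model' or 'engine'"
            )
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {sorted(_MODES)}")
        if self.mode == "gp":
            object.__setattr__(self, "mode", "gradient_projection")
        if (self.x0 is None) == (self.xyz is None):
            raise ConfigError(
                "exactly one starting geometry required: set 'x0' or 'xyz'"
            )
        if self.epsilon is None and self.schedule is None:
            if self.mode == "tube":
                raise ConfigError("tube mode needs 'epsilon' or 'schedule'")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.schedule is not None:
            try:
                EpsSchedule(self.schedule)
            except ValueError as exc:
                raise ConfigError(f"schedule: {exc}") from None
            object.__setattr__(
                self, "schedule", tuple(float(v) for v in self.schedule)
            )
        if self.x0 is not None:
            x0 = tuple(float(v) for v in np.asarray(self.x0, dtype=float).ravel())
            object.__setattr__(self, "x0", x0)

    def settings(
        self, epsilon: float | None = None, seed: int | None = None
    ) -> OptimizationSettings:
        eps = epsilon if epsilon is not None else self.epsilon
        if eps is None and self.schedule is not None:
            eps = self.schedule[0]
        return OptimizationSettings(
            epsilon=eps if self.mode == "tube" else None,
            tol_grad=self.tol_grad,
            tol_gap=self.tol_gap,
            max_iter=self.max_iter,
            max_step=self.max_step,
            mode=self.mode,
            seed=self.seed if seed is None else seed,
        )


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run config, applying defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    unknown = sorted(set(doc) - _ALLOWED_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {unknown}")
    # file paths in a config are relative to the config file itself
    from pathlib import Path

    base = Path(path).resolve().parent
    for key in ("model", "xyz"):
        if isinstance(doc.get(key), str) and not Path(doc[key]).is_absolute():
            doc[key] = str(base / doc[key])
    try:
        return RunConfig(**doc)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None
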