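"""File-exchange protocol to an external electronic-structure engine.

The optimizer only needs energies and gradients of the two states, so any
program that can write two energies and two gradient vectors can drive a
tube search (the gradient-projection mode is unavailable: no engine
coupling vectors are exchanged).  The protocol is deliberately dumb and
debuggable: one JSON request file, one JSON response file, one subprocess
call per evaluation.

Request (written by us)::

    {"geometry_angstrom": [...], "states": [0, 1],
     "wants": "energies+gradients"}

Response (written by the engine)::

    {"geometry_angstrom": [...],        # echo of the request geometry
     "e_lower": -1.0, "e_upper": 1.0,   # eV
     "grad_lower": [...], "grad_upper": [...],   # eV/Angstrom
     "status": "ok"}

The engine command is invoked as ``<command> <request.json> <response.json>``.
Energies are eV and coordinates/gradients Angstrom-based at this boundary.
"""

from __future__ import annotations

import json
import shlex
import subprocess
import tempfile
from pathlib import Path

import numpy as np

from .exceptions import EngineError
from .models import SurfaceEvaluation

__all__ = ["ExternalEngineSurface", "EngineError"]

_ECHO_TOL = 1e-12


class ExternalEngineSurface:
    """Adapter presenting an external engine as an evaluable surface.

    Parameters
    ----------
    command:
        The engine executable and fixed arguments, as a string (shlex-split)
        or a list.  Called as ``command request.json response.json``.
    dimension:
        Number of coordinates exchanged.
    workdir:
        Directory for the exchange files (a temporary directory when
        omitted); files are overwritten per call, so a crashed run leaves
        the last request/response pair behind for inspection.
    timeout:
        Seconds to wait for the engine before failing the evaluation.
    """

    def __init__(self, command, dimension: int, workdir=None, timeout: float = 300.0):
        self.command = shlex.split(command) if isinstance(command, str) else list(command)
        self.dimension = int(dimension)
        self.workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="seamtube_engine_"))
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.timeout = float(timeout)
        self.wants = "energies+gradients"

    def evaluate(self, x) -> SurfaceEvaluation:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(f"geometry has shape {x.shape}, expected ({self.dimension},)")
        req_path = self.workdir / "request.json"
        resp_path = self.workdir / "response.json"
        resp_path.unlink(missing_ok=True)
        with open(req_path, "w") as fh:
            json.dump(
                {
                    "geometry_angstrom": x.tolist(),
                    "states": [0, 1],
                    "wants": self.wants,
                },
                fh,
            )
        try:
            proc = subprocess.run(
                [*self.command, str(req_path), str(resp_path)],
                capture_output=True,
                text=True,
                timeout=self.timeout,
            )
        except subprocess.TimeoutExpired as exc:
            raise EngineError(
                f"engine timed out after {self.timeout}s: {self.command}"
            ) from exc
        if proc.returncode != 0:
            raise EngineError(
                f"engine exited with code {proc.returncode}\n"
                f"stdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
            )
        if not resp_path.exists():
            raise EngineError(
                f"engine wrote no response file\nstdout:\n{proc.stdout}"
                f"\nstderr:\n{proc.stderr}"
            )
        try:
            with open(resp_path) as fh:
                resp = json.load(fh)
        except json.JSONDecodeError as exc:
            raise EngineError(f"engine response is not valid JSON: {exc}") from exc
        return self._parse_response(x, resp, proc)

    def _parse_response(self, x, resp, proc) -> SurfaceEvaluation:
        def fail(msg):
            raise EngineError(
                f"invalid engine response: {msg}\nstdout:\n{proc.stdout}"
                f"\nstderr:\n{proc.stderr}"
            )

        if resp.get("status") != "ok":
            fail(f"status is {resp.get('status')!r}")
        echo = np.asarray(resp.get("geometry_angstrom", []), dtype=float)
        if echo.shape != x.shape or np.max(np.abs(echo - x), initial=0.0) > _ECHO_TOL:
            fail("geometry echo does not match the request")
        for key in ("e_lower", "e_upper"):
            if key not in resp or not np.isfinite(resp[key]):
                fail(f"missing or non-finite {key}")
        e_lower, e_upper = float(resp["e_lower"]), float(resp["e_upper"])
        if e_upper < e_lower:
            fail(f"e_upper={e_upper} < e_lower={e_lower}")
        grads = {}
        for key in ("grad_lower", "grad_upper"):
            if key not in resp:
                fail(f"gradients requested but {key} missing")
            g = np.asarray(resp[key], dtype=float)
            if g.shape != x.shape or not np.all(np.isfinite(g)):
                fail(f"{key} has wrong shape or non-finite entries")
            grads[key] = g
        return SurfaceEvaluation(
            point=x,
            E_lower=e_lower,
            E_upper=e_upper,
            grad_lower=grads["grad_lower"],
            grad_upper=grads["grad_upper"],
            eigvec_lower=None,
            eigvec_upper=None,
            coupling_h=None,
            degenerate=False,
        )
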