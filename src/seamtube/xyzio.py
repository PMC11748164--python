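"""Multi-frame XYZ reading and writing.

Standard XYZ: an atom-count line, a free-text comment line, then one
``element x y z`` line per atom (coordinates in Angstrom); frames are
concatenated.  Optimization trajectories in molecular mode are written as
multi-frame XYZ.  Coordinates are written with 10 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["XYZFrame", "XYZParseError", "read_xyz", "write_xyz"]


class XYZParseError(ValueError):
    """Malformed XYZ content; the message carries the offending line number."""


@dataclass(frozen=True)
class XYZFrame:
    symbols: tuple
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    comment: str = ""

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (len(self.symbols), 3):
            raise ValueError(
                f"coords shape {c.shape} does not match {len(self.symbols)} atoms"
            )
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "coords", c)

    def flat(self) -> np.ndarray:
        """Coordinates flattened to a plain optimization vector."""
        return self.coords.reshape(-1).copy()


def read_xyz(path) -> list[XYZFrame]:
    """Parse a (possibly multi-frame) XYZ file, preserving frame order."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[XYZFrame] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if natoms < 0:
            raise XYZParseError(f"line {i + 1}: negative atom count")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        symbols = []
        coords = []
        for k in range(natoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise XYZParseError(
                    f"line {i + 1}: frame declares {natoms} atoms but the "
                    "file ends early"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"line {ln + 1}: expected 'element x y z', got {lines[ln]!r}"
                )
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"line {ln + 1}: non-numeric coordinate in {lines[ln]!r}"
                ) from None
            symbols.append(parts[0])
            coords.append(xyz)
        frames.append(
            XYZFrame(
                symbols=tuple(symbols),
                coords=np.asarray(coords, dtype=float).reshape(natoms, 3),
                comment=comment,
            )
        )
        i += 2 + natoms
    return frames


def write_xyz(frames, path) -> None:
    """Write frames as standard XYZ with 10-decimal coordinates.

    All frames must share one atom count (a trajectory of one system).
    """
    frames = list(frames)
    if frames:
        n0 = len(frames[0].symbols)
        for k, fr in enumerate(frames):
            if len(fr.symbols) != n0:
                raise ValueError(
                    f"frame {k} has {len(fr.symbols)} atoms, expected {n0}"
                )
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{len(fr.symbols)}\n{fr.comment}\n")
            for sym, (x, y, z) in zip(fr.symbols, fr.coords):
                fh.write(f"{sym:<2s}{x:16.10f}{y:16.10f}{z:16.10f}\n")
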