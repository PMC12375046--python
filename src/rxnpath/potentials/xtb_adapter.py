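"""Feature-gated adapter for external semiempirical tight-binding engines.

The adapter shells out to a GFN2-xTB-class binary, exchanging plain XYZ files
and Hartree energies, and records the engine name and level of theory in every
structure it touches.  It is never required by the rest of the package: the
test suite and all built-in workflows run on the analytic backends.  Output
parsing is factored out (``parse_energy_output``, ``parse_gradient_file``) so
the wire protocol is testable without the engine installed.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calculator import Calculator
from .structure import Structure


class EngineNotFoundError(RuntimeError):
    """The external engine binary is not on PATH."""


_ENERGY_RE = re.compile(r"TOTAL ENERGY\s+(-?\d+\.\d+)\s+Eh", re.IGNORECASE)


def parse_energy_output(text: str) -> float:
    """Total energy (Hartree) from an engine's standard output."""
    m = _ENERGY_RE.search(text)
    if not m:
        raise ValueError("no 'TOTAL ENERGY ... Eh' line in engine output")
    return float(m.group(1))


def parse_gradient_file(text: str, natoms: int) -> np.ndarray:
    """Cartesian gradient (Hartree/Å) from a whitespace table of N rows × 3 columns."""
    rows = [ln.split() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    vals = [[float(v) for v in r[-3:]] for r in rows[-natoms:]]
    g = np.array(vals)
    if g.shape != (natoms, 3):
        raise ValueError(f"gradient table has shape {g.shape}, expected ({natoms}, 3)")
    return g


@dataclass
class XTBAdapter(Calculator):
    """Subprocess adapter for a tight-binding engine with an xtb-style CLI."""

    binary: str = "xtb"
    method: str = "gfn2"
    name: str = "xtb_adapter"

    def _require_binary(self) -> str:
        path = shutil.which(self.binary)
        if path is None:
            raise EngineNotFoundError(
                f"engine binary {self.binary!r} not found on PATH; the adapter is "
                "optional — use a built-in analytic backend instead")
        return path

    def energy(self, s: Structure) -> float:
        from ..iohub.xyz import write_xyz

        exe = self._require_binary()
        with tempfile.TemporaryDirectory() as tmp:
            xyz = Path(tmp) / "input.xyz"
            write_xyz(s, xyz)
            proc = subprocess.run(
                [exe, str(xyz), f"--{self.method}", "--chrg", str(s.charge),
                 "--uhf", str(s.multiplicity - 1)],
                capture_output=True, text=True, cwd=tmp, check=False)
            if proc.returncode != 0:
                raise RuntimeError(f"engine failed (exit {proc.returncode}): "
                                   f"{proc.stderr[-500:]}")
            e = parse_energy_output(proc.stdout)
        s.meta["engine"] = f"{self.binary}/{self.method}"
        return e
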