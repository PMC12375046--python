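"""Multi-frame XYZ read/write.

The comment line carries optional ``E=<value> <unit>``, ``charge=<int>`` and
``mult=<int>`` tokens; energies are stored in ``meta['energy']`` (converted to
Hartree when the unit is recognized).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from rdkit import Chem

from ..constants import HARTREE_TO_KCALMOL
from ..potentials.structure import Structure

_PT = Chem.GetPeriodicTable()


class XYZFormatError(ValueError):
    pass


def _parse_comment(comment: str, s: Structure) -> None:
    tokens = comment.split()
    for idx, tok in enumerate(tokens):
        if tok.startswith("E=") and len(tok) > 2:
            try:
                value = float(tok[2:])
            except ValueError:
                continue
            unit = tokens[idx + 1].lower() if idx + 1 < len(tokens) else "hartree"
            if unit.startswith("kcal"):
                value /= HARTREE_TO_KCALMOL
            s.meta["energy"] = value
        elif tok.startswith("charge="):
            s.charge = int(tok.split("=", 1)[1])
        elif tok.startswith("mult="):
            s.multiplicity = int(tok.split("=", 1)[1])


def read_xyz(path: str | Path) -> list[Structure]:
    """All frames of an XYZ file; errors carry the offending line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Structure] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise XYZFormatError(f"{path}:{ln + 1}: expected an atom count, got {lines[ln]!r}")
        if ln + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        comment = lines[ln + 1] if ln + 1 < len(lines) else ""
        elements, coords = [], []
        for k in range(natoms):
            lineno = ln + 2 + k
            if lineno >= len(lines) or not lines[lineno].strip():
                raise XYZFormatError(f"{path}:{lineno + 1}: frame declares {natoms} atoms "
                                     f"but ends after {k}")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise XYZFormatError(f"{path}:{lineno + 1}: malformed atom line {lines[lineno]!r}")
            el = parts[0]
            try:
                ok = _PT.GetAtomicNumber(el) > 0
            except Exception:
                ok = False
            if not ok:
                raise XYZFormatError(f"{path}:{lineno + 1}: unknown element {el!r}")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise XYZFormatError(f"{path}:{lineno + 1}: malformed coordinate "
                                     f"in {lines[lineno]!r}")
            elements.append(el)
            coords.append(xyz)
        s = Structure(elements, np.array(coords).reshape(natoms, 3), label=comment.strip())
        _parse_comment(comment, s)
        frames.append(s)
        ln += 2 + natoms
    return frames


def write_xyz(structures: Structure | list[Structure], path: str | Path) -> None:
    if isinstance(structures, Structure):
        structures = [structures]
    out = []
    for s in structures:
        comment = s.label or ""
        extra = []
        if "energy" in s.meta and s.meta["energy"] is not None:
            extra.append(f"E={s.meta['energy']:.10f} Hartree")
        extra.append(f"charge={s.charge}")
        extra.append(f"mult={s.multiplicity}")
        comment = (comment + " " if comment else "") + " ".join(extra)
        out.append(str(s.natoms))
        out.append(comment)
        for el, (x, y, z) in zip(s.elements, s.coords):
            out.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")
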