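"""The atomic-system container every stage of the pipeline transforms."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

_PT = Chem.GetPeriodicTable()

#: Minimum physically sensible interatomic distance (Å); closer atoms are a clash.
MIN_ATOM_SEPARATION = 0.3


class StructureError(ValueError):
    pass


@dataclass
class Structure:
    """An atomic system: element symbols, Cartesian coordinates (Å), charge, spin multiplicity.

    ``meta`` is a free-form scratch dict (e.g. ``energy`` in Hartree, relaxation flags);
    it is never used for identity.
    """

    elements: list[str]
    coords: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = [str(e) for e in self.elements]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError(f"coords must be N×3, got shape {self.coords.shape}")
        if len(self.elements) != self.coords.shape[0]:
            raise StructureError(
                f"{len(self.elements)} elements but {self.coords.shape[0]} coordinate rows"
            )
        if self.multiplicity < 1:
            raise StructureError("multiplicity must be a positive integer")

    @property
    def natoms(self) -> int:
        return len(self.elements)

    def atomic_numbers(self) -> np.ndarray:
        return np.array([_PT.GetAtomicNumber(e) for e in self.elements], dtype=int)

    def masses(self) -> np.ndarray:
        """Standard atomic weights, amu."""
        return np.array([_PT.GetAtomicWeight(e) for e in self.elements], dtype=float)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def min_distance(self) -> float:
        if self.natoms < 2:
            return np.inf
        d = self.coords[:, None, :] - self.coords[None, :, :]
        r = np.sqrt((d * d).sum(-1))
        iu = np.triu_indices(self.natoms, 1)
        return float(r[iu].min())

    def validate(self) -> None:
        """Raise if two atoms sit closer than the clash threshold."""
        dmin = self.min_distance()
        if dmin < MIN_ATOM_SEPARATION:
            raise StructureError(f"atoms closer than {MIN_ATOM_SEPARATION} Å (min {dmin:.3f} Å)")

    def copy(self) -> "Structure":
        return replace(self, coords=self.coords.copy(), meta=dict(self.meta))

    def with_coords(self, coords: np.ndarray, **meta) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(self.natoms, 3)
        out.meta.update(meta)
        return out

    def mirrored(self, axis: int = 0) -> "Structure":
        """Mirror image: negate one Cartesian axis."""
        c = self.coords.copy()
        c[:, axis] *= -1.0
        return self.with_coords(c)
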