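"""SMILES seed input: 3-D embedding of (possibly multi-component) line notation."""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ..potentials.structure import Structure
from ..potentials.u import UParams, u_relax

FRAGMENT_SPACING = 4.0  # Å between embedded components before relaxation


class SmilesError(ValueError):
    pass


def _embed_single(smiles: str, seed: int) -> tuple[list[str], np.ndarray, int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"invalid SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise SmilesError(f"3-D embedding failed for {smiles!r}")
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    return elements, coords, Chem.GetFormalCharge(mol)


def parse_smiles_seed(
    smiles: str,
    embed: bool = True,
    p: UParams | None = None,
    seed: int = 7,
    multiplicity: int = 1,
) -> Structure:
    """Structure from a SMILES string.

    Dot-separated components are embedded individually and placed
    ``FRAGMENT_SPACING`` Å apart along x; with ``embed`` on, the combined system
    is relaxed under U to remove residual clashes.
    """
    parts = [tok for tok in smiles.split(".") if tok]
    if not parts:
        raise SmilesError(f"invalid SMILES {smiles!r}")
    all_el: list[str] = []
    blocks: list[np.ndarray] = []
    charge = 0
    offset = 0.0
    for k, part in enumerate(parts):
        el, xyz, q = _embed_single(part, seed=seed + k)
        xyz = xyz - xyz.mean(0)
        span = xyz[:, 0].max() - xyz[:, 0].min()
        xyz[:, 0] += offset + span / 2.0
        offset += span + FRAGMENT_SPACING
        all_el.extend(el)
        blocks.append(xyz)
        charge += q
    s = Structure(all_el, np.vstack(blocks), charge=charge,
                  multiplicity=multiplicity, label=smiles)
    if embed and p is not None:
        s = u_relax(s, p)
    return s
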