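"""The pseudo-potential U used for cheap structure relaxation.

U(x) = Σ_{(i,j) ∈ bonds} a (r_ij − r_bond(i,j))²  +  Σ_{i<j not bonded} b / r_ij^n

Harmonic springs hold the declared bond list near reference lengths while a soft
pairwise repulsion keeps non-bonded atoms apart; minimizing U "relaxes a given
structure to a stable structure" without any electronic-structure cost.  It is
also the vehicle for intermediate proposal: adding a pair to the bond list pulls
the atoms together, removing it (plus a repulsive bias) pushes them apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.optimize import minimize

from .structure import Structure

_PT = Chem.GetPeriodicTable()


class CoincidentAtomsError(ValueError):
    """Two atoms at (numerically) zero separation: the repulsion term is singular."""


@dataclass
class UParams:
    """Parameters of U.

    a       bond-spring weight, Hartree/Å² (must be > 0)
    b       repulsion weight, Hartree·Åⁿ (≥ 0)
    n       repulsion exponent (integer ≥ 1)
    r_bond  optional reference bond-length table {frozenset({el1, el2}): Å};
            pairs not listed fall back to the covalent-radius sum.
    """

    a: float = 1.0
    b: float = 0.3
    n: int = 4
    r_bond: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("UParams.a must be > 0")
        if self.b < 0:
            raise ValueError("UParams.b must be >= 0")
        if self.n < 1:
            raise ValueError("UParams.n must be >= 1")

    def reference_length(self, el_i: str, el_j: str) -> float:
        key = frozenset((el_i, el_j))
        if key in self.r_bond:
            return float(self.r_bond[key])
        return _PT.GetRcovalent(el_i) + _PT.GetRcovalent(el_j)


def _pair_geometry(coords: np.ndarray):
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, 1)
    diff = coords[iu] - coords[ju]
    r = np.sqrt((diff * diff).sum(axis=1))
    return iu, ju, diff, r


def u_energy_gradient(
    s: Structure,
    bonds: list[tuple[int, int]],
    p: UParams,
    bias_pairs: list[tuple[int, int]] | None = None,
    bias_strength: float = 2.0,
) -> tuple[float, np.ndarray]:
    """U and its analytic Cartesian gradient.

    ``bias_pairs`` adds an extra repulsion ``bias_strength / r^n`` on the listed
    pairs (used when proposing bond-breaking intermediates).
    """
    coords = s.coords
    natoms = s.natoms
    bond_set = {(min(i, j), max(i, j)) for i, j in bonds}
    for i, j in bond_set:
        if not (0 <= i < natoms and 0 <= j < natoms) or i == j:
            raise ValueError(f"invalid bond pair ({i}, {j}) for {natoms} atoms")
    bias_set = {(min(i, j), max(i, j)) for i, j in (bias_pairs or [])}

    iu, ju, diff, r = _pair_geometry(coords)
    if natoms >= 2 and r.min() < 1e-8:
        raise CoincidentAtomsError("coincident atoms: pair distance is zero")

    grad = np.zeros_like(coords)
    energy = 0.0
    unit = diff / r[:, None] if r.size else diff

    keys = list(zip(iu.tolist(), ju.tolist()))
    bonded_mask = np.array([k in bond_set for k in keys], dtype=bool)
    bias_mask = np.array([k in bias_set for k in keys], dtype=bool)

    # spring term on bonded pairs
    if bonded_mask.any():
        rb = np.array([p.reference_length(s.elements[i], s.elements[j])
                       for (i, j), m in zip(keys, bonded_mask) if m])
        dr = r[bonded_mask] - rb
        energy += float(p.a * (dr * dr).sum())
        f = 2.0 * p.a * dr  # dU/dr
        np.add.at(grad, iu[bonded_mask], f[:, None] * unit[bonded_mask])
        np.add.at(grad, ju[bonded_mask], -f[:, None] * unit[bonded_mask])

    # repulsion on non-bonded pairs (bonded pairs excluded: the spring already acts there)
    rep_mask = ~bonded_mask
    if p.b > 0 and rep_mask.any():
        rr = r[rep_mask]
        energy += float((p.b / rr**p.n).sum())
        f = -p.n * p.b / rr ** (p.n + 1)
        np.add.at(grad, iu[rep_mask], f[:, None] * unit[rep_mask])
        np.add.at(grad, ju[rep_mask], -f[:, None] * unit[rep_mask])

    # extra repulsive bias on selected pairs
    if bias_set and bias_mask.any():
        rr = r[bias_mask]
        energy += float((bias_strength / rr**p.n).sum())
        f = -p.n * bias_strength / rr ** (p.n + 1)
        np.add.at(grad, iu[bias_mask], f[:, None] * unit[bias_mask])
        np.add.at(grad, ju[bias_mask], -f[:, None] * unit[bias_mask])

    return energy, grad


def u_energy(s: Structure, bonds: list[tuple[int, int]], p: UParams, **kw) -> float:
    return u_energy_gradient(s, bonds, p, **kw)[0]


def u_relax(
    s: Structure,
    p: UParams,
    fixed: set[int] | frozenset[int] = frozenset(),
    bonds: list[tuple[int, int]] | None = None,
    bias_pairs: list[tuple[int, int]] | None = None,
    bias_strength: float = 2.0,
    gtol: float = 1e-5,
    maxiter: int = 1000,
) -> Structure:
    """Locally minimize U with the listed atoms held fixed.

    The returned structure never has a higher U than the input; on non-convergence the
    best point found is returned with ``meta['u_converged'] = False`` and a warning.
    If ``bonds`` is omitted it is taken from the covalent connectivity graph.
    """
    if bonds is None:
        from .species import bond_list

        bonds = bond_list(s)
    fixed = frozenset(fixed)
    free = np.array([i for i in range(s.natoms) if i not in fixed], dtype=int)
    if free.size == 0:
        return s.copy()

    base = s.coords.copy()

    def fun(x):
        c = base.copy()
        c[free] = x.reshape(-1, 3)
        e, g = u_energy_gradient(s.with_coords(c), bonds, p,
                                 bias_pairs=bias_pairs, bias_strength=bias_strength)
        return e, g[free].ravel()

    x0 = base[free].ravel()
    e0 = fun(x0)[0]
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12})
    coords = base.copy()
    coords[free] = res.x.reshape(-1, 3)
    converged = bool(res.success) or float(np.abs(res.jac).max()) < 10 * gtol
    if res.fun > e0:  # never accept an uphill "relaxation"
        coords = base
        converged = True
    if not converged:
        warnings.warn(f"u_relax did not converge in {maxiter} iterations; returning best point",
                      stacklevel=2)
    out = s.with_coords(coords)
    out.meta["u_energy"] = float(min(res.fun, e0))
    out.meta["u_converged"] = converged
    return out
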