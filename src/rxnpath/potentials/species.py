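"""Connectivity perception and conformation-independent species identity.

A species is identified by its element-labeled covalent bond graph (optionally
decorated with stereocenter parities), so all conformers of one molecule hash to
the same id while constitutional isomers do not.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from rdkit import Chem

from .structure import Structure

_PT = Chem.GetPeriodicTable()

DEFAULT_BOND_SCALE = 1.2


class UnknownElementError(ValueError):
    pass


def covalent_radius(element: str) -> float:
    r = _PT.GetRcovalent(element)
    if r <= 0:
        raise UnknownElementError(f"no covalent radius for element {element!r}")
    return r


def connectivity(s: Structure, scale: float = DEFAULT_BOND_SCALE) -> nx.Graph:
    """Covalent bond graph: edge (i, j) iff r_ij < scale × (r_cov(i) + r_cov(j))."""
    g = nx.Graph()
    radii = [covalent_radius(e) for e in s.elements]
    for i, e in enumerate(s.elements):
        g.add_node(i, element=e)
    c = s.coords
    for i in range(s.natoms):
        for j in range(i + 1, s.natoms):
            r = float(np.linalg.norm(c[i] - c[j]))
            if r < scale * (radii[i] + radii[j]):
                g.add_edge(i, j, length=r)
    return g


def bond_list(s: Structure, scale: float = DEFAULT_BOND_SCALE) -> list[tuple[int, int]]:
    return sorted(tuple(sorted(e)) for e in connectivity(s, scale).edges)


def labeled_bond_set(s: Structure, scale: float = DEFAULT_BOND_SCALE) -> frozenset:
    """Bond set over the *indexed* atoms (not canonicalized): the right object for
    asking whether a transformation changed the connectivity of this particular
    atom arrangement — degenerate (identity-exchange) reactions change the labeled
    bonds while leaving the canonical species id untouched."""
    return frozenset(tuple(sorted(e)) for e in connectivity(s, scale).edges)


def fragment_count(s: Structure, scale: float = DEFAULT_BOND_SCALE) -> int:
    return nx.number_connected_components(connectivity(s, scale))


def canonical_species_id(
    s: Structure,
    chiral: bool = False,
    scale: float = DEFAULT_BOND_SCALE,
    graph: nx.Graph | None = None,
) -> str:
    """Canonical hash of the element-labeled connectivity graph.

    With ``chiral`` on, per-stereocenter R/S parities (keyed by a canonical
    per-node hash so the tag survives atom relabeling) are appended, which splits
    enantiomer ids while leaving conformers of one stereoisomer identical.
    """
    g = graph if graph is not None else connectivity(s, scale)
    base = nx.weisfeiler_lehman_graph_hash(g, node_attr="element", iterations=4)
    base = f"{base}|q{s.charge}m{s.multiplicity}"
    if not chiral:
        return base
    from ..conformers import detect_chiral_centers  # late import: conformers depends on us

    tags = detect_chiral_centers(s, graph=g)
    if not tags:
        return base
    node_hashes = nx.weisfeiler_lehman_subgraph_hashes(g, node_attr="element", iterations=4)
    decorated = sorted(f"{node_hashes[t.atom][-1]}:{t.parity}" for t in tags)
    return base + "|" + ",".join(decorated)
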