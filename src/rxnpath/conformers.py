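"""Active-site conformer generation and chirality handling.

Only arrangements of the two halves of the system around the active pair are
sampled: the part carrying active atom j ("B") is spun about its own pair axis
while revolving around the part carrying atom i ("A"), each pose is relaxed with
the pseudo-potential U (pair atoms held fixed), energy-screened against the best
pose and pruned by distance-matrix RMSD.  Whole-backbone conformational search
is deliberately out of scope.

Chirality support: stereocenter detection on the connectivity graph with a
simplified (atomic-number-first) neighbor priority, signed-volume R/S parity,
mirror-image enantiomer generation, and the rotation test that classifies two
elementary steps as identical / enantiomeric / distinct by rigid superposition
of their endpoint minima, with and without reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem

from .geometry import any_perpendicular, kabsch, rotation_about_axis
from .potentials.calculator import Calculator
from .potentials.species import canonical_species_id, connectivity
from .potentials.structure import Structure
from .potentials.u import UParams, u_relax
from .rules import ActivePair

_PT = Chem.GetPeriodicTable()


class FragmentSplitError(ValueError):
    """The active pair cannot be separated into two rotatable parts."""


@dataclass
class RotationGrid:
    """Pose grid for active-site conformer generation.

    spin_steps      rotations of part B about the pair axis
    orbit_steps     positions of B revolving around part A
    radius_offsets  pair-distance offsets (Å) applied along the pair axis
    """

    spin_steps: int = 6
    orbit_steps: int = 6
    radius_offsets: list[float] = field(default_factory=lambda: [0.0])

    def __post_init__(self):
        if self.spin_steps < 1 or self.orbit_steps < 1 or len(self.radius_offsets) < 1:
            raise ValueError("all rotation-grid counts must be >= 1")


@dataclass(frozen=True)
class StereoTag:
    atom: int
    parity: str  # 'R' or 'S' under the simplified priority convention


def split_fragments(s: Structure, pair: ActivePair,
                    graph: nx.Graph | None = None) -> tuple[set[int], set[int]]:
    """Partition the atoms into part A ∋ i and part B ∋ j.

    Different connectivity components → the components themselves (spectator
    fragments join A).  Same component → the two sides of the smallest edge cut
    separating i from j.
    """
    g = graph if graph is not None else connectivity(s)
    i, j = pair.i, pair.j
    comps = list(nx.connected_components(g))
    comp_i = next(c for c in comps if i in c)
    if j not in comp_i:
        comp_j = next(c for c in comps if j in c)
        part_b = set(comp_j)
        part_a = set(range(s.natoms)) - part_b
        return part_a, part_b
    sub = g.subgraph(comp_i)
    try:
        cut = nx.minimum_edge_cut(sub, i, j)
    except nx.NetworkXError as exc:
        raise FragmentSplitError(f"no separating cut for pair ({i}, {j})") from exc
    if not cut:
        raise FragmentSplitError(f"no separating cut for pair ({i}, {j})")
    if len(cut) == 1:
        # several single-edge cuts may exist (e.g. a chain); prefer the most
        # balanced one, deterministically
        best = None
        for edge in sub.edges:
            h = sub.copy()
            h.remove_edge(*edge)
            if nx.has_path(h, i, j):
                continue
            nb = len(nx.node_connected_component(h, j))
            imbalance = abs((sub.number_of_nodes() - nb) - nb)
            key = (imbalance, tuple(sorted(edge)))
            if best is None or key < best[0]:
                best = (key, {edge})
        cut = best[1]
    h = g.copy()
    h.remove_edges_from(cut)
    part_b = set(nx.node_connected_component(h, j))
    if i in part_b:
        raise FragmentSplitError(f"cut fails to separate pair ({i}, {j})")
    part_a = set(range(s.natoms)) - part_b
    return part_a, part_b


def distance_matrix_rmsd(s1: Structure, s2: Structure) -> float:
    """RMSD of the two interatomic-distance matrices (superposition-free).

    sqrt(mean over i<j of (r_ij(s1) − r_ij(s2))²); zero on any rigid motion or
    reflection of the same conformation.
    """
    if s1.elements != s2.elements:
        raise ValueError("structures must share the same elements and atom order")
    if s1.natoms < 2:
        return 0.0
    iu = np.triu_indices(s1.natoms, 1)

    def dm(s):
        d = s.coords[:, None, :] - s.coords[None, :, :]
        return np.sqrt((d * d).sum(-1))[iu]

    diff = dm(s1) - dm(s2)
    return float(np.sqrt((diff * diff).mean()))


def _pose(s: Structure, pair: ActivePair, part_b: set[int],
          spin: float, orbit: float, offset: float) -> np.ndarray:
    """Coordinates with part B revolved around atom i, spun about the pair axis,
    and offset along it."""
    c = s.coords.copy()
    bi = sorted(part_b)
    pi, pj = s.coords[pair.i], s.coords[pair.j]
    axis = pj - pi
    if np.linalg.norm(axis) < 1e-9:
        axis = np.array([1.0, 0.0, 0.0])
    perp = any_perpendicular(axis)
    # revolve B rigidly about atom i around a perpendicular axis
    R_orbit = rotation_about_axis(perp, orbit)
    c[bi] = (c[bi] - pi) @ R_orbit.T + pi
    # spin B about the (rotated) i->j axis
    new_axis = c[pair.j] - pi
    R_spin = rotation_about_axis(new_axis, spin)
    c[bi] = (c[bi] - pi) @ R_spin.T + pi
    if offset:
        u = new_axis / max(np.linalg.norm(new_axis), 1e-9)
        c[bi] = c[bi] + offset * u
    return c


def rotate_conformers(
    s: Structure,
    pair: ActivePair,
    grid: RotationGrid,
    p: UParams,
    e_thresh: float,
    rmsd_thresh: float,
    calc: Calculator,
) -> list[Structure]:
    """Spin/orbit pose grid around the active pair, U-relaxed and screened.

    Each pose is relaxed under U with the pair atoms immobilized, scored with the
    calculator, cut at ``min energy + e_thresh`` and deduplicated by
    distance-matrix RMSD (< ``rmsd_thresh``), lowest energy kept first.  If every
    pose fails (e.g. an unresolvable clash), the single U-relaxed input survives.
    """
    part_a, part_b = split_fragments(s, pair)
    del part_a  # A stays put; only B moves
    fixed = {pair.i, pair.j}
    candidates: list[Structure] = []
    for offset in grid.radius_offsets:
        for ko in range(grid.orbit_steps):
            for ks in range(grid.spin_steps):
                coords = _pose(s, pair, part_b,
                               spin=2 * np.pi * ks / grid.spin_steps,
                               orbit=2 * np.pi * ko / grid.orbit_steps,
                               offset=offset)
                trial = s.with_coords(coords)
                try:
                    relaxed = u_relax(trial, p, fixed=fixed)
                    relaxed.meta["energy"] = calc.energy(relaxed)
                except (ValueError, FloatingPointError):
                    continue
                candidates.append(relaxed)
    if not candidates:
        fallback = u_relax(s, p, fixed=fixed)
        fallback.meta["energy"] = calc.energy(fallback)
        return [fallback]
    candidates.sort(key=lambda st: st.meta["energy"])
    emin = candidates[0].meta["energy"]
    survivors: list[Structure] = []
    for cand in candidates:
        if cand.meta["energy"] > emin + e_thresh:
            break
        if all(distance_matrix_rmsd(cand, kept) >= rmsd_thresh for kept in survivors):
            survivors.append(cand)
    return survivors


# ----- chirality ----------------------------------------------------------


def _branch_ids(g: nx.Graph, center: int) -> dict[int, str]:
    """Canonical label of each substituent branch of ``center`` (graph minus center,
    final-iteration WL hash rooted at the neighbor)."""
    h = g.copy()
    h.remove_node(center)
    hashes = nx.weisfeiler_lehman_subgraph_hashes(h, node_attr="element", iterations=4)
    return {nb: hashes[nb][-1] for nb in g.neighbors(center)}


def detect_chiral_centers(s: Structure, graph: nx.Graph | None = None) -> list[StereoTag]:
    """Tetravalent carbons whose four substituent branches are pairwise distinct.

    Parity convention: neighbors ranked by (atomic number, atomic weight, branch
    hash) descending; parity is 'R' when the signed volume of the three
    highest-priority neighbor vectors (taken from the center) is positive.
    Mirroring the structure flips every parity.  This is a simplified priority
    scheme, not full CIP.
    """
    g = graph if graph is not None else connectivity(s)
    tags = []
    for atom in g.nodes:
        if s.elements[atom] != "C" or g.degree(atom) != 4:
            continue
        branch = _branch_ids(g, atom)
        nbs = list(g.neighbors(atom))
        if len(set(branch[nb] for nb in nbs)) != 4:
            continue
        ranked = sorted(
            nbs,
            key=lambda nb: (_PT.GetAtomicNumber(s.elements[nb]),
                            _PT.GetAtomicWeight(s.elements[nb]),
                            branch[nb]),
            reverse=True,
        )
        v = [s.coords[nb] - s.coords[atom] for nb in ranked[:3]]
        vol = float(np.dot(np.cross(v[0], v[1]), v[2]))
        tags.append(StereoTag(atom=atom, parity="R" if vol > 0 else "S"))
    return sorted(tags, key=lambda t: t.atom)


def generate_enantiomers(s: Structure, p: UParams) -> list[Structure]:
    """Mirror image (one axis negated), U-relaxed; returned only when the input is
    chiral and the mirror is a genuinely different stereoisomer (chiral ids differ)."""
    if not detect_chiral_centers(s):
        return []
    mirror = u_relax(s.mirrored(), p)
    if canonical_species_id(mirror, chiral=True) == canonical_species_id(s, chiral=True):
        return []
    mirror.meta["enantiomer_of"] = s.label or "input"
    return [mirror]


def rotation_test_classify(step1, step2, tol: float = 0.2) -> str:
    """Classify two elementary steps: 'identical', 'enantiomeric', or 'distinct'.

    Steps must connect the same achiral species (ids compared first); their
    endpoint minima are then rigidly superposed — matching directly means the
    steps are the same channel, matching only after reflection means they are
    mirror-image channels.  Endpoint minima (not TS structures) carry the
    comparison because a step's identity is defined by what it connects.
    """
    if (canonical_species_id(step1.reactant) != canonical_species_id(step2.reactant)
            or canonical_species_id(step1.product) != canonical_species_id(step2.product)):
        return "distinct"

    def best_rmsd(a: Structure, b: Structure, mirror: bool) -> float:
        P = a.coords.copy()
        if mirror:
            P[:, 0] *= -1.0
        if a.elements != b.elements:
            return np.inf
        _, _, r = kabsch(P, b.coords)
        return r

    direct = max(best_rmsd(step1.reactant, step2.reactant, False),
                 best_rmsd(step1.product, step2.product, False))
    if direct < tol:
        return "identical"
    mirrored = max(best_rmsd(step1.reactant, step2.reactant, True),
                   best_rmsd(step1.product, step2.product, True))
    if mirrored < tol:
        return "enantiomeric"
    return "distinct"
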