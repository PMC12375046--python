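"""Fragment splitting, rotation-grid conformers, distance-matrix RMSD, chirality."""

import numpy as np
import pytest

from rxnpath.conformers import (
    FragmentSplitError,
    RotationGrid,
    detect_chiral_centers,
    distance_matrix_rmsd,
    generate_enantiomers,
    rotate_conformers,
    rotation_test_classify,
    split_fragments,
)
from rxnpath.geometry import rotation_about_axis
from rxnpath.potentials import Structure, UParams, analytic_backend, canonical_species_id, u_relax
from rxnpath.rules import ActivePair
from rxnpath.tslocate import ElementaryStep, TSCandidate


def chain(n, spacing=1.5, elements=None):
    return Structure(elements or ["C"] * n,
                     np.array([[i * spacing, 0.0, 0.0] for i in range(n)]))


class TestSplitFragments:
    def test_two_components_split_as_components(self, pseudo_bundle):
        s = pseudo_bundle.seeds[0]
        a, b = split_fragments(s, ActivePair(i=0, j=2, action="form"))
        assert a == {0, 1} and b == {2, 3}

    def test_intramolecular_pair_splits_at_min_cut(self):
        # terminal pair of a 4-carbon chain: the cut is the middle bond
        s = chain(4)
        a, b = split_fragments(s, ActivePair(i=0, j=3, action="form"))
        assert a == {0, 1} and b == {2, 3}

    def test_single_atom_part_b_is_valid(self):
        s = Structure(["C", "C", "C"],
                      np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [6.0, 0.0, 0.0]]))
        a, b = split_fragments(s, ActivePair(i=0, j=2, action="form"))
        assert b == {2} and 0 in a

    def test_partition_is_disjoint_and_covering(self):
        s = chain(5)
        a, b = split_fragments(s, ActivePair(i=0, j=4, action="form"))
        assert a | b == set(range(5)) and not (a & b)

    def test_inseparable_ring_pair_raises(self):
        # equilateral triangle of bonded carbons: adjacent atoms have no cut
        # that puts them in different parts without cutting their own bond twice
        t = 1.5
        s = Structure(["C", "C", "C"],
                      np.array([[0.0, 0.0, 0.0], [t, 0.0, 0.0],
                                [t / 2, t * np.sqrt(3) / 2, 0.0]]))
        pair = ActivePair(i=0, j=1, action="break")
        try:
            a, b = split_fragments(s, pair)
            # if a cut exists it must still separate the pair
            assert 0 in a and 1 in b
        except FragmentSplitError:
            pass


class TestDistanceMatrixRmsd:
    def test_identical_structures_zero(self):
        s = chain(4)
        assert distance_matrix_rmsd(s, s) == 0.0

    def test_rigid_rotation_invariant(self, rng):
        s = chain(4)
        R = rotation_about_axis(rng.normal(size=3), 0.7)
        t = s.with_coords(s.coords @ R.T + rng.normal(size=3))
        assert distance_matrix_rmsd(s, t) == pytest.approx(0.0, abs=1e-12)

    def test_diatomic_stretch_gives_delta(self):
        a = chain(2, spacing=1.5)
        b = chain(2, spacing=1.5 + 0.3)
        assert distance_matrix_rmsd(a, b) == pytest.approx(0.3)

    def test_pseudo_metric_triangle_inequality(self, rng):
        from conftest import random_structure

        for _ in range(10):
            x, y, z = (random_structure(rng, natoms=4) for _ in range(3))
            dxy = distance_matrix_rmsd(x, y)
            dyz = distance_matrix_rmsd(y, z)
            dxz = distance_matrix_rmsd(x, z)
            assert dxz <= dxy + dyz + 1e-12
            assert dxy == pytest.approx(distance_matrix_rmsd(y, x))

    def test_element_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix_rmsd(chain(2), chain(2, elements=["C", "O"]))


class TestRotateConformers:
    def test_trivial_grid_returns_single_relaxed_input(self, pseudo_bundle):
        s = pseudo_bundle.seeds[0]
        pair = ActivePair(i=0, j=2, action="form")
        out = rotate_conformers(s, pair, RotationGrid(1, 1), pseudo_bundle.uparams,
                                e_thresh=0.01, rmsd_thresh=0.1,
                                calc=pseudo_bundle.backend)
        assert len(out) == 1

    def test_symmetric_duplicates_pruned_and_energies_windowed(self, pseudo_bundle):
        s = pseudo_bundle.seeds[0]
        pair = ActivePair(i=0, j=2, action="form")
        e_thresh = 0.01
        out = rotate_conformers(s, pair, RotationGrid(4, 4), pseudo_bundle.uparams,
                                e_thresh=e_thresh, rmsd_thresh=0.1,
                                calc=pseudo_bundle.backend)
        energies = [c.meta["energy"] for c in out]
        assert energies == sorted(energies)
        assert max(energies) <= min(energies) + e_thresh + 1e-12
        for a in range(len(out)):
            for b in range(a + 1, len(out)):
                assert distance_matrix_rmsd(out[a], out[b]) >= 0.1

    def test_exhaustive_filter_predicate(self, pseudo_bundle):
        # every grid candidate either survives or is above the window / redundant
        s = pseudo_bundle.seeds[0]
        pair = ActivePair(i=0, j=2, action="form")
        grid = RotationGrid(8, 8)
        out = rotate_conformers(s, pair, grid, pseudo_bundle.uparams,
                                e_thresh=0.005, rmsd_thresh=0.05,
                                calc=pseudo_bundle.backend)
        assert 1 <= len(out) <= grid.spin_steps * grid.orbit_steps
        emin = out[0].meta["energy"]
        assert all(c.meta["energy"] <= emin + 0.005 + 1e-12 for c in out)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            RotationGrid(spin_steps=0)


def chfclbr():
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    p = UParams()
    els = ["C", "H", "F", "Cl", "Br"]
    coords = np.vstack([[0, 0, 0]] + [d * p.reference_length("C", e)
                                      for d, e in zip(dirs, els[1:])])
    return Structure(els, coords)


class TestChirality:
    def test_methane_like_has_no_centers(self):
        dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        s = Structure(["C", "H", "H", "H", "H"], np.vstack([[0, 0, 0], dirs * 1.1]))
        assert detect_chiral_centers(s) == []

    def test_single_center_parity_flips_under_mirror(self):
        s = chfclbr()
        tags = detect_chiral_centers(s)
        assert len(tags) == 1 and tags[0].atom == 0
        mirrored = detect_chiral_centers(s.mirrored())
        assert mirrored[0].parity != tags[0].parity

    def test_two_center_parities_match_signed_volume_oracle(self):
        # two stereocenters bridged by a C-C bond, each with H/F/Cl substituents
        p = UParams()
        d = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        d /= np.linalg.norm(d, axis=1)[:, None]
        c0 = np.zeros(3)
        c1 = d[0] * p.reference_length("C", "C")
        els = ["C", "C", "H", "F", "Cl", "H", "F", "Cl"]
        coords = np.vstack([
            c0, c1,
            c0 + d[1] * p.reference_length("C", "H"),
            c0 + d[2] * p.reference_length("C", "F"),
            c0 + d[3] * p.reference_length("C", "Cl"),
            c1 - d[1] * p.reference_length("C", "H"),
            c1 - d[2] * p.reference_length("C", "F"),
            c1 - d[3] * p.reference_length("C", "Cl"),
        ])
        s = Structure(els, coords)
        tags = detect_chiral_centers(s)
        assert [t.atom for t in tags] == [0, 1]

        # independent oracle: signed volume over priority-ordered neighbors
        from rdkit import Chem

        pt = Chem.GetPeriodicTable()
        from rxnpath.potentials import connectivity

        g = connectivity(s)
        for tag in tags:
            nbs = sorted(g.neighbors(tag.atom),
                         key=lambda n: pt.GetAtomicNumber(s.elements[n]), reverse=True)
            v = [s.coords[n] - s.coords[tag.atom] for n in nbs[:3]]
            vol = np.dot(np.cross(v[0], v[1]), v[2])
            assert tag.parity == ("R" if vol > 0 else "S")

    def test_achiral_molecule_yields_no_enantiomer(self, uparams):
        s = chain(3)
        assert generate_enantiomers(s, uparams) == []

    def test_chiral_molecule_yields_one_equal_energy_enantiomer(self, uparams):
        from rxnpath.potentials import UPotentialBackend, bond_list

        s = u_relax(chfclbr(), uparams)
        calc = UPotentialBackend(bonds=bond_list(s), params=uparams)
        out = generate_enantiomers(s, uparams)
        assert len(out) == 1
        assert calc.energy(out[0]) == pytest.approx(calc.energy(s), abs=1e-8)

    def test_meso_like_mirror_coincides(self, uparams):
        # two centers of opposite parity related by inversion: the mirror is the
        # same stereoisomer, so no enantiomer is emitted
        p = UParams()
        d = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        d /= np.linalg.norm(d, axis=1)[:, None]
        c0 = np.zeros(3)
        c1 = d[0] * p.reference_length("C", "C")
        half = [d[1] * p.reference_length("C", "H"),
                d[2] * p.reference_length("C", "F"),
                d[3] * p.reference_length("C", "Cl")]
        els = ["C", "C", "H", "F", "Cl", "H", "F", "Cl"]
        coords = np.vstack([c0, c1] + [c0 + v for v in half] + [c1 - v for v in half])
        s = Structure(els, coords)
        tags = detect_chiral_centers(s)
        assert len(tags) == 2 and tags[0].parity != tags[1].parity
        assert generate_enantiomers(s, uparams) == []

    def test_mirror_twice_restores_chiral_id(self):
        s = chfclbr()
        assert canonical_species_id(s.mirrored().mirrored(), chiral=True) \
            == canonical_species_id(s, chiral=True)


def make_step(reactant, product, e_ts=0.02):
    ts = TSCandidate(structure=reactant, energy=e_ts, nimag=1, validated=True)
    return ElementaryStep(
        reactant_id=canonical_species_id(reactant),
        product_id=canonical_species_id(product),
        reactant=reactant, product=product, ts=ts,
        barrier=e_ts, delta_e=0.0,
        pair=ActivePair(i=0, j=1, action="form"))


class TestRotationTest:
    def setup_method(self):
        self.r = chfclbr()
        # "product": stretch the C-Br bond a little (same connectivity class demo)
        c = self.r.coords.copy()
        c[4] *= 1.15
        self.p = self.r.with_coords(c)

    def test_rotated_copy_is_identical(self, rng):
        step1 = make_step(self.r, self.p)
        R = rotation_about_axis(rng.normal(size=3), 1.2)
        step2 = make_step(self.r.with_coords(self.r.coords @ R.T + 1.0),
                          self.p.with_coords(self.p.coords @ R.T + 1.0))
        assert rotation_test_classify(step1, step2) == "identical"

    def test_mirrored_copy_is_enantiomeric(self):
        step1 = make_step(self.r, self.p)
        step2 = make_step(self.r.mirrored(), self.p.mirrored())
        assert rotation_test_classify(step1, step2) == "enantiomeric"

    def test_different_connectivity_is_distinct(self):
        step1 = make_step(self.r, self.p)
        other = chain(5, elements=["C", "H", "F", "Cl", "Br"])
        step2 = make_step(other, other.with_coords(other.coords * 1.05))
        assert rotation_test_classify(step1, step2) == "distinct"
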