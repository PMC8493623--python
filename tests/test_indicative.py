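import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pixkit.elements import mass_of, vdw_radius
from pixkit.errors import MissingEnergyError, PixkitError
from pixkit.indicative_analysis import (HBondModel, build_driver_list,
                                        contact_fraction, detect_1d_motifs,
                                        detect_hbonds, hbond_energy,
                                        lattice_energy_estimate, run_indicative,
                                        weak_hbond_warning)
from pixkit.molecule_builder import Atom, Molecule
from pixkit.symmetry_pairs import (EnergyBreakdown, MolecularPair, OrtepCode,
                                   enumerate_pairs, image_molecule,
                                   pair_multiplicities)


def atom(element, x, y, z, label=""):
    return Atom(element=element, cart=(x, y, z), mass=mass_of(element),
                source_site=label)


class TestHBondEnergy:
    def test_limit_to_zero(self):
        assert hbond_energy(100.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_and_negative(self):
        e = [hbond_energy(d) for d in (1.7, 2.0, 2.5)]
        assert e[0] < e[1] < e[2] < 0

    def test_default_anchors(self):
        # anchors E(1.7) = -30 and E(2.2) = -10 solve to B = ln(3)/0.5
        b = math.log(3.0) / 0.5
        a = 30.0 * math.exp(1.7 * b)
        model = HBondModel()
        assert model.B == pytest.approx(b)
        assert model.A == pytest.approx(a)
        assert hbond_energy(1.7) == pytest.approx(-30.0)
        assert hbond_energy(2.2) == pytest.approx(-10.0)

    @given(st.floats(1.2, 5.0), st.floats(1.2, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_strict_monotonicity_property(self, d1, d2):
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        assert hbond_energy(lo) < hbond_energy(hi) < 0


class TestDetectHBonds:
    def _hbond_geometry(self):
        """O-H donor aimed at an acceptor O 1.8 A from H, angle 180."""
        donor = Molecule(atoms=[atom("O", 0, 0, 0, "Od"),
                                atom("H", 0.99, 0, 0, "H1")], bonds=[(0, 1)])
        acceptor = Molecule(atoms=[atom("O", 0.99 + 1.8, 0, 0, "Oa")],
                            residue_id=1)
        return donor, acceptor

    def test_inside_vdw_detected(self):
        from pixkit.indicative_analysis import _scan_hbonds
        donor, acceptor = self._hbond_geometry()
        found = _scan_hbonds(donor, acceptor, OrtepCode(0, 0, 1, 1), HBondModel())
        assert len(found) == 1
        hb = found[0]
        assert hb.d_ha == pytest.approx(1.8)
        assert hb.angle_dha == pytest.approx(180.0)
        assert hb.estimated_energy < 0

    def test_outside_vdw_not_detected(self):
        from pixkit.indicative_analysis import _scan_hbonds
        donor, _ = self._hbond_geometry()
        acceptor = Molecule(atoms=[atom("O", 0.99 + 2.9, 0, 0, "Oa")])
        assert _scan_hbonds(donor, acceptor, OrtepCode(0, 0, 1, 1),
                            HBondModel()) == []

    def test_bad_angle_rejected(self):
        from pixkit.indicative_analysis import _scan_hbonds
        donor, _ = self._hbond_geometry()
        # acceptor at 90 degrees from the O-H direction, 1.8 A from H
        acceptor = Molecule(atoms=[atom("O", 0.99, 1.8, 0, "Oa")])
        assert _scan_hbonds(donor, acceptor, OrtepCode(0, 0, 1, 1),
                            HBondModel()) == []

    def test_screw_chain_fixture(self, toys, toy_molecules):
        table = enumerate_pairs(toys["screw_chain"].structure,
                                toy_molecules["screw_chain"], cutoff=10)
        hbonds = detect_hbonds(table)
        assert hbonds, "planted H bond not found"
        # every detected bond is O-H...O at the planted geometry
        assert {hb.donor_label for hb in hbonds} == {"O1"}
        assert {hb.acceptor_label for hb in hbonds} == {"O1"}

    def test_matches_brute_force_scan(self, toys, toy_molecules):
        """Oracle: exhaustive donor-H/acceptor triple scan over image atoms."""
        name = "screw_chain"
        structure = toys[name].structure
        mols = toy_molecules[name]
        table = enumerate_pairs(structure, mols, cutoff=10)
        found = {(hb.h_label, hb.acceptor_label, str(hb.code),
                  round(hb.d_ha, 6))
                 for hb in detect_hbonds(table)}
        expected = set()
        # manual scan in both directions for every pair
        for p in table:
            ref = mols[p.ref_residue - 1]
            img = image_molecule(structure, mols[p.neighbor_residue - 1],
                                 p.code.op_index, p.code.translation)
            for dmol, amol in ((ref, img), (img, ref)):
                for hi, h in enumerate(dmol.atoms):
                    if h.element != "H":
                        continue
                    dheavy = [dmol.atoms[j] for a, b in dmol.bonds
                              for j in (a, b)
                              if hi in (a, b) and j != hi]
                    if not dheavy or dheavy[0].element not in "NOSF":
                        continue
                    for acc in amol.atoms:
                        if acc.element not in {"N", "O", "S", "F", "Cl"}:
                            continue
                        d_ha = float(np.linalg.norm(h.pos - acc.pos))
                        if d_ha >= vdw_radius("H") + vdw_radius(acc.element):
                            continue
                        v1 = dheavy[0].pos - h.pos
                        v2 = acc.pos - h.pos
                        cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                                   * np.linalg.norm(v2))
                        if math.degrees(math.acos(np.clip(cosang, -1, 1))) < 120:
                            continue
                        expected.add((h.source_site, acc.source_site,
                                      str(p.code), round(d_ha, 6)))
        assert found == expected


class TestContactFraction:
    def test_two_atoms_in_contact(self):
        a = Molecule(atoms=[atom("C", 0, 0, 0)])
        b = Molecule(atoms=[atom("C", 2.0, 0, 0)])
        assert contact_fraction(a, b) == (1.0, 1.0)

    def test_two_atoms_far(self):
        a = Molecule(atoms=[atom("C", 0, 0, 0)])
        b = Molecule(atoms=[atom("C", 10.0, 0, 0)])
        assert contact_fraction(a, b) == (0.0, 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        a = Molecule(atoms=[atom("C", *p) for p in rng.uniform(0, 5, (20, 3))])
        b = Molecule(atoms=[atom("O", *p) for p in rng.uniform(3, 8, (20, 3))])
        fr, fn = contact_fraction(a, b, margin=1.0)
        thr_co = vdw_radius("C") + vdw_radius("O") + 1.0
        na = sum(1 for x in a.atoms
                 if any(np.linalg.norm(x.pos - y.pos) < thr_co for y in b.atoms))
        nb = sum(1 for y in b.atoms
                 if any(np.linalg.norm(x.pos - y.pos) < thr_co for x in a.atoms))
        assert fr == pytest.approx(na / 20)
        assert fn == pytest.approx(nb / 20)

    def test_monotone_in_margin(self):
        rng = np.random.default_rng(3)
        a = Molecule(atoms=[atom("C", *p) for p in rng.uniform(0, 6, (15, 3))])
        b = Molecule(atoms=[atom("C", *p) for p in rng.uniform(4, 10, (15, 3))])
        fracs = [contact_fraction(a, b, margin=m)[0]
                 for m in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert fracs == sorted(fracs)

    def test_margin_zero_is_strict_vdw(self):
        a = Molecule(atoms=[atom("C", 0, 0, 0)])
        near = Molecule(atoms=[atom("C", 3.3, 0, 0)])    # < 3.4 vdW sum
        far = Molecule(atoms=[atom("C", 3.5, 0, 0)])     # > 3.4
        assert contact_fraction(a, near, margin=0.0) == (1.0, 1.0)
        assert contact_fraction(a, far, margin=0.0) == (0.0, 0.0)

    def test_negative_margin_rejected(self):
        a = Molecule(atoms=[atom("C", 0, 0, 0)])
        with pytest.raises(PixkitError):
            contact_fraction(a, a, margin=-0.1)


class TestMotifs:
    def test_translation_stack(self, toys, toy_molecules):
        rep = run_indicative(toys["translation_stack"].structure,
                             toy_molecules["translation_stack"], cutoff=15)
        stacks = [m for m in rep.motifs if m.kind == "vdw-stack"]
        assert any(m.direction == (1, 0, 0) and m.period == 1 for m in stacks)

    def test_inversion_dimer_no_motif(self, toys, toy_molecules):
        rep = run_indicative(toys["inversion_dimer"].structure,
                             toy_molecules["inversion_dimer"], cutoff=15)
        assert rep.motifs == []

    def test_screw_chain_period_two(self, toys, toy_molecules):
        rep = run_indicative(toys["screw_chain"].structure,
                             toy_molecules["screw_chain"], cutoff=15)
        chains = [m for m in rep.motifs if m.kind == "hbond-chain"]
        assert any(m.direction == (0, 1, 0) and m.period == 2 for m in chains)

    def test_supercell_percolation_oracle(self, toys, toy_molecules):
        """Brute force: build 5 molecules by composing the screw op and check
        they form a single H-bond-connected chain advancing along b."""
        from pixkit.cif_io import frac_to_cart
        structure = toys["screw_chain"].structure
        mol = toy_molecules["screw_chain"][0]
        op = structure.operation(2)
        cell = structure.cell
        # explicit chain: g^k images for k = 0..4
        images = []
        for k in range(5):
            m = mol
            for _ in range(k):
                m = image_molecule(structure, m, 2, (0, 0, 0))
            images.append(m)
        # consecutive images must be H-bond linked (O...O inside vdW + H)
        for m1, m2 in zip(images, images[1:]):
            o1 = [a for a in m1.atoms if a.element == "O"][0]
            o2 = [a for a in m2.atoms if a.element == "O"][0]
            assert np.linalg.norm(o1.pos - o2.pos) < 3.1
        # image 2 is the pure +b translate of image 0 (period 2)
        delta = images[2].centroid() - images[0].centroid()
        np.testing.assert_allclose(delta, frac_to_cart(cell, (0, 1, 0)),
                                   atol=1e-9)


class TestDriversAndEstimate:
    def test_driver_union_and_dedup(self):
        hb = []
        model = HBondModel()

        def mk_hb(code, d):
            from pixkit.indicative_analysis import HydrogenBond
            return HydrogenBond("O1", "H1", "O2", 1, 1, d, d + 1.0, 170.0,
                                hbond_energy(d, model), code)

        from pixkit.indicative_analysis import ContactRecord
        hbonds = [mk_hb(OrtepCode(0, 0, 0, 2), 1.8),
                  mk_hb(OrtepCode(0, 1, 0, 1), 2.0)]
        contacts = [
            ContactRecord(OrtepCode(0, 1, 0, 1), 1, 1, 0.5, 0.5, 1.0),  # overlap
            ContactRecord(OrtepCode(1, 0, 0, 1), 1, 1, 0.4, 0.4, 1.0),
            ContactRecord(OrtepCode(0, 0, 1, 1), 1, 1, 0.05, 0.05, 1.0),  # weak
        ]
        drivers = build_driver_list(hbonds, contacts, driver_threshold=0.2)
        codes = [c for c, _ in drivers]
        assert len(codes) == 3
        # strongest H bond first, contact-only pair last
        assert codes[0] == "55502"
        assert codes[-1] == "65501"

    def test_empty_driver_list(self):
        assert build_driver_list([], []) == []

    def test_estimate_six_neighbors(self):
        e = EnergyBreakdown(0, 0, 0, 0, -10.0)
        pairs = [MolecularPair(1, 1, OrtepCode(1, 0, 0, 1), 5.0,
                               multiplicity=6, energy=e)]
        assert lattice_energy_estimate(pairs) == pytest.approx(-30.0)

    def test_estimate_empty(self):
        assert lattice_energy_estimate([]) == 0.0

    def test_estimate_missing_energy_raises(self):
        p = MolecularPair(1, 1, OrtepCode(1, 0, 0, 1), 5.0)
        with pytest.raises(MissingEnergyError):
            lattice_energy_estimate([p])

    def test_two_residue_bookkeeping(self):
        # residue 1 sees pair A (x2, -8); residue 2 sees pair B (x4, -3);
        # the A/B cross pair contributes a row to each residue (-5 each).
        ea = EnergyBreakdown(0, 0, 0, 0, -8.0)
        eb = EnergyBreakdown(0, 0, 0, 0, -3.0)
        ex = EnergyBreakdown(0, 0, 0, 0, -5.0)
        pairs = [
            MolecularPair(1, 1, OrtepCode(1, 0, 0, 1), 5.0, 2, ea),
            MolecularPair(2, 2, OrtepCode(0, 1, 0, 1), 6.0, 4, eb),
            MolecularPair(1, 2, OrtepCode(0, 0, 0, 2), 4.0, 1, ex),
            MolecularPair(2, 1, OrtepCode(0, 0, 0, 2), 4.0, 1, ex),
        ]
        # per-residue half sums: r1: (2*-8 + -5)/2 = -10.5; r2: (4*-3 + -5)/2 = -8.5
        expected = (-10.5 + -8.5) / 2
        assert lattice_energy_estimate(pairs) == pytest.approx(expected)

    def test_inverse_twin_invariance(self, toys, toy_molecules):
        toy = toys["p21c_small"]
        table = enumerate_pairs(toy.structure, toy_molecules["p21c_small"],
                                cutoff=10)
        grouped = pair_multiplicities(table)
        rng = np.random.default_rng(5)
        for p in grouped.pairs:
            v = float(rng.uniform(-20, -1))
            p.energy = EnergyBreakdown(0, 0, 0, 0, v)
        e1 = lattice_energy_estimate(grouped)
        # replace each representative by its inverse-code twin: same distance,
        # same energy, swapped residues
        from pixkit.symmetry_pairs import inverse_code
        twins = [MolecularPair(p.neighbor_residue, p.ref_residue,
                               inverse_code(p.code, toy.structure),
                               p.centroid_distance, p.multiplicity, p.energy)
                 for p in grouped.pairs]
        assert lattice_energy_estimate(twins) == pytest.approx(e1)


class TestWeakWarnings:
    def _bond(self, energy):
        from pixkit.indicative_analysis import HydrogenBond
        return HydrogenBond("O1", "H1", "O2", 1, 1, 2.0, 2.8, 170.0, energy,
                            OrtepCode(0, 0, 0, 1))

    def test_weak_warned(self):
        assert len(weak_hbond_warning([self._bond(-5.0)])) == 1

    def test_strong_not_warned(self):
        assert weak_hbond_warning([self._bond(-30.0)]) == []

    def test_boundary_strict(self):
        assert weak_hbond_warning([self._bond(-10.0)]) == []
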