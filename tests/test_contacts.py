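"""Contact typing, strand classification, buried interface areas."""

import numpy as np
import pytest

from zlattice import (
    RESIDUE_ROLES,
    Structure,
    classify_strand,
    detect_anchor,
    find_contacts,
    interface_area,
    protein_protein_interface,
)
from zlattice.structure import AtomRecord, Chain, Residue

from conftest import random_rigid


def make_residue(chain, name, number, atoms):
    res = Residue(name, number)
    for i, (atom_name, pos) in enumerate(atoms):
        res.atoms.append(
            AtomRecord(
                i + 1, atom_name, atom_name[0], name, number, chain,
                np.asarray(pos, dtype=float),
            )
        )
    return res


def two_group_structure(res_a, res_b, waters=()):
    st = Structure()
    ca, cb, cw = Chain("A"), Chain("B"), Chain("W")
    ca.residues.extend(res_a)
    cb.residues.extend(res_b)
    for i, pos in enumerate(waters):
        cw.residues.append(make_residue("W", "HOH", i + 1, [("O", pos)]))
    st.chains = [ca, cb] + ([cw] if waters else [])
    return st


def atoms_of(st, chain_id):
    return [a for r in st.chain(chain_id).residues for a in r.atoms]


class TestFindContacts:
    def test_planted_hbond(self):
        # lysine NZ donor 2.9 A from a phosphate OP1 acceptor
        ra = [make_residue("A", "LYS", 1, [("NZ", [0, 0, 0])])]
        rb = [make_residue("B", "DG", 1, [("OP1", [2.9, 0, 0])])]
        st = two_group_structure(ra, rb)
        recs = find_contacts(st, atoms_of(st, "A"), atoms_of(st, "B"))
        kinds = {r.kind for r in recs}
        assert "hbond" in kinds
        hb = next(r for r in recs if r.kind == "hbond")
        assert hb.atoms == ("NZ", "OP1")
        assert hb.distances[0] == pytest.approx(2.9)

    def test_beyond_cutoffs_nothing(self):
        ra = [make_residue("A", "LYS", 1, [("NZ", [0, 0, 0])])]
        rb = [make_residue("B", "DG", 1, [("OP1", [5.0, 0, 0])])]
        st = two_group_structure(ra, rb)
        assert find_contacts(st, atoms_of(st, "A"), atoms_of(st, "B")) == []

    def test_vdw_only_between_apolar(self):
        ra = [make_residue("A", "PHE", 1, [("CZ", [0, 0, 0])])]
        rb = [make_residue("B", "DG", 1, [("C8", [3.8, 0, 0])])]
        st = two_group_structure(ra, rb)
        recs = find_contacts(st, atoms_of(st, "A"), atoms_of(st, "B"))
        assert [r.kind for r in recs] == ["vdw"]

    def test_water_mediated_bridge(self):
        ra = [make_residue("A", "TRP", 1, [("NE1", [0, 0, 0])])]
        rb = [make_residue("B", "DG", 1, [("OP2", [5.6, 0, 0])])]
        st = two_group_structure(ra, rb, waters=[[2.8, 0, 0]])
        recs = find_contacts(st, atoms_of(st, "A"), atoms_of(st, "B"))
        wm = [r for r in recs if r.kind == "water_mediated"]
        assert len(wm) == 1
        assert len(wm[0].distances) == 2
        assert wm[0].water == ("W", 1)

    def test_empty_selection(self):
        ra = [make_residue("A", "LYS", 1, [("NZ", [0, 0, 0])])]
        st = two_group_structure(ra, [])
        assert find_contacts(st, atoms_of(st, "A"), []) == []

    def test_disjoint_groups_required(self):
        ra = [make_residue("A", "LYS", 1, [("NZ", [0, 0, 0])])]
        st = two_group_structure(ra, [])
        sel = atoms_of(st, "A")
        with pytest.raises(ValueError):
            find_contacts(st, sel, sel)

    def test_invariant_under_rigid_motion_and_reorder(self):
        rng = np.random.default_rng(21)
        ra = [make_residue("A", "ARG", 1,
                           [("NH1", [0, 0, 0]), ("NH2", [1.0, 1.0, 0])])]
        rb = [make_residue("B", "DG", 1,
                           [("OP1", [3.0, 0, 0]), ("OP2", [-2.8, 0.5, 0])])]
        st = two_group_structure(ra, rb)
        before = find_contacts(st, atoms_of(st, "A"), atoms_of(st, "B"))
        g = random_rigid(rng)
        st2 = st.transformed(g)
        ga = list(reversed(atoms_of(st2, "A")))
        gb = list(reversed(atoms_of(st2, "B")))
        after = find_contacts(st2, ga, gb)
        assert [(r.kind, r.atoms) for r in before] == [(r.kind, r.atoms) for r in after]
        for x, y in zip(before, after):
            assert x.distances[0] == pytest.approx(y.distances[0], abs=1e-9)

    def test_chpi_detected_via_contacts(self, fixture_6p3):
        cplx, domains, _ = fixture_6p3
        mono = domains[0].chain
        ga = [a for r in mono.residues for a in r.atoms]
        gb = [a for c in cplx.nucleic_chains() for r in c.residues for a in r.atoms]
        recs = find_contacts(cplx, ga, gb)
        assert any(r.kind == "ch_pi" for r in recs)


class TestClassifyStrand:
    def test_primary_secondary_and_na(self, fixture_6p3):
        cplx, domains, _ = fixture_6p3
        anchors = detect_anchor(cplx)
        anchor = anchors[0]  # chain C, anchored on strand A
        recs = [
            # contact to the anchor G itself
            _fake_dna_contact(("A", "DG", 1)),
            # contact to its Watson-Crick partner on the other chain
            _fake_dna_contact(("B", "DC", 12)),
            # contact outside the duplex
            _fake_dna_contact(("Q", "DG", 1)),
        ]
        with pytest.warns(UserWarning, match="outside the duplex"):
            out = classify_strand(recs, anchor, cplx)
        assert [r.strand_class for r in out] == ["primary", "secondary", "n/a"]

    def test_protein_partner_untouched(self, fixture_6p3):
        cplx, _, _ = fixture_6p3
        anchor = detect_anchor(cplx)[0]
        rec = _fake_dna_contact(("D", "ALA", 5))
        out = classify_strand([rec], anchor, cplx)
        assert out[0].strand_class == "n/a"  # not a DNA partner; left as-is


def _fake_dna_contact(partner):
    from zlattice.contacts import ContactRecord

    return ContactRecord(
        kind="hbond",
        protein_residue=("C", "LYS", 1),
        partner=partner,
        atoms=("NZ", "OP1"),
        distances=(2.9,),
    )


class TestProteinProteinInterface:
    def test_planted_salt_bridge(self):
        ra = [make_residue("A", "GLU", 36,
                           [("OE1", [0, 0, 0]), ("OE2", [0.5, 1.0, 0])])]
        rb = [make_residue("B", "ARG", 42, [("NH1", [3.0, 0, 0])])]
        st = two_group_structure(ra, rb)
        recs = protein_protein_interface(st, "A", "B")
        assert any(r.kind == "salt_bridge" for r in recs)
        assert all(r.strand_class == "protein-protein" for r in recs)

    def test_salt_bridge_gone_at_6A(self):
        ra = [make_residue("A", "GLU", 36, [("OE1", [0, 0, 0])])]
        rb = [make_residue("B", "ARG", 42, [("NH1", [6.0, 0, 0])])]
        st = two_group_structure(ra, rb)
        assert protein_protein_interface(st, "A", "B") == []

    def test_dyad_symmetric_pair_mirrors(self):
        """A dyad-related Glu/Arg pair produces the mirrored records."""
        dyad_axis = np.array([1.0, 0, 0])
        from zlattice import RigidTransform

        dyad = RigidTransform.from_axis_angle(dyad_axis, 180.0)
        glu_atoms = [("OE1", [2.0, 1.4, 0.5]), ("OE2", [2.5, 2.3, 0.4])]
        arg_atoms = [("NH1", [2.2, -1.2, -0.6]), ("NE", [2.8, -2.0, -1.4])]
        ra = [
            make_residue("A", "GLU", 36, glu_atoms),
            make_residue("A", "ARG", 42,
                         [(n, dyad.apply(np.array(p))) for n, p in arg_atoms]),
        ]
        rb = [
            make_residue("B", "ARG", 42, arg_atoms),
            make_residue("B", "GLU", 36,
                         [(n, dyad.apply(np.array(p))) for n, p in glu_atoms]),
        ]
        st = two_group_structure(ra, rb)
        recs = protein_protein_interface(st, "A", "B")
        bridges = {
            (r.protein_residue[1:], r.partner[1:])
            for r in recs if r.kind == "salt_bridge"
        }
        # symmetric salt bridges: Glu(A)-Arg(B) and Arg(A)-Glu(B)
        assert (("GLU", 36), ("ARG", 42)) in bridges
        assert (("ARG", 42), ("GLU", 36)) in bridges


class TestResidueRoles:
    def test_roles_match_interface_map(self):
        assert set(RESIDUE_ROLES["triad"]) == {"TYR45", "ASN41", "TRP65"}
        # roles disjoint except Arg42 (primary-strand DNA + dimer contact)
        overlap = set(RESIDUE_ROLES["primary"]) & set(RESIDUE_ROLES["protein_protein"])
        assert overlap == {"ARG42"}
        assert not set(RESIDUE_ROLES["secondary"]) & set(RESIDUE_ROLES["primary"])


def mc_buried(coords, radii, split, probe, n=30000, seed=1):
    """Monte-Carlo buried-area oracle: SASA(A)+SASA(B)-SASA(AB)."""
    rng = np.random.default_rng(seed)

    def sasa(idx):
        total = 0.0
        exp = radii + probe
        for i in idx:
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = coords[i] + exp[i] * v
            free = np.ones(n, dtype=bool)
            for j in idx:
                if j == i:
                    continue
                free &= np.linalg.norm(pts - coords[j], axis=1) >= exp[j]
            total += free.mean() * 4 * np.pi * exp[i] ** 2
        return total

    a_idx = list(range(split))
    b_idx = list(range(split, len(coords)))
    return sasa(a_idx) + sasa(b_idx) - sasa(a_idx + b_idx)


class TestInterfaceArea:
    def _structure(self, pa, pb):
        ra = [make_residue("A", "ALA", i + 1, [("CA", p)]) for i, p in enumerate(pa)]
        rb = [make_residue("B", "ALA", i + 1, [("CA", p)]) for i, p in enumerate(pb)]
        return two_group_structure(ra, rb)

    def test_far_groups_zero(self):
        st = self._structure([[0, 0, 0]], [[100.0, 0, 0]])
        rep = interface_area(st, atoms_of(st, "A"), atoms_of(st, "B"))
        assert rep.bsa_total == pytest.approx(0.0, abs=1e-9)

    def test_touching_spheres_match_monte_carlo(self):
        # centers just inside contact range: small positive buried area
        sep = 1.70 + 1.70 + 2 * 1.4 - 1.0
        st = self._structure([[0, 0, 0]], [[sep, 0, 0]])
        rep = interface_area(st, atoms_of(st, "A"), atoms_of(st, "B"), n_points=3840)
        coords = np.array([[0.0, 0, 0], [sep, 0, 0]])
        ref = mc_buried(coords, np.array([1.7, 1.7]), 1, 1.4, n=60000)
        assert rep.bsa_total > 0
        assert rep.bsa_total == pytest.approx(ref, rel=0.02)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(2)
        pa = rng.uniform(0, 8, size=(6, 3))
        pb = rng.uniform(4, 12, size=(6, 3))
        st = self._structure(pa, pb)
        r1 = interface_area(st, atoms_of(st, "A"), atoms_of(st, "B"))
        r2 = interface_area(st, atoms_of(st, "B"), atoms_of(st, "A"))
        assert r1.interface_area == pytest.approx(r2.interface_area, abs=1e-9)
        assert r1.interface_area == pytest.approx(r1.bsa_total / 2)

    def test_per_residue_sums_to_total(self, fixture_6p3):
        cplx, domains, _ = fixture_6p3
        mono = domains[0].chain
        ga = [a for r in mono.residues for a in r.atoms]
        gb = [a for c in cplx.nucleic_chains() for r in c.residues for a in r.atoms]
        rep = interface_area(cplx, ga, gb, n_points=240)
        assert sum(rep.per_residue.values()) == pytest.approx(rep.bsa_total, rel=0.01)

    def test_overlapping_selections_rejected(self, fixture_6p3):
        cplx, domains, _ = fixture_6p3
        ga = [a for r in domains[0].chain.residues for a in r.atoms]
        with pytest.raises(ValueError, match="verlapping"):
            interface_area(cplx, ga, ga)
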