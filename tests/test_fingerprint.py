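"""Ligand typing, h-bond / hydrophobic detection, fingerprint assembly."""

import numpy as np
import pytest

from protomerscope import (
    build_fingerprint,
    detect_hbonds,
    detect_hydrophobic,
    has_glu501_hbond,
    make_protomer,
    ScaffoldSpec,
    type_ligand_atoms,
)
from protomerscope.fingerprint import (
    H_ACCEPTOR,
    H_DONOR,
    HYDROPHOBIC,
    ligand_glu501_min_distance,
)

from conftest import random_rotation, toy_structure


def amide_ligand(offset=np.zeros(3)):
    """Minimal amide fragment: N1 (donor) — C2 (carbonyl C) = O2 (acceptor)."""
    return [
        (900, "LIG", "N1", "N", offset + [0.0, 0.0, 0.0]),
        (900, "LIG", "C2", "C", offset + [1.35, 0.0, 0.0]),
        (900, "LIG", "O2", "O", offset + [2.0, 1.0, 0.0]),
    ]


def benzene_ligand(center, radius=1.39):
    ring = []
    for i in range(6):
        ang = np.radians(60 * i)
        ring.append(
            (901, "BNZ", f"C{i + 1}", "C",
             center + radius * np.array([np.cos(ang), np.sin(ang), 0.0]))
        )
    return ring


class TestTyping:
    def test_amide_nitrogen_donor_carbonyl_oxygen_acceptor(self):
        s = toy_structure(
            [(10, "GLY", "CA", "C", [50.0, 0.0, 0.0])], amide_ligand()
        )
        typing = type_ligand_atoms(s, "LIG")
        assert "N1" in typing.donor_atoms
        assert "O2" in typing.acceptor_atoms
        assert "O2" not in typing.donor_atoms  # carbonyl-length C=O
        assert typing.heavy_atoms == {"N1", "C2", "O2"}

    def test_benzene_ring_typed_aromatic(self):
        s = toy_structure(
            [(10, "GLY", "CA", "C", [50.0, 0.0, 0.0])],
            benzene_ligand(np.zeros(3)),
        )
        typing = type_ligand_atoms(s, "BNZ")
        assert typing.aromatic_atoms == {f"C{i}" for i in range(1, 7)}
        assert typing.donor_atoms == set()

    def test_override_strips_donor_role(self):
        s = toy_structure(
            [(10, "GLY", "CA", "C", [50.0, 0.0, 0.0])], amide_ligand()
        )
        typing = type_ligand_atoms(s, "LIG", overrides={"N1": set()})
        assert "N1" not in typing.donor_atoms
        typing2 = type_ligand_atoms(s, "LIG", overrides={"C2": {"acceptor"}})
        assert "C2" in typing2.acceptor_atoms

    def test_typing_deterministic(self):
        s = toy_structure(
            [(10, "GLY", "CA", "C", [50.0, 0.0, 0.0])], amide_ligand()
        )
        assert type_ligand_atoms(s, "LIG") == type_ligand_atoms(s, "LIG")


class TestHbonds:
    def _complex(self, n1_to_oe1=2.9):
        protein = [
            (501, "GLU", "CA", "C", [0.0, -30.0, 0.0]),
            (501, "GLU", "OE1", "O", [0.0, 0.0, 0.0]),
            (501, "GLU", "OE2", "O", [2.2, 0.0, 0.0]),
            (574, "HIS", "CA", "C", [0.0, 40.0, 0.0]),
            (574, "HIS", "O", "O", [1.0, 43.0, 0.0]),
        ]
        return toy_structure(protein, amide_ligand(np.array([0.0, n1_to_oe1, 0.0])))

    def test_ligand_donates_to_glutamate_carboxylate(self):
        s = self._complex(2.9)
        typing = type_ligand_atoms(s, "LIG")
        recs = detect_hbonds(s, "A", "LIG", typing)
        donors = [r for r in recs if r.interaction == H_DONOR and r.residue_id == 501]
        assert len(donors) == 1
        assert donors[0].min_distance == pytest.approx(2.9)
        assert donors[0].ligand_atom == "N1"

    @pytest.mark.parametrize("d, found", [(3.5, True), (3.51, False)])
    def test_inclusive_boundary(self, d, found):
        s = self._complex(d)
        typing = type_ligand_atoms(s, "LIG")
        recs = [r for r in detect_hbonds(s, "A", "LIG", typing)
                if r.interaction == H_DONOR and r.residue_id == 501]
        assert bool(recs) is found

    def test_donation_to_backbone_carbonyl(self):
        # donor amide placed 3.0 Å from the His574 backbone carbonyl oxygen
        protein = [
            (574, "HIS", "CA", "C", [0.0, 0.0, 0.0]),
            (574, "HIS", "C", "C", [1.5, 0.0, 0.0]),
            (574, "HIS", "O", "O", [2.2, 1.0, 0.0]),
        ]
        s = toy_structure(protein, amide_ligand(np.array([2.2, 4.0, 0.0])))
        typing = type_ligand_atoms(s, "LIG")
        recs = detect_hbonds(s, "A", "LIG", typing)
        assert any(
            r.interaction == H_DONOR and r.residue_id == 574 and r.protein_atom == "O"
            for r in recs
        )


class TestGlu501Hbond:
    @pytest.mark.parametrize(
        "d, formed", [(2.9, True), (3.5, True), (4.5, False), (6.0, False), (12.0, False)]
    )
    def test_distance_regimes(self, d, formed):
        s = make_protomer(ScaffoldSpec(ligand_glu501_distance=d))
        got, dist = has_glu501_hbond(s, "A", "LIG")
        assert got is formed
        assert dist == pytest.approx(d, abs=1e-9)

    def test_no_donor_ligand_never_forms(self):
        # carbon-only ligand next to the carboxylate: no donor, no h-bond
        protein = [
            (501, "GLU", "OE1", "O", [0.0, 0.0, 0.0]),
            (501, "GLU", "OE2", "O", [2.2, 0.0, 0.0]),
        ]
        lig = [(902, "VMX", "C1", "C", [0.0, 3.0, 0.0]),
               (902, "VMX", "C2", "C", [1.5, 3.2, 0.0])]
        s = toy_structure(protein, lig)
        formed, dist = has_glu501_hbond(s, "A", "VMX")
        assert formed is False and dist == np.inf


class TestHydrophobic:
    def test_dual_cutoff_aromatic_vs_plain(self):
        # aromatic(ligand ring) vs aromatic(PHE ring) pair at 4.2 Å: rejected;
        # the same distance with a plain apolar protein carbon: accepted
        protein = [
            (30, "PHE", "CG", "C", [0.0, 0.0, 0.0]),
            (30, "PHE", "CD1", "C", [1.39, 0.0, 0.0]),
            (30, "PHE", "CD2", "C", [-0.695, 1.2, 0.0]),
            (30, "PHE", "CE1", "C", [2.085, 1.2, 0.0]),
            (30, "PHE", "CE2", "C", [0.0, 2.4, 0.0]),
            (30, "PHE", "CZ", "C", [1.39, 2.4, 0.0]),
            (40, "LEU", "CD1", "C", [0.0, 0.0, 50.0]),
        ]
        ring_a = benzene_ligand(np.array([0.0, -1.2 - 4.2, 0.0]))  # 4.2 Å from CG
        s = toy_structure(protein, ring_a)
        typing = type_ligand_atoms(s, "BNZ")
        recs = detect_hydrophobic(s, "A", "BNZ", typing)
        assert not any(r.residue_id == 30 and r.min_distance < 4.3 for r in recs
                       if r.protein_atom == "CG")

        lig2 = [(903, "ALK", "C1", "C", [0.0, 0.0, 45.8])]  # 4.2 Å from LEU CD1
        s2 = toy_structure(protein, lig2)
        typing2 = type_ligand_atoms(s2, "ALK")
        recs2 = detect_hydrophobic(s2, "A", "ALK", typing2)
        hits = [r for r in recs2 if r.residue_id == 40]
        assert len(hits) == 1 and hits[0].min_distance == pytest.approx(4.2)

    def test_no_contact_beyond_cutoff(self):
        protein = [(40, "LEU", "CD1", "C", [0.0, 0.0, 0.0])]
        lig = [(903, "ALK", "C1", "C", [0.0, 0.0, 4.6])]
        s = toy_structure(protein, lig)
        typing = type_ligand_atoms(s, "ALK")
        assert detect_hydrophobic(s, "A", "ALK", typing) == []

    def test_apolar_contact_with_asn_sidechain_carbon(self):
        s = make_protomer(ScaffoldSpec())
        # place a ligand carbon 4.4 Å from the Asn500 CB apolar atom
        cb = s.atoms.coord[s.residue_atom_indices("A", 500, ["CB"])][0]
        coords = s.atoms.coord.copy()
        c3 = np.flatnonzero(s.atoms.atom_name == "C3")[0]
        coords[c3] = cb + np.array([0.0, 4.4, 0.0])
        moved = s.with_coordinates(coords)
        typing = type_ligand_atoms(moved, "LIG")
        recs = detect_hydrophobic(moved, "A", "LIG", typing)
        assert any(r.residue_id == 500 and r.interaction == HYDROPHOBIC for r in recs)


def brute_force_fingerprint(structure, protomer, ligand, typing, thresholds):
    """Independent all-pairs enumeration of the fingerprint record set."""
    from protomerscope.fingerprint import _protein_roles

    atoms = structure.atoms
    lig_idx = structure.ligand_indices(ligand)
    p_idx, p_don, p_acc, p_arom, p_apol = _protein_roles(structure, protomer)
    best = {}

    def consider(res, interaction, d, la, pa):
        key = (res, interaction)
        if key not in best or d < best[key][0]:
            best[key] = (d, la, pa)

    for li in lig_idx:
        lname = atoms.atom_name[li]
        for k, pi in enumerate(p_idx):
            d = float(np.linalg.norm(atoms.coord[li] - atoms.coord[pi]))
            res = int(atoms.res_id[pi])
            if lname in typing.donor_atoms and p_acc[k] and d <= thresholds.hbond_cutoff:
                consider(res, H_DONOR, d, lname, atoms.atom_name[pi])
            if lname in typing.acceptor_atoms and p_don[k] and d <= thresholds.hbond_cutoff:
                consider(res, H_ACCEPTOR, d, lname, atoms.atom_name[pi])
            lig_apolar = atoms.element[li].upper() == "C" or lname in typing.aromatic_atoms
            if lig_apolar and (p_apol[k] or p_arom[k]):
                cut = (
                    thresholds.hydrophobic_aromatic_cutoff
                    if lname in typing.aromatic_atoms and p_arom[k]
                    else thresholds.hydrophobic_cutoff
                )
                if d <= cut:
                    consider(res, HYDROPHOBIC, d, lname, atoms.atom_name[pi])
    return {k: v[0] for k, v in best.items()}


class TestFingerprint:
    def test_two_pair_fixture_yields_two_records(self):
        protein = [
            (501, "GLU", "OE1", "O", [0.0, 0.0, 0.0]),
            (501, "GLU", "OE2", "O", [2.2, 0.0, 0.0]),
            (40, "LEU", "CD1", "C", [0.0, 0.0, 50.0]),
        ]
        lig = amide_ligand(np.array([0.0, 3.0, 0.0])) + [
            (900, "LIG", "C9", "C", [0.0, 0.0, 46.0])
        ]
        s = toy_structure(protein, lig)
        fp = build_fingerprint(s, "A", "LIG")
        kinds = {(r.residue_id, r.interaction) for r in fp.records}
        assert (501, H_DONOR) in kinds
        assert (40, HYDROPHOBIC) in kinds

    def test_deterministic(self, holo_protomer):
        a = build_fingerprint(holo_protomer, "A", "LIG")
        b = build_fingerprint(holo_protomer, "A", "LIG")
        assert a == b

    def test_matches_bruteforce_on_random_fixtures(self):
        from protomerscope import DEFAULT_THRESHOLDS

        rng = np.random.default_rng(77)
        for _ in range(25):
            protein = [
                (10, "GLU", "OE1", "O", rng.normal(scale=4, size=3)),
                (10, "GLU", "OE2", "O", rng.normal(scale=4, size=3)),
                (14, "LYS", "NZ", "N", rng.normal(scale=4, size=3)),
                (20, "LEU", "CD1", "C", rng.normal(scale=4, size=3)),
                (24, "GLY", "O", "O", rng.normal(scale=4, size=3)),
                (24, "GLY", "N", "N", rng.normal(scale=4, size=3)),
            ]
            lig = amide_ligand(rng.normal(scale=4, size=3))
            s = toy_structure(protein, lig)
            typing = type_ligand_atoms(s, "LIG")
            fp = build_fingerprint(s, "A", "LIG", typing)
            got = {(r.residue_id, r.interaction): r.min_distance for r in fp.records}
            want = brute_force_fingerprint(s, "A", "LIG", typing, DEFAULT_THRESHOLDS)
            assert set(got) == set(want)
            for key in got:
                assert got[key] == pytest.approx(want[key], abs=1e-9)

    def test_invariant_under_rigid_motion_and_permutation(self, holo_protomer):
        rng = np.random.default_rng(9)
        base = build_fingerprint(holo_protomer, "A", "LIG")
        rot = random_rotation(rng)
        moved = holo_protomer.with_coordinates(
            holo_protomer.atoms.coord @ rot.T + rng.normal(scale=10, size=3)
        )
        fp = build_fingerprint(moved, "A", "LIG")
        assert [(r.residue_id, r.interaction) for r in fp.records] == [
            (r.residue_id, r.interaction) for r in base.records
        ]
        for ra, rb in zip(fp.records, base.records):
            assert ra.min_distance == pytest.approx(rb.min_distance, abs=1e-8)

    def test_records_respect_governing_cutoffs(self, holo_protomer):
        from protomerscope import DEFAULT_THRESHOLDS as thr

        fp = build_fingerprint(holo_protomer, "A", "LIG")
        for r in fp.records:
            cutoff = {
                H_DONOR: thr.hbond_cutoff,
                H_ACCEPTOR: thr.hbond_cutoff,
                HYDROPHOBIC: thr.hydrophobic_cutoff,
            }[r.interaction]
            assert r.min_distance <= cutoff

    def test_glu501_min_distance_matches_record(self, holo_protomer):
        d = ligand_glu501_min_distance(holo_protomer, "A", "LIG")
        assert d == pytest.approx(2.9, abs=1e-9)
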