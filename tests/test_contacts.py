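"""Structure parsing, polar-contact networks, B-factors and superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from conftest import make_ca_structure, random_ca_positions
from enzstab.contacts import (align_rmsd, kabsch_superpose,
                              ligand_polar_contacts, map_equivalent_residue,
                              normalized_bfactor, polar_partner_atoms,
                              read_structure, residue_network,
                              survey_salt_bridges, write_pdb)
from enzstab.synthetic import (ToyAtomSpec, ToyResidueSpec, ToyStructureSpec,
                               build_toy_structure)


def _pair_structure(distance, res_a="ARG", atom_a="NH1", res_b="GLU",
                    atom_b="OE1", b=20.0, chains=1):
    spec = ToyStructureSpec(residues=(
        ToyResidueSpec(res_a, 75, (ToyAtomSpec("CA", (0.0, 5.0, 0.0), b=b),
                                   ToyAtomSpec(atom_a, (0.0, 0.0, 0.0), b=b))),
        ToyResidueSpec(res_b, 349, (ToyAtomSpec("CA", (distance, 5.0, 0.0), b=b),
                                    ToyAtomSpec(atom_b, (distance, 0.0, 0.0), b=b))),
    ), chains=chains)
    return build_toy_structure(spec)


class TestPdbIO:
    def test_round_trip_preserves_geometry_and_b(self):
        st1, text = _pair_structure(3.0, b=17.5)
        st2 = read_structure(text)
        a = st2.find_residue("A", 75).atom("NH1")
        b = st2.find_residue("A", 349).atom("OE1")
        assert np.linalg.norm(a.pos - b.pos) == pytest.approx(3.0, abs=1e-3)
        assert a.b == pytest.approx(17.5)
        # serializing again reproduces the text
        assert write_pdb(st2) == text

    def test_altloc_highest_occupancy_kept(self):
        text = (
            "ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.50 10.00           C\n"
            "ATOM      2  CA BSER A   1       1.000   0.000   0.000  0.40 12.00           C\n"
            "ATOM      3  OG  SER A   1       2.000   0.000   0.000  1.00 11.00           O\n"
            "END\n")
        s = read_structure(text)
        ca = s.find_residue("A", 1).atom("CA")
        assert ca.pos[0] == pytest.approx(0.0)   # occ 0.50 beats 0.40
        assert len(s.find_residue("A", 1).atoms) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="ATOM"):
            read_structure("REMARK nothing here\nEND\n")

    def test_malformed_record_reports_line_number(self):
        text = ("ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00 10.00\n"
                "ATOM      2  CA  GLY A   2       bad.xyz  0.000   0.000  1.00 10.00\n")
        with pytest.raises(ValueError, match="line.*2"):
            read_structure(text)

    def test_waters_flagged(self):
        spec = ToyStructureSpec(residues=(
            ToyResidueSpec("GLY", 1, (ToyAtomSpec("CA", (0, 0, 0)),)),
            ToyResidueSpec("HOH", 501, (ToyAtomSpec("O", (5, 0, 0)),)),
        ))
        s, text = build_toy_structure(spec)
        parsed = read_structure(text)
        assert parsed.find_residue("A", 501).is_water


class TestPolarTable:
    def test_ala_backbone_only(self):
        spec = ToyStructureSpec(residues=(
            ToyResidueSpec("ALA", 1, (ToyAtomSpec("N", (0, 0, 0)),
                                      ToyAtomSpec("CA", (1, 0, 0)),
                                      ToyAtomSpec("O", (2, 0, 0)),
                                      ToyAtomSpec("CB", (3, 0, 0)))),))
        s, _ = build_toy_structure(spec)
        names = {a.name for a, _ in polar_partner_atoms(s.residues[0])}
        assert names == {"N", "O"}

    def test_glu_carboxylate_tagged_negative(self):
        _, text = _pair_structure(3.0)
        s = read_structure(text)
        tags = {a.name: t for a, t in polar_partner_atoms(s.find_residue("A", 349))}
        assert tags["OE1"] == -1

    def test_arg_guanidinium_tagged_positive(self):
        _, text = _pair_structure(3.0)
        s = read_structure(text)
        tags = {a.name: t for a, t in polar_partner_atoms(s.find_residue("A", 75))}
        assert tags["NH1"] == +1

    def test_unknown_residue_rejected(self):
        from enzstab.contacts import Residue
        with pytest.raises(ValueError, match="XYZ"):
            polar_partner_atoms(Residue(chain="A", name="XYZ", seqid=1))


class TestResidueNetwork:
    def test_salt_bridge_detected(self):
        s, _ = _pair_structure(3.0)
        edges = residue_network(s, "A", 75)
        assert len(edges) == 1
        assert edges[0].kind == "salt_bridge"
        assert edges[0].distance == pytest.approx(3.0, abs=1e-6)

    def test_cutoff_excludes_distant_pair(self):
        s, _ = _pair_structure(3.6)
        assert residue_network(s, "A", 75, cutoff=3.5) == []

    def test_his_contact_is_hydrogen_bond(self, active_site_wt):
        edges = residue_network(active_site_wt, "A", 75)
        kinds = {(e.atom_b, e.kind) for e in edges}
        assert ("A/THR 116/O", "hydrogen_bond") in kinds
        assert not any(e.kind == "salt_bridge" for e in edges)

    def test_his_charged_flag_creates_salt_bridge(self):
        s, _ = _pair_structure(3.0, res_a="HIS", atom_a="NE2")
        assert residue_network(s, "A", 75)[0].kind == "hydrogen_bond"
        assert residue_network(s, "A", 75, his_charged=True)[0].kind == "salt_bridge"

    def test_missing_residue_rejected(self):
        s, _ = _pair_structure(3.0)
        with pytest.raises(KeyError):
            residue_network(s, "A", 999)

    @given(st.floats(2.5, 5.0), st.floats(2.5, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_cutoff_monotonicity(self, c1, c2):
        lo, hi = sorted((c1, c2))
        s, _ = _pair_structure(3.2)
        e_lo = {(e.atom_a, e.atom_b) for e in residue_network(s, "A", 75, cutoff=lo)}
        e_hi = {(e.atom_a, e.atom_b) for e in residue_network(s, "A", 75, cutoff=hi)}
        assert e_lo <= e_hi


class TestLigandContacts:
    def _with_ligand(self, distance):
        spec = ToyStructureSpec(residues=(
            ToyResidueSpec("GLU", 349, (ToyAtomSpec("CA", (0, 5, 0)),
                                        ToyAtomSpec("OE1", (0, 0, 0)))),
            ToyResidueSpec("ALA", 10, (ToyAtomSpec("N", (40, 0, 0)),
                                       ToyAtomSpec("CA", (41, 0, 0)))),
        ), ligand=ToyResidueSpec("DNJ", 500,
                                 (ToyAtomSpec("O2", (distance, 0.0, 0.0)),
                                  ToyAtomSpec("C2", (distance + 1.2, 0.0, 0.0)))))
        return build_toy_structure(spec)[0]

    def test_contacting_residue_reported(self):
        out = ligand_polar_contacts(self._with_ligand(3.0), "DNJ")
        assert list(out) == ["A/GLU 349"]
        assert out["A/GLU 349"][0].distance == pytest.approx(3.0, abs=1e-6)

    def test_tiny_cutoff_empty(self):
        assert ligand_polar_contacts(self._with_ligand(3.0), "DNJ", cutoff=0.1) == {}

    def test_absent_ligand_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            ligand_polar_contacts(self._with_ligand(3.0), "NAG")

    def test_ligand_near_one_chain_only(self):
        # two chains 100 A apart, ligand bound at chain A's site
        spec = ToyStructureSpec(residues=(
            ToyResidueSpec("GLU", 349, (ToyAtomSpec("CA", (0, 5, 0)),
                                        ToyAtomSpec("OE1", (0, 0, 0)))),
        ), chains=2, ligand=ToyResidueSpec("DNJ", 500,
                                           (ToyAtomSpec("O2", (3.0, 0, 0)),)))
        s, _ = build_toy_structure(spec)
        out = ligand_polar_contacts(s, "DNJ")
        assert all(key.startswith("A/") for key in out)


class TestNormalizedBFactor:
    def test_uniform_b_gives_unity(self):
        s, _ = _pair_structure(3.0, b=20.0)
        rep = normalized_bfactor(s, [(75, "ARG"), (349, "GLU")])
        assert rep.cross_chain_combined == pytest.approx(1.0)

    def test_hand_ratio(self):
        # target side-chain B 30 against chain mean 20 -> 1.5
        spec = ToyStructureSpec(residues=(
            ToyResidueSpec("ASN", 163, (ToyAtomSpec("CA", (0, 0, 0), b=10.0),
                                        ToyAtomSpec("OD1", (1, 0, 0), b=30.0))),
            ToyResidueSpec("GLY", 1, (ToyAtomSpec("CA", (9, 0, 0), b=10.0),
                                      ToyAtomSpec("N", (8, 0, 0), b=30.0))),
        ))
        s, _ = build_toy_structure(spec)
        rep = normalized_bfactor(s, [(163, "ASN")])
        assert rep.chain_mean_b["A"] == pytest.approx(20.0)
        assert rep.per_chain_residue["A"][163] == pytest.approx(1.5)

    def test_identical_chains_match_single_chain(self):
        s1, _ = _pair_structure(3.0, b=25.0, chains=1)
        s3, _ = _pair_structure(3.0, b=25.0, chains=3)
        r1 = normalized_bfactor(s1, [(349, "GLU")])
        r3 = normalized_bfactor(s3, [(349, "GLU")])
        assert r3.cross_chain_combined == pytest.approx(r1.cross_chain_combined)
        assert set(r3.per_chain_combined) == {"A", "B", "C"}

    def test_whole_chain_target_all_atoms_is_exactly_one(self):
        s, _ = _pair_structure(3.0)
        rep = normalized_bfactor(s, [(75, "ARG"), (349, "GLU")],
                                 side_chain_only=False)
        assert rep.cross_chain_combined == 1.0

    def test_missing_target_named_in_error(self):
        s, _ = _pair_structure(3.0)
        with pytest.raises(ValueError, match="163"):
            normalized_bfactor(s, [(163, "ASN")])


class TestKabsch:
    def test_identity(self):
        pts = random_ca_positions(10, seed=1)
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_exact_recovery_of_rigid_motion(self):
        pts = random_ca_positions(25, seed=2)
        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        moved = (rot @ pts.T).T + np.array([1.0, -2.0, 3.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        ours = kabsch_superpose(a, b)
        # scipy's align_vectors is an independent Kabsch implementation
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        oracle = rssd / np.sqrt(len(a))
        assert ours.rmsd == pytest.approx(oracle, abs=1e-6)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestAlignRmsd:
    def test_identical_structures(self):
        seq = "ARNDCEQGHILKMFPSTWYV" * 3
        pos = random_ca_positions(len(seq), seed=3)
        s = make_ca_structure(seq, pos)
        res = align_rmsd(s, s)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_atoms_used == res.n_atoms_start == len(seq)

    def test_displaced_residue_rejected(self):
        seq = "ARNDCEQGHILKMFPSTWYV" * 5
        pos = random_ca_positions(len(seq), seed=4)
        s_a = make_ca_structure(seq, pos)
        pos_b = pos.copy()
        pos_b[42] += np.array([5.0, 0.0, 0.0])   # one residue shoved 5 A
        s_b = make_ca_structure(seq, pos_b)
        res = align_rmsd(s_a, s_b)
        assert res.n_atoms_used == len(seq) - 1
        assert res.rmsd < 0.05

    def test_rejection_never_increases_rmsd(self):
        seq = "ARNDCEQGHILKMFPSTWYV" * 5
        rng = np.random.default_rng(5)
        pos = random_ca_positions(len(seq), seed=5)
        s_a = make_ca_structure(seq, pos)
        s_b = make_ca_structure(seq, pos + rng.normal(0, 0.3, pos.shape))
        full = align_rmsd(s_a, s_b, cycles=0)       # no rejection
        trimmed = align_rmsd(s_a, s_b, cycles=5)
        assert trimmed.rmsd <= full.rmsd + 1e-12

    def test_sequence_pairing_handles_numbering_offset(self):
        seq = "ARNDCEQGHILKMFPSTWYV"
        pos = random_ca_positions(len(seq), seed=6)
        s_a = make_ca_structure(seq, pos, seqid_start=1)
        s_b = make_ca_structure(seq, pos, seqid_start=101)
        with pytest.raises(ValueError):            # label pairing finds no pairs
            align_rmsd(s_a, s_b, pairing="label")
        res = align_rmsd(s_a, s_b, pairing="sequence")
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)


class TestHomologSurvey:
    def test_mixed_homolog_set(self):
        arg_close, _ = _pair_structure(2.9)
        arg_far, _ = _pair_structure(3.2)
        his_var, _ = _pair_structure(3.0, res_a="HIS", atom_a="NE2")
        table = survey_salt_bridges([
            ("homolog1", arg_close, "A", 75, 349),
            ("homolog2", arg_far, "A", 75, 349),
            ("his_variant", his_var, "A", 75, 349),
        ])
        verdicts = dict(zip(table["structure"], table["salt_bridge_3.5A"]))
        assert verdicts == {"homolog1": True, "homolog2": True,
                            "his_variant": False}
        assert table["min_distance"].round(3).tolist() == [2.9, 3.2, 3.0]

    def test_unmapped_row_flagged_not_dropped(self):
        s, _ = _pair_structure(3.0)
        table = survey_salt_bridges([("ok", s, "A", 75, 349),
                                     ("lost", s, "A", None, 349)])
        assert len(table) == 2
        assert not table[table["structure"] == "lost"]["mapped"].iloc[0]

    def test_wider_cutoff_sensitivity_column(self):
        s, _ = _pair_structure(3.8)
        table = survey_salt_bridges([("x", s, "A", 75, 349)])
        row = table.iloc[0]
        assert not row["salt_bridge_3.5A"] and row["salt_bridge_4A"]


class TestMapEquivalentResidue:
    SEQ = "ARNDCEQGHILKMFPSTWYVVWYTSPFMKLIGQECDNRAD"   # 40 residues, non-repetitive

    def _structure(self, seq, seqid_start=1):
        return make_ca_structure(seq, random_ca_positions(len(seq), seed=7),
                                 seqid_start=seqid_start)

    def test_identity_mapping(self):
        s = self._structure(self.SEQ)
        assert map_equivalent_residue(self.SEQ, 9, s) == ("A", 9)

    def test_n_terminal_extension_shifts_by_one(self):
        s = self._structure("G" + self.SEQ)
        chain, num = map_equivalent_residue(self.SEQ, 9, s)
        assert num == 10

    def test_deleted_position_unmapped(self):
        # homolog lacking residue 9 (H): alignment puts a gap there
        homolog = self.SEQ[:8] + self.SEQ[9:]
        s = self._structure(homolog)
        assert map_equivalent_residue(self.SEQ, 9, s) is None
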