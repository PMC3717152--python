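import numpy as np
import pytest

from modelcheck.model_qc import (
    ChecklistEntry,
    HBondCriteria,
    check_disulfides,
    detect_cis_prolines,
    detect_clashes,
    detect_hbonds,
    load_default_checklist,
    ramachandran_classify,
    run_checklist,
)
from modelcheck.synthetic import BundleSpec, build_helix, make_bundle
from modelcheck.structure_io import Atom, Residue, Structure


def helix_structure(n_res, names=None, overrides=None, seq_start=1):
    from modelcheck.synthetic import _build_backbone

    bb = _build_backbone(n_res, -57.0, -47.0, overrides=overrides or {})
    st = Structure(id="helix")
    st.chains["A"] = [
        Residue(
            name=(names or ["ALA"] * n_res)[i],
            seq_number=seq_start + i,
            chain="A",
            atoms=[Atom(k, k[0], v) for k, v in res.items()],
        )
        for i, res in enumerate(bb)
    ]
    return st.validate()


class TestHBonds:
    def test_serine_asparagine_contact_within_cutoff(self, mini_builder, criteria):
        st = mini_builder([
            ("SER", 1, {"OG": [0, 0, 0]}),
            ("ASN", 2, {"OD1": [2.9, 0, 0]}),
        ])
        bonds = detect_hbonds(st, criteria)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].angle is None  # no hydrogens: heavy-only criterion

    def test_same_pair_beyond_cutoff(self, mini_builder, criteria):
        st = mini_builder([
            ("SER", 1, {"OG": [0, 0, 0]}),
            ("ASN", 2, {"OD1": [4.2, 0, 0]}),
        ])
        assert detect_hbonds(st, criteria) == []

    def test_single_residue_has_no_self_bonds(self, mini_builder, criteria):
        st = mini_builder([("SER", 1, {"N": [0, 0, 0], "OG": [2.8, 0, 0], "O": [0, 2.8, 0]})])
        assert detect_hbonds(st, criteria) == []

    @pytest.mark.parametrize(
        "h_xyz, n_bonds",
        [([0.96, 0.0, 0.0], 1),   # H points at the acceptor: near-linear D-H...A
         ([-0.96, 0.0, 0.0], 0)], # H points away: angle fails
        ids=["toward-acceptor", "away-from-acceptor"],
    )
    def test_angle_criterion_applies_with_hydrogens(self, mini_builder, h_xyz, n_bonds):
        st = mini_builder([
            ("SER", 1, {"OG": [0, 0, 0], "HG": h_xyz}),
            ("ASN", 2, {"OD1": [2.9, 0, 0]}),
        ])
        st.chains["A"][0].atoms[1].is_hydrogen = True
        assert len(detect_hbonds(st, HBondCriteria())) == n_bonds

    def test_output_sorted_by_distance(self, mini_builder, criteria):
        st = mini_builder([
            ("SER", 1, {"OG": [0, 0, 0]}),
            ("ASN", 2, {"OD1": [3.2, 0, 0]}),
            ("THR", 3, {"OG1": [0, 2.7, 0]}),
        ])
        bonds = detect_hbonds(st, criteria)
        assert [round(b.distance, 1) for b in bonds] == sorted(round(b.distance, 1) for b in bonds)

    def test_invariant_under_rigid_transform(self, mini_builder, criteria):
        from scipy.spatial.transform import Rotation

        st = mini_builder([
            ("SER", 1, {"OG": [0, 0, 0]}),
            ("ASN", 2, {"OD1": [2.9, 0, 0]}),
        ])
        moved = st.transform(Rotation.from_euler("xyz", [20, 45, -70], degrees=True).as_matrix(),
                             np.array([10.0, -5.0, 2.0]))
        d0 = detect_hbonds(st, criteria)[0].distance
        d1 = detect_hbonds(moved, criteria)[0].distance
        assert d0 == pytest.approx(d1, abs=1e-9)


class TestChecklist:
    def test_primary_pair_present_by_construction(self, mini_builder, criteria):
        st = mini_builder([
            ("SER", 64, {"OG": [0, 0, 0]}),
            ("ASN", 113, {"OD1": [2.9, 0, 0], "ND2": [3.5, 1.0, 0]}),
        ])
        entry = ChecklistEntry("TM II-TM IV", ("SER", 64), ("ASN", 113))
        result = run_checklist(st, [entry], criteria)
        assert result.verdicts[0].status == "present"

    def test_displaced_partner_absent_other_pair_present(self, mini_builder, criteria):
        st = mini_builder([
            ("SER", 64, {"OG": [0, 0, 0]}),
            ("ASN", 113, {"OD1": [8.0, 0, 0]}),       # displaced out of range
            ("TRP", 148, {"NE1": [0, 3.0, 0]}),        # in range
        ])
        entries = [
            ChecklistEntry("TM II-TM IV", ("SER", 64), ("ASN", 113)),
            ChecklistEntry("TM II-TM IV", ("SER", 64), ("TRP", 148)),
        ]
        result = run_checklist(st, entries, criteria)
        assert result.status_of(("SER", 64), ("ASN", 113)) == "absent"
        assert result.status_of(("SER", 64), ("TRP", 148)) == "present"

    def test_alternative_partner_reported(self, mini_builder, criteria):
        st = mini_builder([
            ("ASP", 69, {"OD1": [0, 0, 0], "OD2": [0.5, 1.1, 0]}),
            ("SER", 433, {"OG": [9.0, 0, 0]}),         # primary out of range
            ("TYR", 440, {"OH": [2.8, 0, 0]}),         # alternative in range
        ])
        entry = ChecklistEntry("TM II-TM VII", ("ASP", 69), ("SER", 433),
                               alternatives=[("TYR", 440)])
        result = run_checklist(st, [entry], criteria)
        assert result.verdicts[0].status == "alternative"
        assert result.verdicts[0].partner == ("TYR", 440)

    def test_salt_bridge_rule_for_charged_pair(self, mini_builder, criteria):
        # N-O at 4.0 A: beyond H-bond range, within salt-bridge range
        st = mini_builder([
            ("ARG", 121, {"NH1": [0, 0, 0], "NH2": [1.0, 1.0, 0]}),
            ("GLU", 382, {"OE1": [4.0, 0, 0], "OE2": [4.5, 1.0, 0]}),
        ])
        entry = ChecklistEntry("TM III-TM VI", ("ARG", 121), ("GLU", 382))
        result = run_checklist(st, [entry], criteria)
        assert result.verdicts[0].status == "present"

    def test_unresolvable_residue_reported_distinctly(self, mini_builder, criteria):
        st = mini_builder([("SER", 64, {"OG": [0, 0, 0]})])
        entry = ChecklistEntry("TM II-TM IV", ("SER", 64), ("ASN", 113))
        result = run_checklist(st, [entry], criteria)
        assert result.verdicts[0].status == "unresolvable"

    def test_loosening_distance_is_monotone(self, mini_builder):
        st = mini_builder([
            ("SER", 64, {"OG": [0, 0, 0]}),
            ("ASN", 113, {"OD1": [3.4, 0, 0]}),
        ])
        entry = ChecklistEntry("x", ("SER", 64), ("ASN", 113))
        tight = run_checklist(st, [entry], HBondCriteria(heavy_only_distance=3.5))
        loose = run_checklist(st, [entry], HBondCriteria(heavy_only_distance=4.5))
        assert tight.verdicts[0].status == "present"
        assert loose.verdicts[0].status == "present"

    def test_default_checklist_matches_published_pairs(self):
        entries = load_default_checklist()
        pairs = [(e.residue_a, e.residue_b) for e in entries]
        assert len(pairs) == len(set(pairs)) == 9
        assert (("SER", 64), ("ASN", 113)) in pairs
        assert (("ARG", 121), ("GLU", 382)) in pairs
        alternatives = [alt for e in entries for alt in e.alternatives]
        for alt in (("TYR", 440), ("GLN", 179), ("ASP", 120), ("SER", 118), ("THR", 190)):
            assert alt in alternatives


class TestRamachandran:
    def test_ideal_helix_all_interior_favored(self):
        st = helix_structure(12)
        report = ramachandran_classify(st)
        assert report.rama_counts == {"favored": 10, "allowed": 0, "disallowed": 0}

    def test_forced_positive_phi_is_disallowed_for_non_glycine(self):
        st = helix_structure(9, overrides={4: {"phi": 60.0, "psi": -120.0}})
        report = ramachandran_classify(st)
        assert report.rama_counts["disallowed"] == 1
        assert report.disallowed[0][1] == 5  # seq number of the forced residue

    def test_glycine_tolerates_positive_phi(self):
        names = ["ALA"] * 9
        names[4] = "GLY"
        st = helix_structure(9, names=names, overrides={4: {"phi": 60.0, "psi": -120.0}})
        report = ramachandran_classify(st)
        assert report.rama_counts["disallowed"] == 0

    def test_dipeptide_has_no_interior_residue(self):
        st = helix_structure(2)
        report = ramachandran_classify(st)
        assert sum(report.rama_counts.values()) == 0

    def test_bundle_generator_output_is_clean(self, bundle):
        report = ramachandran_classify(bundle)
        assert report.rama_counts["disallowed"] == 0
        assert report.rama_counts["allowed"] == 0
        assert report.rama_counts["favored"] > 150


class TestBackboneScreens:
    def test_cis_proline_detected(self):
        names = ["ALA"] * 8
        names[4] = "PRO"
        st = helix_structure(8, names=names, overrides={4: {"omega": 0.0}})
        assert detect_cis_prolines(st) == [("PRO", 5)]

    def test_trans_proline_not_flagged(self):
        names = ["ALA"] * 8
        names[4] = "PRO"
        st = helix_structure(8, names=names)
        assert detect_cis_prolines(st) == []

    def test_disulfide_at_bond_length(self, mini_builder):
        st = mini_builder([
            ("CYS", 96, {"SG": [0, 0, 0], "CA": [1.8, 0, 0], "N": [2.5, 1, 0], "C": [2.5, -1, 0]}),
            ("CYS", 176, {"SG": [2.05, 0, 0], "CA": [3.9, 0, 0], "N": [4.5, 1, 0], "C": [4.5, -1, 0]}),
        ])
        ss = check_disulfides(st)
        assert len(ss) == 1
        assert ss[0][:2] == (96, 176)
        assert ss[0][2] == pytest.approx(2.05)

    def test_distant_cysteines_not_bonded(self, mini_builder):
        st = mini_builder([
            ("CYS", 96, {"SG": [0, 0, 0]}),
            ("CYS", 176, {"SG": [5.0, 0, 0]}),
        ])
        assert check_disulfides(st) == []

    def test_bundle_is_clash_free(self, bundle):
        assert detect_clashes(bundle) == []

    def test_overlapping_atoms_flagged(self, mini_builder):
        st = mini_builder([
            ("ALA", 1, {"CB": [0, 0, 0]}),
            ("LEU", 5, {"CB": [1.0, 0, 0]}),  # 1.0 < 0.6 * (1.7 + 1.7)
        ])
        clashes = detect_clashes(st)
        assert len(clashes) == 1
        assert clashes[0][2] == pytest.approx(1.0)
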