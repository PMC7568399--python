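"""Geometric screening: active-site distances and side-chain bonding."""

import numpy as np
import pytest

from phyloconsensus.consensus import CandidateSite
from phyloconsensus.errors import ConfigError, MappingError
from phyloconsensus.structure_filter import (
    apply_structural_filters,
    detect_sidechain_bonds,
    distance_to_active_site,
    load_structure,
)

from conftest import write_pdb


def gly(chain, num, x=0.0, y=0.0, z=0.0):
    return (
        chain, num, "GLY",
        [
            ("N", "N", x, y, z),
            ("CA", "C", x + 1.5, y, z),
            ("C", "C", x + 2.2, y + 1.3, z),
            ("O", "O", x + 3.4, y + 1.4, z),
        ],
    )


def ala(chain, num, x=0.0, y=0.0, z=0.0):
    c = gly(chain, num, x, y, z)
    return (chain, num, "ALA", c[3] + [("CB", "C", x + 1.9, y - 1.4, z)])


class TestLoadStructure:
    def test_toy_three_residue_model(self, tmp_path):
        p = write_pdb(tmp_path / "toy.pdb", [gly("A", 1), gly("A", 2, 10), gly("A", 3, 20)])
        model = load_structure(p, query_sequence="GGG")
        assert len(model.residues) == 3
        assert model.mapping == {1: ("A", 1), 2: ("A", 2), 3: ("A", 3)}

    def test_offset_mismatch_detected_at_first_position(self, tmp_path):
        p = write_pdb(tmp_path / "toy.pdb", [gly("A", 1), ala("A", 2, 10), gly("A", 3, 20)])
        # shifting by one aligns query position 1 ('G') against the ALA at 2
        with pytest.raises(MappingError, match="position 1"):
            load_structure(p, query_sequence="GA", offset=1)

    def test_sequence_mismatch_raises_mapping_error(self, tmp_path):
        p = write_pdb(tmp_path / "toy.pdb", [gly("A", 1), gly("A", 2, 10)])
        with pytest.raises(MappingError):
            load_structure(p, query_sequence="GW")

    def test_gapped_query_sequence_accepted(self, tmp_path):
        p = write_pdb(tmp_path / "toy.pdb", [gly("A", 1), ala("A", 2, 10)])
        model = load_structure(p, query_sequence="G-A")  # gaps stripped
        assert model.residue_at(2).name == "ALA"

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        atoms = [
            ("N", "N", 0.0, 0.0, 0.0, 0.3, "A"),
            ("N", "N", 9.0, 0.0, 0.0, 0.7, "B"),
            ("CA", "C", 1.5, 0.0, 0.0, 1.0, " "),
            ("C", "C", 2.2, 1.3, 0.0, 1.0, " "),
            ("O", "O", 3.4, 1.4, 0.0, 1.0, " "),
        ]
        p = write_pdb(tmp_path / "alt.pdb", [("A", 1, "GLY", atoms)])
        model = load_structure(p, query_sequence="G")
        res = model.residue_at(1)
        n_idx = res.atom_names.index("N")
        assert res.coords[n_idx][0] == pytest.approx(9.0)  # occupancy 0.7 wins


class TestDistanceToActiveSite:
    def _model(self, tmp_path):
        # three single-residue "probes" at controlled positions
        residues = [
            ("A", 1, "GLY", [("CA", "C", 0.0, 0.0, 0.0)]),
            ("A", 2, "GLY", [("CA", "C", 3.0, 4.0, 0.0)]),
            ("A", 3, "GLY", [("CA", "C", 6.3, 0.0, 0.0)]),
        ]
        p = write_pdb(tmp_path / "probes.pdb", residues)
        return load_structure(p, query_sequence="GGG")

    def test_member_of_active_site_is_zero(self, tmp_path):
        model = self._model(tmp_path)
        assert distance_to_active_site(model, 1, [1, 2]) == 0.0

    def test_three_four_five_triangle(self, tmp_path):
        model = self._model(tmp_path)
        assert distance_to_active_site(model, 2, [1]) == pytest.approx(5.0)

    def test_minimum_over_active_site_members(self, tmp_path):
        model = self._model(tmp_path)
        d = distance_to_active_site(model, 3, [1, 2])
        assert d == pytest.approx(min(6.3, np.hypot(3.3, 4.0)))

    def test_empty_active_site_rejected(self, tmp_path):
        model = self._model(tmp_path)
        with pytest.raises(ConfigError):
            distance_to_active_site(model, 1, [])

    def test_rigid_body_invariance(self, tmp_path):
        model = self._model(tmp_path)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        moved = model.transformed(rot, np.array([5.0, -3.0, 11.0]))
        for pos in (2, 3):
            assert distance_to_active_site(moved, pos, [1]) == pytest.approx(
                distance_to_active_site(model, pos, [1]), abs=1e-6
            )


class TestDetectSidechainBonds:
    def test_isolated_residue_empty_report(self, tmp_path):
        p = write_pdb(
            tmp_path / "iso.pdb",
            [
                ("A", 1, "SER", [
                    ("N", "N", 0, 0, 0), ("CA", "C", 1.5, 0, 0),
                    ("C", "C", 2.2, 1.3, 0), ("O", "O", 3.4, 1.4, 0),
                    ("CB", "C", 1.9, -1.4, 0), ("OG", "O", 1.2, -2.6, 0),
                ]),
                gly("A", 2, 50.0),
            ],
        )
        model = load_structure(p, query_sequence="SG")
        assert detect_sidechain_bonds(model, 1) == []

    def test_glycine_has_no_sidechain_bonds(self, tmp_path):
        p = write_pdb(tmp_path / "g.pdb", [gly("A", 1), gly("A", 2, 2.0)])
        model = load_structure(p, query_sequence="GG")
        assert detect_sidechain_bonds(model, 1) == []

    def test_lys_asp_salt_bridge_at_3p8(self, tmp_path):
        lys = ("A", 1, "LYS", [
            ("N", "N", 0, 0, 0), ("CA", "C", 1.5, 0, 0),
            ("C", "C", 2.2, 1.3, 0), ("O", "O", 3.4, 1.4, 0),
            ("CB", "C", 1.9, -1.4, 0), ("NZ", "N", 3.0, -4.0, 0),
        ])
        asp = ("A", 2, "ASP", [
            ("N", "N", 10, 0, 0), ("CA", "C", 11.5, 0, 0),
            ("C", "C", 12.2, 1.3, 0), ("O", "O", 13.4, 1.4, 0),
            ("CB", "C", 11.9, -1.4, 0),
            ("OD1", "O", 3.0, -7.8, 0),  # 3.8 Å below NZ
            ("OD2", "O", 11.0, -3.4, 0),
        ])
        p = write_pdb(tmp_path / "kd.pdb", [lys, asp])
        model = load_structure(p, query_sequence="KD")
        bonds = detect_sidechain_bonds(model, 1)
        assert len(bonds) == 1
        assert bonds[0].kind == "salt_bridge"
        assert bonds[0].distance == pytest.approx(3.8)
        assert bonds[0].partner_position == 2

    def test_salt_bridge_beyond_4A_not_reported(self, tmp_path):
        lys = ("A", 1, "LYS", [
            ("N", "N", 0, 0, 0), ("CA", "C", 1.5, 0, 0),
            ("C", "C", 2.2, 1.3, 0), ("O", "O", 3.4, 1.4, 0),
            ("NZ", "N", 3.0, -4.0, 0),
        ])
        asp = ("A", 2, "ASP", [
            ("N", "N", 10, 0, 0), ("CA", "C", 11.5, 0, 0),
            ("C", "C", 12.2, 1.3, 0), ("O", "O", 13.4, 1.4, 0),
            ("OD1", "O", 3.0, -8.2, 0),  # 4.2 Å
        ])
        p = write_pdb(tmp_path / "kd.pdb", [lys, asp])
        model = load_structure(p, query_sequence="KD")
        assert detect_sidechain_bonds(model, 1) == []

    def test_ser_og_to_backbone_o_is_hbond(self, tmp_path):
        ser = ("A", 1, "SER", [
            ("N", "N", 0, 0, 0), ("CA", "C", 1.5, 0, 0),
            ("C", "C", 2.2, 1.3, 0), ("O", "O", 3.4, 1.4, 0),
            ("CB", "C", 1.9, -1.4, 0), ("OG", "O", 1.2, -2.6, 0),
        ])
        # partner backbone O placed 3.2 Å from OG; everything else far
        other = ("A", 2, "GLY", [
            ("N", "N", 20, 0, 0), ("CA", "C", 21.5, 0, 0),
            ("C", "C", 22.2, 1.3, 0), ("O", "O", 1.2, -5.8, 0),
        ])
        p = write_pdb(tmp_path / "sg.pdb", [ser, other])
        model = load_structure(p, query_sequence="SG")
        bonds = detect_sidechain_bonds(model, 1)
        assert [b.kind for b in bonds] == ["hbond"]
        assert bonds[0].distance == pytest.approx(3.2)

    def test_backbone_only_contact_of_candidate_ignored(self, tmp_path):
        # candidate's own backbone N near partner O, side chain far away
        ala1 = ("A", 1, "ALA", [
            ("N", "N", 0, 0, 0), ("CA", "C", 1.5, 0, 0),
            ("C", "C", 2.2, 1.3, 0), ("O", "O", 3.4, 1.4, 0),
            ("CB", "C", 1.9, -30.0, 0),
        ])
        other = ("A", 2, "GLY", [
            ("N", "N", 20, 0, 0), ("CA", "C", 21.5, 0, 0),
            ("C", "C", 22.2, 1.3, 0), ("O", "O", 0.0, 3.0, 0),
        ])
        p = write_pdb(tmp_path / "bb.pdb", [ala1, other])
        model = load_structure(p, query_sequence="AG")
        assert detect_sidechain_bonds(model, 1) == []


class TestApplyStructuralFilters:
    def _sites(self):
        return [
            CandidateSite(1, "G", "A", 55.0),
            CandidateSite(2, "G", "V", 45.0),
            CandidateSite(3, "G", "S", 65.0),
        ]

    def _model(self, tmp_path):
        residues = [
            ("A", 1, "GLY", [("CA", "C", 5.9, 0, 0)]),   # too close
            ("A", 2, "GLY", [("CA", "C", 8.0, 0, 0)]),   # far, no contacts
            ("A", 3, "GLY", [("CA", "C", 0, 6.3, 0)]),   # just outside 6 Å
            ("A", 9, "GLY", [("CA", "C", 0.0, 0.0, 0.0)]),  # active site
        ]
        p = write_pdb(tmp_path / "f.pdb", residues)
        return load_structure(p, query_sequence="GGG" + "G" * 5 + "G")

    def test_statuses_and_order_preserved(self, tmp_path):
        model = self._model(tmp_path)
        out = apply_structural_filters(self._sites(), model, [9], min_distance=6.0)
        assert [s.filter_status for s in out] == [
            "rejected_distance", "passed", "passed",
        ]
        assert [s.label for s in out] == ["G1A", "G2V", "G3S"]
        assert out[2].distance_to_active_site == pytest.approx(6.3)

    def test_exactly_6A_rejected_strictly_greater_passes(self, tmp_path):
        model = self._model(tmp_path)
        out = apply_structural_filters(self._sites(), model, [9], min_distance=6.31)
        # the 6.3 Å site is now inside the exclusion radius
        assert out[2].filter_status == "rejected_distance"

    def test_bonded_precedence_after_distance(self, tmp_path):
        lys = ("A", 1, "LYS", [
            ("N", "N", 10, 0, 0), ("CA", "C", 11.5, 0, 0),
            ("C", "C", 12.2, 1.3, 0), ("O", "O", 13.4, 1.4, 0),
            ("NZ", "N", 13.0, -4.0, 0),
        ])
        asp = ("A", 2, "ASP", [
            ("N", "N", 20, 0, 0), ("CA", "C", 21.5, 0, 0),
            ("C", "C", 22.2, 1.3, 0), ("O", "O", 23.4, 1.4, 0),
            ("OD1", "O", 13.0, -7.5, 0),
        ])
        active = ("A", 9, "GLY", [("CA", "C", -20.0, 0, 0)])
        p = write_pdb(tmp_path / "kb.pdb", [lys, asp, active])
        model = load_structure(p, query_sequence="KD" + "G" * 6 + "G")
        out = apply_structural_filters(
            [CandidateSite(1, "K", "E", 80.0)], model, [9]
        )
        assert out[0].filter_status == "rejected_bonded"
        assert out[0].bonds[0].kind == "salt_bridge"

    def test_tightening_min_distance_never_unrejects(self, tmp_path):
        model = self._model(tmp_path)
        loose = apply_structural_filters(self._sites(), model, [9], min_distance=6.0)
        tight = apply_structural_filters(self._sites(), model, [9], min_distance=7.0)
        for a, b in zip(loose, tight):
            if a.filter_status.startswith("rejected"):
                assert b.filter_status.startswith("rejected")
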