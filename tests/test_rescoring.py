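"""Empirical scoring terms, decomposition identities, external energy adapter."""

import math

import numpy as np
import pytest

from cidock.errors import SchemaError, UsageError, ValidationError
from cidock.molecules import Molecule, Pose
from cidock.rescoring import (
    ExternalEnergyRecord,
    ScoreBreakdown,
    ScoringCoefficients,
    empirical_score,
    load_external_energies,
    rank_energy,
)
from cidock.synthgen import make_toy_ligand


@pytest.fixture
def receptor():
    # C / O / C triangle; O available as H-bond acceptor
    return Molecule("rec", ["C", "O", "C"],
                    np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.8, 0]]),
                    bonds=[], is_receptor=True)


def _pose(mol):
    return Pose(mol, "E", -8.0, 0)


class TestIdentities:
    def test_breakdown_identity_enforced(self):
        with pytest.raises(ValidationError):
            ScoreBreakdown(-1.0, -1.0, 0.5, -0.5, -1.0, -5.0)
        sb = ScoreBreakdown.from_terms(-1.0, -1.0, 0.5, -0.5, -1.0)
        assert sb.dG_bind == pytest.approx(-3.0, abs=1e-12)

    def test_external_identity_enforced(self):
        with pytest.raises(ValidationError):
            ExternalEnergyRecord("t", -45.0, -20.0, -15.0, -9.0)
        rec = ExternalEnergyRecord.from_terms("t", -45.0, -20.0, -15.0)
        assert rec.dG_bind == pytest.approx(-10.0, abs=1e-12)


class TestEmpiricalScore:
    def test_far_pose_leaves_only_deformation_and_constant(self, receptor):
        lig = make_toy_ligand(8, seed=3).translated([100.0, 0, 0])
        sb = empirical_score(receptor, _pose(lig))
        assert sb.dG_vdw == 0.0 and sb.dG_hbond == 0.0 and sb.dG_hydrophobic == 0.0
        assert sb.dG_bind == pytest.approx(sb.dG_deformation + sb.dG_0, abs=1e-12)

    def test_rigid_ligand_far_with_zero_constant_scores_zero(self, receptor):
        coeffs = ScoringCoefficients(dG_0=0.0)
        lig = Molecule("rigid", ["C", "C"],
                       np.array([[100.0, 0, 0], [101.5, 0, 0]]), [(0, 1, 1)])
        sb = empirical_score(receptor, _pose(lig), coeffs)
        assert sb.dG_bind == pytest.approx(0.0, abs=1e-12)

    def test_toy_system_matches_hand_enumerated_pairs(self, receptor):
        coeffs = ScoringCoefficients()
        # ligand: one C at 4.0 Å from receptor C0; one N 2.15 Å from receptor O
        # with its C neighbour trans to the O (C-N...O angle ≈ 154°)
        lig = Molecule("lig", ["C", "N"],
                       np.array([[0.0, 0.0, 4.0], [2.2, 0.0, 2.0]]), [(0, 1, 1)])
        sb = empirical_score(receptor, _pose(lig), coeffs)

        # hand-enumerated: six receptor-ligand pairs, scalar arithmetic
        rxyz = receptor.coords
        lxyz = lig.coords
        radii = {"C": 1.70, "N": 1.55, "O": 1.52}
        vdw = 0.0
        for i, rel in enumerate(receptor.elements):
            for j, lel in enumerate(lig.elements):
                r = float(np.linalg.norm(rxyz[i] - lxyz[j]))
                if r <= 8.0:
                    r0 = radii[rel] + radii[lel]
                    q = (r0 / max(r, 0.4 * r0)) ** 4
                    vdw += q * q - 2 * q
        assert sb.dG_vdw == pytest.approx(coeffs.vdw_weight * vdw, abs=1e-9)

        # exactly one polar pair within 3.5 Å: receptor O — ligand N;
        # ligand N's only neighbour C gives an X-N...O angle > 120°
        assert sb.dG_hbond == pytest.approx(coeffs.hbond_weight * 1, abs=1e-12)

        # C-C pairs within 4.5 Å: C0-C(lig0) at 4.0 only
        cc = sum(1 for i in (0, 2) for j in (0,)
                 if np.linalg.norm(rxyz[i] - lxyz[j]) <= 4.5)
        assert cc == 1
        assert sb.dG_hydrophobic == pytest.approx(coeffs.hydrophobic_weight * cc,
                                                  abs=1e-12)
        # two-heavy-atom ligand has no rotors
        assert sb.dG_deformation == 0.0
        assert sb.dG_bind == pytest.approx(
            sb.dG_vdw + sb.dG_hbond + sb.dG_deformation + sb.dG_hydrophobic + sb.dG_0,
            abs=1e-12)

    def test_hbond_angle_gate_blocks_closed_geometry(self, receptor):
        coeffs = ScoringCoefficients()
        # neighbour C placed so the C-N...O angle is ~60° — inside the gate
        lig = Molecule("bent", ["C", "N"],
                       np.array([[4.0, 1.0, 0.0], [3.0, 1.5, 0.0]]), [(0, 1, 1)])
        sb = empirical_score(receptor, _pose(lig), coeffs)
        assert sb.dG_hbond == 0.0

    def test_adding_one_valid_hbond_changes_one_quantum(self, receptor):
        coeffs = ScoringCoefficients()
        base = Molecule("l1", ["C", "N"],
                        np.array([[0.0, 0.0, 4.0], [2.2, 0.0, 2.0]]), [(0, 1, 1)])
        # add an O within 3.5 Å of the receptor O, neighbour C trans (≈147°)
        plus = Molecule("l2", ["C", "N", "O"],
                        np.array([[0.0, 0.0, 4.0], [2.2, 0.0, 2.0],
                                  [1.5, 0.0, 0.9]]), [(0, 1, 1), (0, 2, 1)])
        d_o = np.linalg.norm(plus.coords[2] - receptor.coords[1])
        assert d_o <= coeffs.hbond_distance
        sb0 = empirical_score(receptor, _pose(base), coeffs)
        sb1 = empirical_score(receptor, _pose(plus), coeffs)
        assert sb1.dG_hbond - sb0.dG_hbond == pytest.approx(coeffs.hbond_weight,
                                                            abs=1e-12)

    def test_doubling_rotor_weight_doubles_deformation(self):
        lig = make_toy_ligand(8, seed=3)
        rec = Molecule("far", ["C"], np.array([[500.0, 0, 0]]), [], is_receptor=True)
        sb1 = empirical_score(rec, _pose(lig), ScoringCoefficients(rotor_penalty=0.35))
        sb2 = empirical_score(rec, _pose(lig), ScoringCoefficients(rotor_penalty=0.70))
        assert sb1.dG_deformation > 0
        assert sb2.dG_deformation == pytest.approx(2 * sb1.dG_deformation, abs=1e-12)

    def test_invariant_under_joint_rigid_motion(self, receptor):
        lig = make_toy_ligand(6, seed=5).translated([2.0, 1.0, 3.0])
        sb0 = empirical_score(receptor, _pose(lig))
        t = math.radians(37.0)
        rot = np.array([[math.cos(t), -math.sin(t), 0],
                        [math.sin(t), math.cos(t), 0], [0, 0, 1]])
        shift = np.array([4.0, -2.0, 7.0])
        rec2 = receptor.with_coords(receptor.coords @ rot.T + shift)
        lig2 = lig.with_coords(lig.coords @ rot.T + shift)
        sb1 = empirical_score(rec2, _pose(lig2))
        assert sb1.dG_bind == pytest.approx(sb0.dG_bind, abs=1e-9)
        assert sb1.dG_hbond == sb0.dG_hbond
        assert sb1.dG_hydrophobic == sb0.dG_hydrophobic


class TestExternalEnergies:
    HEADER = "target_id\tdE_bind\tTdS_sol\tTdS_conf"

    def test_totals_computed_from_terms(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(f"{self.HEADER}\nT1\t-45.0\t-20.0\t-15.0\n")
        recs = load_external_energies(p)
        assert len(recs) == 1 and recs[0].dG_bind == pytest.approx(-10.0)

    def test_inconsistent_stated_total_rejected_with_row(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(f"{self.HEADER}\tdG_bind\n"
                     "T1\t-45.0\t-20.0\t-15.0\t-10.0\n"
                     "T2\t-30.0\t-10.0\t-10.0\t-9.0\n")
        with pytest.raises(ValidationError, match="row 3"):
            load_external_energies(p)

    def test_empty_file_returns_empty_list(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert load_external_energies(p) == []

    def test_missing_columns_raise_schema_error(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("target_id\tdE_bind\nT1\t-45.0\n")
        with pytest.raises(SchemaError):
            load_external_energies(p)


class TestRankEnergy:
    def test_preserves_values_per_scheme(self):
        records = {f"t{i}": ScoreBreakdown.from_terms(v, 0, 0, 0, 0)
                   for i, v in enumerate([-10.0, -5.0, -7.0], start=1)}
        out = rank_energy(records, "empirical")
        assert out == {"t1": -10.0, "t2": -5.0, "t3": -7.0}
        assert sorted(out, key=out.get) == ["t1", "t3", "t2"]

    def test_missing_target_named(self):
        records = {"t1": ExternalEnergyRecord.from_terms("t1", -40, -20, -10),
                   "t2": ScoreBreakdown.from_terms(-5, 0, 0, 0, 0)}
        with pytest.raises(ValidationError, match="t2"):
            rank_energy(records, "external")

    def test_invalid_scheme_is_usage_error(self):
        with pytest.raises(UsageError):
            rank_energy({}, "both")
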