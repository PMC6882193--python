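"""Binding-affinity estimation for the consensus pose.

Two routes are supported:

* an implemented, transparent empirical scoring function with the classic
  additive free-energy decomposition

      ΔG_bind = ΔG_vdw + ΔG_H-bond + ΔG_deformation + ΔG_hydrophobic + ΔG_0

  where each interaction term is computed from receptor-ligand heavy-atom
  geometry and multiplied by a configurable coefficient; and

* a file-based adapter for externally computed MM/PBSA-style energies,

      ΔG_bind = ΔE_bind − TΔS_sol − TΔS_conf

  whose terms are produced by an external calculator and only validated and
  ingested here.

The empirical coefficients default to drug-like magnitudes; no numeric
equivalence with any published scoring program is claimed — the contract is
the decomposition identity and the geometric gating of each term.
All energies are kcal/mol, all distances Å.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import SchemaError, UsageError, ValidationError
from .molecules import Molecule, Pose, count_rotatable_bonds

log = logging.getLogger(__name__)

_IDENTITY_TOL = 1e-9
_EXTERNAL_TOTAL_TOL = 1e-6

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "F": 1.47,
              "Cl": 1.75, "Br": 1.85, "I": 1.98}
_DEFAULT_RADIUS = 1.70
_POLAR = {"N", "O"}


@dataclass(frozen=True)
class ScoringCoefficients:
    """Weights and geometric gates of the empirical scoring terms.

    Distances in Å, angle in degrees, weights in kcal/mol per unit of the
    term's raw geometric sum (per contact for the counting terms, per
    rotatable bond for the deformation penalty).
    """

    vdw_weight: float = 0.30
    vdw_cutoff: float = 8.0
    hbond_weight: float = -1.20
    hbond_distance: float = 3.5
    hbond_angle_deg: float = 120.0
    hydrophobic_weight: float = -0.08
    hydrophobic_cutoff: float = 4.5
    rotor_penalty: float = 0.35
    dG_0: float = -1.50

    def __post_init__(self) -> None:
        if min(self.vdw_cutoff, self.hbond_distance, self.hydrophobic_cutoff) <= 0:
            raise ValidationError("all distance cutoffs must be positive")
        if not 0 < self.hbond_angle_deg <= 180:
            raise ValidationError("H-bond angle gate must lie in (0, 180] degrees")


DEFAULT_COEFFICIENTS = ScoringCoefficients()


@dataclass(frozen=True)
class ScoreBreakdown:
    """Empirical ΔG decomposition; the additive identity is enforced."""

    dG_vdw: float
    dG_hbond: float
    dG_deformation: float
    dG_hydrophobic: float
    dG_0: float
    dG_bind: float

    def __post_init__(self) -> None:
        total = (self.dG_vdw + self.dG_hbond + self.dG_deformation
                 + self.dG_hydrophobic + self.dG_0)
        if abs(total - self.dG_bind) > _IDENTITY_TOL:
            raise ValidationError(
                f"ΔG decomposition identity violated: terms sum to {total}, "
                f"dG_bind is {self.dG_bind}")

    @classmethod
    def from_terms(cls, dG_vdw: float, dG_hbond: float, dG_deformation: float,
                   dG_hydrophobic: float, dG_0: float) -> "ScoreBreakdown":
        return cls(dG_vdw, dG_hbond, dG_deformation, dG_hydrophobic, dG_0,
                   dG_vdw + dG_hbond + dG_deformation + dG_hydrophobic + dG_0)


@dataclass(frozen=True)
class ExternalEnergyRecord:
    """One externally computed MM/PBSA-style energy; identity enforced."""

    target_id: str
    dE_bind: float
    TdS_sol: float
    TdS_conf: float
    dG_bind: float
    source: str = "external"

    def __post_init__(self) -> None:
        implied = self.dE_bind - self.TdS_sol - self.TdS_conf
        if abs(implied - self.dG_bind) > _IDENTITY_TOL:
            raise ValidationError(
                f"target {self.target_id!r}: ΔG_bind {self.dG_bind} does not equal "
                f"ΔE_bind − TΔS_sol − TΔS_conf = {implied}")

    @classmethod
    def from_terms(cls, target_id: str, dE_bind: float, TdS_sol: float,
                   TdS_conf: float, source: str = "external") -> "ExternalEnergyRecord":
        return cls(target_id, dE_bind, TdS_sol, TdS_conf,
                   dE_bind - TdS_sol - TdS_conf, source)


# ---------------------------------------------------------------------------
# empirical scoring
# ---------------------------------------------------------------------------

def _soft_84(r: np.ndarray, r0: np.ndarray) -> np.ndarray:
    # 8-4 potential: well depth -1 at r0, repulsive on close approach.
    q = (r0 / np.maximum(r, 0.4 * r0)) ** 4
    return q * q - 2.0 * q


def _angle_gate_ok(atom: int, partner_xyz: np.ndarray, mol: Molecule,
                   neighbors: list[int], min_angle_deg: float) -> bool:
    """True when the heavy-neighbour geometry permits a hydrogen bond.

    For an atom with known heavy neighbours the X–D···A angle must open to at
    least the gate for some neighbour X; atoms without recorded neighbours
    (isolated heteroatoms, receptors read without bonds) pass by default.
    """
    if not neighbors:
        return True
    d = mol.coords[atom]
    v1 = partner_xyz - d
    n1 = np.linalg.norm(v1)
    if n1 < 1e-9:
        return False
    for x in neighbors:
        v2 = mol.coords[x] - d
        n2 = np.linalg.norm(v2)
        if n2 < 1e-9:
            continue
        cosang = float(np.dot(v1, v2) / (n1 * n2))
        ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if ang >= min_angle_deg:
            return True
    return False


def _heavy_neighbor_map(mol: Molecule) -> dict[int, list[int]]:
    nb: dict[int, list[int]] = {}
    for i, j, _ in mol.bonds:
        if mol.elements[i] != "H" and mol.elements[j] != "H":
            nb.setdefault(i, []).append(j)
            nb.setdefault(j, []).append(i)
    return nb


def empirical_score(receptor: Molecule, pose: Pose | Molecule,
                    coeffs: ScoringCoefficients = DEFAULT_COEFFICIENTS,
                    ) -> ScoreBreakdown:
    """Score a ligand pose against a receptor with the additive decomposition.

    Terms, all over heavy atoms in the shared coordinate frame:

    * van der Waals — soft 8-4 contact sum over receptor-ligand pairs within
      ``vdw_cutoff`` (radii-scaled well of depth 1 per ideal contact);
    * H-bond — count of N/O donor-acceptor pairs within ``hbond_distance``
      whose heavy-neighbour angles open past ``hbond_angle_deg``;
    * deformation — rotatable-bond count of the ligand times the rotor penalty
      (conformational entropy lost on binding);
    * hydrophobic — count of carbon-carbon contacts within
      ``hydrophobic_cutoff`` (buried apolar surface proxy);

    each multiplied by its coefficient, plus the regression constant ΔG_0.
    """
    lig = pose.molecule if isinstance(pose, Pose) else pose
    rx = receptor.heavy_coords
    lx = lig.heavy_coords
    if not (np.all(np.isfinite(rx)) and np.all(np.isfinite(lx))):
        raise ValidationError("non-finite coordinates in receptor or pose")
    r_el = np.array(receptor.heavy_elements)
    l_el = np.array(lig.heavy_elements)

    d = cdist(rx, lx)

    # van der Waals
    r0 = (np.array([_VDW_RADII.get(e, _DEFAULT_RADIUS) for e in r_el])[:, None]
          + np.array([_VDW_RADII.get(e, _DEFAULT_RADIUS) for e in l_el])[None, :])
    within = d <= coeffs.vdw_cutoff
    vdw_sum = float(_soft_84(d, r0)[within].sum()) if within.any() else 0.0

    # hydrogen bonds (distance + angle gated, counted once per pair)
    rec_nb = _heavy_neighbor_map(receptor)
    lig_nb = _heavy_neighbor_map(lig)
    rec_heavy = receptor.heavy_indices
    lig_heavy = lig.heavy_indices
    hb_pairs = 0
    cand = np.argwhere((d <= coeffs.hbond_distance)
                       & (np.isin(r_el, list(_POLAR))[:, None])
                       & (np.isin(l_el, list(_POLAR))[None, :]))
    for ri, li in cand:
        ra, la = int(rec_heavy[ri]), int(lig_heavy[li])
        if _angle_gate_ok(la, receptor.coords[ra], lig,
                          lig_nb.get(la, []), coeffs.hbond_angle_deg) and \
           _angle_gate_ok(ra, lig.coords[la], receptor,
                          rec_nb.get(ra, []), coeffs.hbond_angle_deg):
            hb_pairs += 1

    # hydrophobic carbon-carbon contacts
    cc = (r_el == "C")[:, None] & (l_el == "C")[None, :]
    hp_pairs = int(np.count_nonzero(cc & (d <= coeffs.hydrophobic_cutoff)))

    rotors = count_rotatable_bonds(lig)

    return ScoreBreakdown.from_terms(
        dG_vdw=coeffs.vdw_weight * vdw_sum,
        dG_hbond=coeffs.hbond_weight * hb_pairs,
        dG_deformation=coeffs.rotor_penalty * rotors,
        dG_hydrophobic=coeffs.hydrophobic_weight * hp_pairs,
        dG_0=coeffs.dG_0)


# ---------------------------------------------------------------------------
# external energies (MM/PBSA-style adapter)
# ---------------------------------------------------------------------------

_EXTERNAL_COLUMNS = ("target_id", "dE_bind", "TdS_sol", "TdS_conf")


def load_external_energies(path: str | Path) -> list[ExternalEnergyRecord]:
    """Read a tab-separated external energy table.

    Required columns: ``target_id  dE_bind  TdS_sol  TdS_conf``; an optional
    ``dG_bind`` column must satisfy the decomposition identity to 1e-6 or the
    offending row is rejected.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        log.warning("external energy table %s is empty", path)
        return []
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXTERNAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        implied = float(row.dE_bind) - float(row.TdS_sol) - float(row.TdS_conf)
        if "dG_bind" in df.columns and not pd.isna(getattr(row, "dG_bind", float("nan"))):
            stated = float(row.dG_bind)
            if abs(stated - implied) > _EXTERNAL_TOTAL_TOL:
                raise ValidationError(
                    f"{path}: row {row_no} (target {row.target_id!r}) states "
                    f"dG_bind={stated} but terms imply {implied}")
        records.append(ExternalEnergyRecord.from_terms(
            str(row.target_id), float(row.dE_bind), float(row.TdS_sol),
            float(row.TdS_conf), source=str(path)))
    return records


def rank_energy(records: Mapping[str, object], scheme: str) -> dict[str, float]:
    """Extract one ΔG_bind per target for the chosen scoring scheme.

    ``records`` maps target_id to a ScoreBreakdown, an ExternalEnergyRecord,
    or a dict holding either under the keys ``empirical``/``external``.
    Schemes are exclusive — empirical and external energies are never fused.
    """
    if scheme not in ("empirical", "external"):
        raise UsageError(f"scheme must be 'empirical' or 'external', got {scheme!r}")
    wanted = ScoreBreakdown if scheme == "empirical" else ExternalEnergyRecord
    out: dict[str, float] = {}
    missing: list[str] = []
    for target_id, rec in records.items():
        if isinstance(rec, Mapping):
            rec = rec.get(scheme)
        if not isinstance(rec, wanted):
            missing.append(target_id)
            continue
        out[target_id] = float(rec.dG_bind)
    if missing:
        raise ValidationError(
            f"no {scheme} record for targets: {sorted(missing)}")
    return out
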