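"""Inverse-screen orchestration: one ligand against a target library.

For every target the ligand is docked by the configured engine panel, the
cluster-vote consensus selects one pose, the pose is rescored, and the
targets are ranked by predicted binding free energy (ascending — stronger
predicted binders first).  Targets whose entire engine panel failed are
carried unranked with a failure note rather than silently dropped, and are
excluded from N when top-k% fractions are computed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .consensus import DEFAULT_RMSD_THRESHOLD, run_consensus
from .engines import EngineConfig, run_engine_panel, stable_seed
from .errors import ValidationError
from .geometry import BoxSpec
from .molecules import Molecule
from .rescoring import (
    DEFAULT_COEFFICIENTS,
    ExternalEnergyRecord,
    ScoringCoefficients,
    empirical_score,
    rank_energy,
)


@dataclass
class TargetEntry:
    """One entry of the target library: receptor, active-site box, annotations."""

    target_id: str
    receptor: Molecule
    box: BoxSpec
    annotations: dict = field(default_factory=dict)
    ref_ligand: Molecule | None = None


@dataclass(frozen=True)
class ScreenRow:
    rank: int
    target_id: str
    dG_bind: float
    engine_votes: int
    tie_broken: bool


@dataclass
class RankedScreenResult:
    """Per-target energies for one ligand, sorted best-first."""

    ligand_id: str
    rows: list[ScreenRow]
    scheme: str
    failures: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for expected, row in enumerate(self.rows, start=1):
            if row.rank != expected:
                raise ValidationError("ranks must be 1..N without gaps")
        energies = [r.dG_bind for r in self.rows]
        if any(b < a - 1e-12 for a, b in zip(energies, energies[1:])):
            raise ValidationError("dG_bind must be non-decreasing with rank")

    @property
    def n_ranked(self) -> int:
        return len(self.rows)

    def rank_of(self, target_id: str) -> int:
        for row in self.rows:
            if row.target_id == target_id:
                return row.rank
        raise KeyError(target_id)

    def energies(self) -> dict[str, float]:
        return {r.target_id: r.dG_bind for r in self.rows}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{"rank": r.rank, "target_id": r.target_id,
                              "dG_bind": r.dG_bind, "engine_votes": r.engine_votes,
                              "tie_broken": r.tie_broken} for r in self.rows])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def write_json(self, path: str | Path) -> None:
        payload = {"ligand_id": self.ligand_id, "scheme": self.scheme,
                   "rows": [r.__dict__ for r in self.rows],
                   "failures": [{"target_id": t, "error": e} for t, e in self.failures]}
        Path(path).write_text(json.dumps(payload, indent=2))


def inverse_screen(ligand: Molecule, library: Sequence[TargetEntry],
                   engine_cfgs: Sequence[EngineConfig],
                   scheme: str = "empirical",
                   threshold: float = DEFAULT_RMSD_THRESHOLD,
                   coeffs: ScoringCoefficients = DEFAULT_COEFFICIENTS,
                   external_energies: Mapping[str, ExternalEnergyRecord] | None = None,
                   strict: bool = False,
                   symmetry_aware: bool = True) -> RankedScreenResult:
    """Dock → consensus → rescore → rank one ligand over the whole library.

    Engine seeds are re-derived per target from (engine seed, target id), so
    results are independent of library order.  Energy ties across targets
    break by higher engine votes, then lexicographic target id.
    """
    if not library:
        raise ValidationError("target library is empty")
    ids = [t.target_id for t in library]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate target ids in library")

    scored: list[tuple[str, float, int, bool]] = []
    failures: list[tuple[str, str]] = []
    records: dict[str, dict] = {}
    meta: dict[str, tuple[int, bool]] = {}
    for target in sorted(library, key=lambda t: t.target_id):
        cfgs = [replace(cfg, seed=stable_seed(cfg.seed, target.target_id))
                for cfg in engine_cfgs]
        try:
            ensembles, _ = run_engine_panel(cfgs, ligand, target.receptor, target.box,
                                            strict=strict, target_id=target.target_id)
            winner, pose, _ = run_consensus(ensembles, threshold, symmetry_aware)
        except Exception as exc:  # noqa: BLE001 — per-target failure note
            if strict:
                raise
            failures.append((target.target_id, str(exc)))
            continue
        rec: dict = {"empirical": empirical_score(target.receptor, pose, coeffs)}
        if external_energies and target.target_id in external_energies:
            rec["external"] = external_energies[target.target_id]
        records[target.target_id] = rec
        meta[target.target_id] = (winner.engine_votes, winner.tie_broken)
    if not records:
        raise ValidationError(
            "all targets failed: " + "; ".join(f"{t}: {e}" for t, e in failures))

    energies = rank_energy(records, scheme)
    order = sorted(energies, key=lambda t: (energies[t], -meta[t][0], t))
    rows = [ScreenRow(rank, t, energies[t], meta[t][0], meta[t][1])
            for rank, t in enumerate(order, start=1)]
    return RankedScreenResult(ligand.name, rows, scheme, failures)


def ranked_result_from_energies(ligand_id: str, energies: Mapping[str, float],
                                scheme: str = "external",
                                engine_votes: Mapping[str, int] | None = None,
                                ) -> RankedScreenResult:
    """Rank a plain target → ΔG_bind map (e.g. an ingested external table)."""
    if not energies:
        raise ValidationError("no energies to rank")
    votes = engine_votes or {}
    order = sorted(energies, key=lambda t: (energies[t], -votes.get(t, 0), t))
    rows = [ScreenRow(rank, t, float(energies[t]), votes.get(t, 0), False)
            for rank, t in enumerate(order, start=1)]
    return RankedScreenResult(ligand_id, rows, scheme)


def top_fraction(result: RankedScreenResult, k: float) -> set[str]:
    """Targets ranked within the best k% of positions: rank ≤ floor(k/100 · N)."""
    if not 0 < k <= 100:
        raise ValidationError(f"k must lie in (0, 100], got {k}")
    cutoff = math.floor(k / 100.0 * result.n_ranked)
    return {r.target_id for r in result.rows if r.rank <= cutoff}
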