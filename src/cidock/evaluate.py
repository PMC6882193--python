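"""Target-fishing performance statistics.

A screened ligand's known targets are the positives.  A known target counts
as recovered at level k when its rank falls within the best k% of library
positions; binarizing at that cutoff yields the TP/FP/TN/FN confusion
counts.  The ROC is swept over all rank thresholds, so the AUC equals the
probability that a random known target receives a lower (better) energy
than a random non-target, with ties counted one half (rank-sum
formulation).  Panel summaries report per-drug success rates (share of
drugs with ≥ 1 known target recovered) and pooled TOP percentages (share
of all known targets recovered).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import UsageError, ValidationError
from .screen import RankedScreenResult, top_fraction


@dataclass(frozen=True)
class KnownTargetAnnotation:
    """The experimentally confirmed targets of one ligand (the positives)."""

    ligand_id: str
    known_target_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.known_target_ids:
            raise ValidationError(f"ligand {self.ligand_id!r} has no known targets")


def read_annotations(path: str | Path) -> dict[str, KnownTargetAnnotation]:
    """Tab-separated 'ligand_id<TAB>known_target_id' pairs, one per line."""
    pairs: dict[str, set[str]] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}:{ln}: expected 'ligand<TAB>target'")
        pairs.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return {lig: KnownTargetAnnotation(lig, frozenset(targets))
            for lig, targets in pairs.items()}


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def binarize_at_top(result: RankedScreenResult, annotation: KnownTargetAnnotation,
                    k: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) from the top-k% cutoff.

    Known targets inside the top fraction are true positives; non-targets
    inside are false positives; the rest partition accordingly.
    """
    screened = {r.target_id for r in result.rows}
    unknown = sorted(annotation.known_target_ids - screened)
    if unknown:
        raise ValidationError(
            f"known targets not present in the screened library: {unknown}")
    top = top_fraction(result, k)
    known = annotation.known_target_ids
    tp = len(known & top)
    fn = len(known - top)
    fp = len(top - known)
    tn = len(screened - known - top)
    return tp, fp, tn, fn


def roc_auc(energies: Mapping[str, float], positives: Iterable[str]) -> float:
    """AUC of the energy ranking: P(energy_pos < energy_neg), ties at 1/2.

    Computed by the rank-sum (Mann-Whitney) formulation, which equals the
    trapezoidal area under the ROC curve swept over all thresholds.
    """
    positives = set(positives)
    ids = list(energies)
    labels = np.array([t in positives for t in ids])
    n_pos = int(labels.sum())
    n_neg = len(ids) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UsageError("AUC is undefined without at least one positive "
                         "and one negative target")
    values = np.array([energies[t] for t in ids], dtype=float)
    ranks = rankdata(values)                       # ascending: best energy = rank 1
    u_against = float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0
    return 1.0 - u_against / (n_pos * n_neg)


def drug_success_rate(n_success: int, n_drugs: int) -> float:
    """Per-drug success percentage, rounded half-up to 2 decimals."""
    if n_drugs < 1 or not 0 <= n_success <= n_drugs:
        raise ValidationError("need 0 <= n_success <= n_drugs, n_drugs >= 1")
    return _round_half_up(100.0 * n_success / n_drugs, 2)


def target_recovery_top(n_recovered: int, n_known_total: int, k: float | None = None,
                        ) -> int:
    """Pooled TOP percentage: share of all known targets recovered at level k,
    rounded half-up to the nearest integer percent."""
    if n_known_total < 1 or not 0 <= n_recovered <= n_known_total:
        raise ValidationError("need 0 <= n_recovered <= n_known_total >= 1")
    return int(_round_half_up(100.0 * n_recovered / n_known_total, 0))


@dataclass
class EvaluationReport:
    """Panel-level summary of a multi-drug inverse screen."""

    per_ligand: pd.DataFrame            # ligand_id, k, TP, FP, TN, FN, success
    auc_per_ligand: dict[str, float]
    auc_macro: float
    success_rates: dict[float, float]   # k -> percent (2 decimals)
    top_percentages: dict[float, int]   # k -> integer percent
    false_positive_rates: dict[float, float]  # k -> percent of non-targets in top
    n_drugs: int = 0
    n_known_total: int = 0
    notes: list[str] = field(default_factory=list)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "n_drugs": self.n_drugs,
            "n_known_total": self.n_known_total,
            "auc_macro": self.auc_macro,
            "auc_per_ligand": self.auc_per_ligand,
            "success_rates": {str(k): v for k, v in self.success_rates.items()},
            "top_percentages": {str(k): v for k, v in self.top_percentages.items()},
            "false_positive_rates": {str(k): v
                                     for k, v in self.false_positive_rates.items()},
            "per_ligand": self.per_ligand.to_dict(orient="records"),
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def write_tsv(self, path: str | Path) -> None:
        self.per_ligand.to_csv(path, sep="\t", index=False)


def evaluate_panel(results: Mapping[str, RankedScreenResult],
                   annotations: Mapping[str, KnownTargetAnnotation],
                   ks: tuple[float, ...] = (2.0, 5.0, 10.0)) -> EvaluationReport:
    """Confusion counts, AUCs, success rates and TOP percentages for a panel.

    Per-drug AUCs are macro-averaged; TOP percentages and false-positive
    rates pool counts over all drugs.
    """
    if not results:
        raise ValidationError("no screen results to evaluate")
    missing = sorted(set(results) - set(annotations))
    if missing:
        raise ValidationError(f"no annotation for ligands: {missing}")

    rows = []
    aucs: dict[str, float] = {}
    notes: list[str] = []
    for lig, result in results.items():
        ann = annotations[lig]
        aucs[lig] = roc_auc(result.energies(), ann.known_target_ids)
        for k in ks:
            tp, fp, tn, fn = binarize_at_top(result, ann, k)
            rows.append({"ligand_id": lig, "k": k, "TP": tp, "FP": fp,
                         "TN": tn, "FN": fn, "success": tp > 0})
    per_ligand = pd.DataFrame(rows)

    success_rates = {}
    top_percentages = {}
    fprs = {}
    n_known_total = sum(len(annotations[lig].known_target_ids) for lig in results)
    for k in ks:
        sub = per_ligand[per_ligand["k"] == k]
        success_rates[k] = drug_success_rate(int(sub["success"].sum()), len(results))
        top_percentages[k] = target_recovery_top(int(sub["TP"].sum()), n_known_total, k)
        denom = int((sub["FP"] + sub["TN"]).sum())
        fprs[k] = _round_half_up(100.0 * int(sub["FP"].sum()) / denom, 2) if denom else 0.0
    for lig, result in results.items():
        for target_id, err in result.failures:
            notes.append(f"{lig}: target {target_id} unranked ({err})")

    return EvaluationReport(per_ligand, aucs, float(np.mean(list(aucs.values()))),
                            success_rates, top_percentages, fprs,
                            n_drugs=len(results), n_known_total=n_known_total,
                            notes=notes)
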