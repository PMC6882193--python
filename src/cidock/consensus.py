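"""Two-level cluster-vote consensus across docking engines.

Level 1 (within an engine): the pose ensemble is leader-clustered at a 2.0 Å
in-place RMSD threshold, visiting poses best-score-first.  A cluster's *vote*
is its pose count and its representative is its best-scoring member.

Level 2 (across engines): the representatives of every engine's clusters are
pooled into a new ensemble and clustered with the same rule.  A consensus
cluster's *engine votes* is the number of distinct engines contributing a
representative to it — four agreeing engines yield four votes.  Ties on
engine votes are judged by total pose support (the sum of the contributing
single-engine cluster votes), then by representative score, then pose id, so
selection is fully deterministic.

Raw scores are never compared across engines; only votes and pose supports
cross the engine boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .geometry import DEFAULT_AUTOMORPHISM_CAP, heavy_automorphisms, rmsd_to_leaders
from .molecules import Pose, PoseEnsemble

CONSENSUS_ENGINE_ID = "consensus"
DEFAULT_RMSD_THRESHOLD = 2.0


@dataclass
class ConformationalCluster:
    """A set of mutually similar poses; vote = member count."""

    member_pose_ids: list[str]
    vote: int
    representative_pose_id: str
    engine_id: str

    def __post_init__(self) -> None:
        if not self.member_pose_ids:
            raise ValidationError("cluster must have at least one member")
        if self.vote != len(self.member_pose_ids):
            raise ValidationError("cluster vote must equal its member count")
        if self.representative_pose_id not in self.member_pose_ids:
            raise ValidationError("cluster representative must be a member")


@dataclass
class ConsensusResult:
    """The cross-engine winning cluster and how it won."""

    winning_cluster: ConformationalCluster
    engine_votes: int
    supporting_engines: frozenset[str]
    total_pose_support: int
    tie_broken: bool
    consensus_pose_id: str
    representative_score: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.engine_votes != len(self.supporting_engines):
            raise ValidationError("engine_votes must equal the supporting engine count")
        if self.consensus_pose_id != self.winning_cluster.representative_pose_id:
            raise ValidationError("consensus pose must be the winning cluster's representative")


def _leader_cluster(items: list[tuple[str, Pose]], threshold: float,
                    symmetry_aware: bool,
                    automorphism_cap: int) -> list[list[int]]:
    """Leader clustering over (pose_id, Pose) items in the given visit order.

    Returns index groups into ``items``; a pose joins the first cluster whose
    *leader* (founding pose) is strictly within ``threshold`` Å.
    """
    mol0 = items[0][1].molecule
    if symmetry_aware:
        perms = heavy_automorphisms(mol0, cap=automorphism_cap)
    else:
        perms = np.arange(mol0.n_heavy, dtype=int)[None, :]
    clusters: list[list[int]] = []
    leader_coords: list[np.ndarray] = []
    for idx, (_, pose) in enumerate(items):
        if leader_coords:
            d = rmsd_to_leaders(pose.heavy_coords, np.stack(leader_coords), perms)
            hit = np.nonzero(d < threshold)[0]
        else:
            hit = np.array([], dtype=int)
        if hit.size:
            clusters[int(hit[0])].append(idx)
        else:
            clusters.append([idx])
            leader_coords.append(pose.heavy_coords)
    return clusters


def cluster_poses(ensemble: PoseEnsemble, threshold: float = DEFAULT_RMSD_THRESHOLD,
                  symmetry_aware: bool = True,
                  automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP,
                  ) -> list[ConformationalCluster]:
    """Leader-cluster one engine's poses at the RMSD threshold (strict <).

    Poses are visited best-score-first (ties by pose index), so every leader —
    and hence every representative — is its cluster's best-scoring member.
    Clusters are returned sorted by vote, descending.
    """
    if threshold <= 0:
        raise ValidationError("clustering threshold must be positive")
    order = sorted(ensemble.poses, key=lambda p: (p.engine_score, p.pose_index))
    items = [(p.pose_id, p) for p in order]
    groups = _leader_cluster(items, threshold, symmetry_aware, automorphism_cap)
    clusters = []
    for g in groups:
        members = [items[i][0] for i in g]
        rep = min((items[i][1] for i in g),
                  key=lambda p: (p.engine_score, p.pose_index))
        clusters.append(ConformationalCluster(members, len(members),
                                              rep.pose_id, ensemble.engine_id))
    rep_pose = {c.representative_pose_id: ensemble.pose_by_id(c.representative_pose_id)
                for c in clusters}
    clusters.sort(key=lambda c: (-c.vote, rep_pose[c.representative_pose_id].engine_score,
                                 rep_pose[c.representative_pose_id].pose_index))
    return clusters


def select_representative(cluster: ConformationalCluster,
                          ensemble: PoseEnsemble) -> Pose:
    """Best-scoring member of a cluster; equal scores break to lowest pose index."""
    members = []
    for pid in cluster.member_pose_ids:
        try:
            members.append(ensemble.pose_by_id(pid))
        except KeyError:
            raise ValidationError(
                f"cluster member {pid!r} not found in ensemble {ensemble.engine_id!r}")
    return min(members, key=lambda p: (p.engine_score, p.pose_index))


def consensus_vote(per_engine_clusters: Mapping[str, list[ConformationalCluster]],
                   representatives: Mapping[str, Pose],
                   threshold: float = DEFAULT_RMSD_THRESHOLD,
                   symmetry_aware: bool = True,
                   automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP,
                   ) -> list[ConsensusResult]:
    """Pool per-engine representatives and cluster them at the same threshold.

    Candidates come back ordered by (engine votes desc, total pose support
    desc, representative score asc, pose id); ``select_consensus`` takes the
    head of this list.
    """
    if not per_engine_clusters or all(not v for v in per_engine_clusters.values()):
        raise ValidationError("consensus_vote requires at least one engine with clusters")
    entries: list[tuple[str, Pose, str, int]] = []   # (rep_id, pose, engine, vote)
    for engine_id in sorted(per_engine_clusters):
        for cluster in per_engine_clusters[engine_id]:
            rep_id = cluster.representative_pose_id
            if rep_id not in representatives:
                raise ValidationError(f"no pose provided for representative {rep_id!r}")
            entries.append((rep_id, representatives[rep_id], engine_id, cluster.vote))
    # deterministic pooled visit order that never compares scores across engines
    entries.sort(key=lambda e: (-e[3], e[2], e[1].pose_index))
    items = [(rep_id, pose) for rep_id, pose, _, _ in entries]
    groups = _leader_cluster(items, threshold, symmetry_aware, automorphism_cap)

    candidates = []
    for g in groups:
        member_entries = [entries[i] for i in g]
        member_ids = [e[0] for e in member_entries]
        engines = frozenset(e[2] for e in member_entries)
        support = sum(e[3] for e in member_entries)
        rep_id, rep_pose, _, _ = min(
            member_entries, key=lambda e: (e[1].engine_score, e[1].pose_index, e[2]))
        cluster = ConformationalCluster(member_ids, len(member_ids), rep_id,
                                        CONSENSUS_ENGINE_ID)
        candidates.append(ConsensusResult(
            winning_cluster=cluster, engine_votes=len(engines),
            supporting_engines=engines, total_pose_support=support,
            tie_broken=False, consensus_pose_id=rep_id,
            representative_score=rep_pose.engine_score))
    candidates.sort(key=lambda c: (-c.engine_votes, -c.total_pose_support,
                                   c.representative_score, c.consensus_pose_id))
    return candidates


def select_consensus(candidates: list[ConsensusResult]) -> ConsensusResult:
    """Pick the winning consensus cluster from ordered candidates.

    The full ordering is (engine votes desc, total pose support desc,
    representative score asc, lexicographic pose id); ``tie_broken`` flags a
    winner that tied on engine votes and needed the deeper cascade.
    """
    if not candidates:
        raise ValidationError("select_consensus requires at least one candidate")
    ordered = sorted(candidates, key=lambda c: (-c.engine_votes, -c.total_pose_support,
                                                c.representative_score,
                                                c.consensus_pose_id))
    winner = ordered[0]
    tie = len(ordered) > 1 and ordered[1].engine_votes == winner.engine_votes
    return replace(winner, tie_broken=tie)


def run_consensus(ensembles: Mapping[str, PoseEnsemble],
                  threshold: float = DEFAULT_RMSD_THRESHOLD,
                  symmetry_aware: bool = True,
                  ) -> tuple[ConsensusResult, Pose, dict[str, list[ConformationalCluster]]]:
    """Full two-level pipeline: per-engine clustering, cross-engine vote, selection.

    Returns the winning consensus result, its representative pose, and the
    per-engine cluster lists for reporting.
    """
    per_engine: dict[str, list[ConformationalCluster]] = {}
    representatives: dict[str, Pose] = {}
    for engine_id, ens in ensembles.items():
        clusters = cluster_poses(ens, threshold, symmetry_aware)
        per_engine[engine_id] = clusters
        for c in clusters:
            representatives[c.representative_pose_id] = \
                ens.pose_by_id(c.representative_pose_id)
    candidates = consensus_vote(per_engine, representatives, threshold, symmetry_aware)
    winner = select_consensus(candidates)
    return winner, representatives[winner.consensus_pose_id], per_engine
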