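"""The cluster-vote consensus: clustering, voting, tie-breaking, selection."""

import numpy as np
import networkx as nx
import pytest

from cidock.consensus import (
    ConformationalCluster,
    cluster_poses,
    consensus_vote,
    run_consensus,
    select_consensus,
    select_representative,
)
from cidock.errors import ValidationError
from cidock.geometry import pose_rmsd
from cidock.molecules import Pose, PoseEnsemble
from cidock.synthgen import EnsembleSpec, make_pose_ensembles, make_toy_ligand


def _ensemble(ligand, offsets, scores, engine="ENG"):
    poses = [Pose(ligand.translated(off), engine, s, k)
             for k, (off, s) in enumerate(zip(offsets, scores))]
    return PoseEnsemble(ligand.name, "tgt", engine, poses, max_poses=len(poses))


def connected_components_oracle(ensemble, threshold=2.0):
    """Independent clustering oracle for well-separated data: connected
    components of the graph joining pose pairs with RMSD below threshold."""
    g = nx.Graph()
    g.add_nodes_from(p.pose_id for p in ensemble.poses)
    for i, a in enumerate(ensemble.poses):
        for b in ensemble.poses[i + 1:]:
            if pose_rmsd(a, b) < threshold:
                g.add_edge(a.pose_id, b.pose_id)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestClusterPoses:
    def test_single_pose(self, chain_ligand):
        ens = _ensemble(chain_ligand, [np.zeros(3)], [-9.0])
        clusters = cluster_poses(ens)
        assert len(clusters) == 1
        assert clusters[0].vote == 1
        assert clusters[0].representative_pose_id == "ENG:0"

    def test_two_poses_below_threshold_merge(self, chain_ligand):
        ens = _ensemble(chain_ligand, [np.zeros(3), np.array([1.5, 0, 0])],
                        [-9.0, -8.0])
        clusters = cluster_poses(ens, threshold=2.0)
        assert len(clusters) == 1 and clusters[0].vote == 2

    def test_threshold_is_strict(self):
        # RMSD exactly 2.0 must start a new cluster ("lower than" is strict);
        # exactly representable coordinates so the RMSD is exactly 2.0
        from cidock.molecules import Molecule
        clean = Molecule("clean", ["N", "C"],
                         np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]), [(0, 1, 1)])
        ens = _ensemble(clean, [np.zeros(3), np.array([2.0, 0, 0])], [-9.0, -8.0])
        assert len(cluster_poses(ens, threshold=2.0)) == 2
        assert len(cluster_poses(ens, threshold=2.0 + 1e-9)) == 1

    def test_representative_is_best_scoring_member(self, chain_ligand):
        ens = _ensemble(chain_ligand,
                        [np.zeros(3), np.array([0.5, 0, 0]), np.array([0, 0.5, 0])],
                        [-7.0, -9.1, -8.5])
        clusters = cluster_poses(ens)
        assert clusters[0].representative_pose_id == "ENG:1"

    def test_planted_blobs_match_connected_components_oracle(self, chain_ligand):
        spec = EnsembleSpec(1, 30, [[0, 0, 0], [10, 0, 0], [0, 12, 0]],
                            [[17, 9, 4]], intra_site_jitter=0.25, seed=21)
        ensembles, truth = make_pose_ensembles(spec, chain_ligand)
        ens = next(iter(ensembles.values()))
        clusters = cluster_poses(ens)
        assert sorted(c.vote for c in clusters) == [4, 9, 17]
        got = {frozenset(c.member_pose_ids) for c in clusters}
        assert got == connected_components_oracle(ens)
        for c in clusters:  # every cluster is one planted site
            assert len({truth[pid] for pid in c.member_pose_ids}) == 1

    def test_vote_conservation_and_partition(self, chain_ligand):
        for seed in range(30):
            spec = EnsembleSpec(1, 24, [[0, 0, 0], [9, 0, 0]], [[15, 9]],
                                intra_site_jitter=0.4, seed=seed)
            ens = next(iter(make_pose_ensembles(spec, chain_ligand)[0].values()))
            clusters = cluster_poses(ens)
            assert sum(c.vote for c in clusters) == len(ens)
            members = [pid for c in clusters for pid in c.member_pose_ids]
            assert sorted(members) == sorted(p.pose_id for p in ens.poses)

    def test_input_order_invariance(self, chain_ligand):
        spec = EnsembleSpec(1, 20, [[0, 0, 0], [8, 0, 0]], [[12, 8]],
                            intra_site_jitter=0.5, seed=5)
        ens = next(iter(make_pose_ensembles(spec, chain_ligand)[0].values()))
        baseline = [frozenset(c.member_pose_ids) for c in cluster_poses(ens)]
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = PoseEnsemble(ens.ligand_id, ens.target_id, ens.engine_id,
                                    list(rng.permutation(ens.poses)),
                                    max_poses=len(ens.poses))
            assert [frozenset(c.member_pose_ids)
                    for c in cluster_poses(shuffled)] == baseline

    def test_empty_rejected(self, chain_ligand):
        with pytest.raises(ValidationError):
            PoseEnsemble("l", "t", "E", [])


class TestSelectRepresentative:
    def test_best_score_and_tie_break(self, chain_ligand):
        ens = _ensemble(chain_ligand, [np.zeros(3)] * 3, [-7.0, -9.1, -9.1])
        cluster = ConformationalCluster(["ENG:0", "ENG:1", "ENG:2"], 3, "ENG:1", "ENG")
        rep = select_representative(cluster, ens)
        assert rep.pose_id == "ENG:1"  # -9.1, lower pose_index than ENG:2

    def test_missing_member_raises(self, chain_ligand):
        ens = _ensemble(chain_ligand, [np.zeros(3)], [-7.0])
        cluster = ConformationalCluster(["ENG:9"], 1, "ENG:9", "ENG")
        with pytest.raises(ValidationError):
            select_representative(cluster, ens)


def _cluster(engine, idx, vote, rep_pose):
    members = [f"{engine}:{idx * 100 + m}" for m in range(vote)]
    members[0] = rep_pose.pose_id
    return ConformationalCluster(members, vote, rep_pose.pose_id, engine)


class TestConsensusVote:
    def test_four_agreeing_engines_score_four_votes(self, chain_ligand):
        reps, clusters = {}, {}
        for k, engine in enumerate(["LEDOCK", "PSOVina", "Vina", "PLANTS"]):
            pose = Pose(chain_ligand.translated([0.2 * k, 0, 0]), engine, -9.0, 0)
            reps[pose.pose_id] = pose
            clusters[engine] = [_cluster(engine, 0, 10, pose)]
        winner = select_consensus(consensus_vote(clusters, reps))
        assert winner.engine_votes == 4
        assert winner.supporting_engines == frozenset(
            ["LEDOCK", "PSOVina", "Vina", "PLANTS"])

    def test_single_engine_gives_single_votes(self, chain_ligand):
        pose_a = Pose(chain_ligand, "E1", -9.0, 0)
        pose_b = Pose(chain_ligand.translated([8, 0, 0]), "E1", -7.0, 1)
        reps = {p.pose_id: p for p in (pose_a, pose_b)}
        clusters = {"E1": [_cluster("E1", 0, 5, pose_a), _cluster("E1", 1, 3, pose_b)]}
        assert all(c.engine_votes == 1 for c in consensus_vote(clusters, reps))

    def test_engine_vote_tie_judged_by_pose_support(self, chain_ligand):
        site_a, site_b = np.zeros(3), np.array([10.0, 0, 0])
        reps, clusters = {}, {}
        for engine, site, vote in [("E1", site_a, 40), ("E2", site_a, 35),
                                   ("E3", site_b, 10), ("E4", site_b, 12)]:
            pose = Pose(chain_ligand.translated(site), engine, -8.0, 0)
            reps[pose.pose_id] = pose
            clusters[engine] = [_cluster(engine, 0, vote, pose)]
        candidates = consensus_vote(clusters, reps)
        assert [c.engine_votes for c in candidates] == [2, 2]
        assert [c.total_pose_support for c in candidates] == [75, 22]
        winner = select_consensus(candidates)
        assert winner.supporting_engines == frozenset(["E1", "E2"])
        assert winner.tie_broken

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            consensus_vote({}, {})


class TestSelectConsensus:
    def test_highest_vote_wins(self, chain_ligand):
        sites = [np.zeros(3), np.array([10.0, 0, 0]), np.array([0, 10.0, 0])]
        reps, clusters = {}, {}
        engines = [["E1", "E2", "E3", "E4"], ["E1", "E2"], ["E3"]]
        for s, (site, engs) in enumerate(zip(sites, engines)):
            for engine in engs:
                pose = Pose(chain_ligand.translated(site), engine, -8.0, s)
                reps[pose.pose_id] = pose
                clusters.setdefault(engine, []).append(_cluster(engine, s, 5, pose))
        winner = select_consensus(consensus_vote(clusters, reps))
        assert winner.engine_votes == 4
        assert not winner.tie_broken  # second-best candidate has only 2 votes

    def test_votes_and_support_tied_breaks_on_representative_score(self, chain_ligand):
        reps, clusters = {}, {}
        for engine, site, score in [("E1", np.zeros(3), -9.5),
                                    ("E2", np.array([10.0, 0, 0]), -6.0)]:
            pose = Pose(chain_ligand.translated(site), engine, score, 0)
            reps[pose.pose_id] = pose
            clusters[engine] = [_cluster(engine, 0, 7, pose)]
        winner = select_consensus(consensus_vote(clusters, reps))
        assert winner.supporting_engines == frozenset(["E1"])
        assert winner.representative_score == -9.5
        assert winner.tie_broken

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValidationError):
            select_consensus([])


class TestEndToEndConsensus:
    def test_adding_agreeing_engine_never_lowers_votes(self, chain_ligand):
        weights3 = [[16, 8], [14, 10], [20, 4]]
        spec3 = EnsembleSpec(3, 24, [[0, 0, 0], [9, 0, 0]], weights3,
                             intra_site_jitter=0.3, seed=17)
        ens3, _ = make_pose_ensembles(spec3, chain_ligand)
        votes3 = run_consensus(ens3)[0].engine_votes
        spec4 = EnsembleSpec(4, 24, [[0, 0, 0], [9, 0, 0]],
                             weights3 + [[18, 6]], intra_site_jitter=0.3, seed=17)
        ens4, _ = make_pose_ensembles(spec4, chain_ligand)
        assert run_consensus(ens4)[0].engine_votes >= votes3

    def test_consensus_pose_is_winning_representative(self, chain_ligand):
        spec = EnsembleSpec(4, 20, [[0, 0, 0], [9, 0, 0]], None,
                            intra_site_jitter=0.3, seed=2)
        ensembles, _ = make_pose_ensembles(spec, chain_ligand)
        winner, pose, _ = run_consensus(ensembles)
        assert pose.pose_id == winner.consensus_pose_id
        assert winner.consensus_pose_id == winner.winning_cluster.representative_pose_id
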