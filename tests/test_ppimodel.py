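"""Pose clustering, consensus model selection and interface overlap."""

import numpy as np
import pytest

from conftest import brute_force_select
from ppiscreen import synthkit
from ppiscreen.ppimodel import (
    OverlapReport,
    PoseEnsemble,
    cluster_poses,
    overlap_analysis,
    read_pose_ensemble,
    select_model,
)
from ppiscreen.structio import Atom, Structure


def _ensemble(coords, scores, receptor=None):
    if receptor is None:
        receptor = Structure(models=[[Atom(1, "C", "CA", "R", 1, "", "GLY", (0.0, 0.0, 0.0))]])
    return PoseEnsemble(receptor, np.asarray(coords, float), np.asarray(scores, float))


class TestClusterPoses:
    def test_identical_poses_form_one_cluster(self):
        base = np.zeros((1, 4, 3))
        e = _ensemble(np.repeat(base, 10, axis=0), np.arange(10.0))
        clusters = cluster_poses(e, rmsd_threshold=5.0)
        assert len(clusters) == 1 and clusters[0].size == 10

    def test_zero_threshold_gives_singletons(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(6, 3, 3)) * 10
        e = _ensemble(coords, np.arange(6.0))
        clusters = cluster_poses(e, rmsd_threshold=0.0)
        assert len(clusters) == 6
        assert all(c.size == 1 for c in clusters)

    def test_planted_cluster_sizes_recovered(self, pose_ensemble_60_30_10):
        rec, coords, scores, truth = pose_ensemble_60_30_10
        e = PoseEnsemble(rec, coords, scores)
        clusters = cluster_poses(e, rmsd_threshold=5.0)
        assert sorted((c.size for c in clusters), reverse=True) == [60, 30, 10]
        # recovered membership matches the generator's assignment exactly
        assign = truth.labels["assignments"]
        for c in clusters:
            assert len({assign[i] for i in c.members}) == 1

    def test_clusters_partition_the_ensemble(self, pose_ensemble_60_30_10):
        rec, coords, scores, _ = pose_ensemble_60_30_10
        clusters = cluster_poses(PoseEnsemble(rec, coords, scores), 5.0)
        seen = [i for c in clusters for i in c.members]
        assert sorted(seen) == list(range(len(coords)))

    def test_atom_count_mismatch_rejected(self):
        rec = Structure(models=[[Atom(1, "C", "CA", "R", 1, "", "GLY", (0.0, 0.0, 0.0))]])
        poses = Structure(
            models=[
                [Atom(1, "C", "CA", "P", 1, "", "GLY", (0.0, 0.0, 0.0))],
                [Atom(1, "C", "CA", "P", 1, "", "GLY", (0.0, 0.0, 0.0)),
                 Atom(2, "C", "CA", "P", 2, "", "GLY", (1.0, 0.0, 0.0))],
            ]
        )
        with pytest.raises(ValueError, match="differ"):
            read_pose_ensemble(rec, poses, [0.0, 1.0])


class TestSelectModel:
    def test_global_best_outside_largest_cluster_is_skipped(self, pose_ensemble_60_30_10):
        rec, coords, scores, truth = pose_ensemble_60_30_10
        e = PoseEnsemble(rec, coords, scores)
        clusters = cluster_poses(e, 5.0)
        sel = select_model(clusters, e)
        assign = truth.labels["assignments"]
        # global best was planted in the 10-member cluster
        assert assign[int(np.argmin(scores))] == truth.labels["best_cluster"]
        assert truth.labels["best_cluster"] != 0
        # selection goes to the best member of the 60-member cluster instead
        assert assign[sel] == 0
        assert sel == brute_force_select(assign, scores)

    def test_single_cluster_returns_its_best(self):
        base = np.zeros((1, 3, 3))
        e = _ensemble(np.repeat(base, 5, axis=0), [3.0, -1.0, 2.0, 0.0, 5.0])
        clusters = cluster_poses(e, 5.0)
        assert select_model(clusters, e) == 1

    def test_matches_brute_force_on_many_random_ensembles(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sizes = [int(x) for x in rng.integers(2, 12, size=3)]
            rec, coords, scores, truth = synthkit.make_pose_ensemble(
                sizes, jitter=0.8, separation=20.0, seed=seed,
                best_cluster=int(rng.integers(3)),
            )
            e = PoseEnsemble(rec, coords, scores)
            sel = select_model(cluster_poses(e, 5.0), e)
            assert sel == brute_force_select(truth.labels["assignments"], scores)

    def test_invariant_under_uniform_score_shift(self, pose_ensemble_60_30_10):
        rec, coords, scores, _ = pose_ensemble_60_30_10
        e1 = PoseEnsemble(rec, coords, scores)
        e2 = PoseEnsemble(rec, coords, scores + 100.0)
        assert select_model(cluster_poses(e1, 5.0), e1) == select_model(
            cluster_poses(e2, 5.0), e2
        )


def _partner(chain, positions):
    return Structure(
        models=[
            [Atom(i + 1, "C", "CA", chain, i + 1, "", "GLY", tuple(map(float, p)))
             for i, p in enumerate(positions)]
        ]
    )


def _receptor_row(n):
    return Structure(
        models=[
            [Atom(i + 1, "C", "CA", "R", i + 1, "", "GLY", (float(4 * i), 0.0, 0.0))
             for i in range(n)]
        ]
    )


class TestOverlap:
    def test_disjoint_faces_not_exclusive(self):
        rec = _receptor_row(10)
        a = _partner("A", [(0.0, 3.0, 0.0)])
        b = _partner("B", [(36.0, -3.0, 0.0)])
        rep = overlap_analysis(rec, a, b, cutoff=4.0)
        assert rep.jaccard == 0.0 and not rep.mutually_exclusive

    def test_identical_placements_fully_exclusive(self):
        rec = _receptor_row(10)
        a = _partner("A", [(12.0, 3.0, 0.0)])
        b = _partner("B", [(12.0, 3.0, 0.0)])
        rep = overlap_analysis(rec, a, b, cutoff=4.0)
        assert rep.jaccard == 1.0 and rep.mutually_exclusive

    def test_constructed_six_of_eighteen(self):
        # patchA = residues 1-12, patchB = residues 7-18: |A∩B|=6, |A∪B|=18
        rec = _receptor_row(18)
        a = _partner("A", [(4.0 * i, 2.0, 0.0) for i in range(0, 12)])
        b = _partner("B", [(4.0 * i, -2.0, 0.0) for i in range(6, 18)])
        rep = overlap_analysis(rec, a, b, cutoff=3.0)
        assert len(rep.patchA) == 12 and len(rep.patchB) == 12
        assert rep.jaccard == pytest.approx(6.0 / 18.0, abs=1e-12)
        assert rep.mutually_exclusive  # 0.333 >= default threshold 0.25

    def test_shared_chain_ids_rejected(self):
        rec = _receptor_row(3)
        a = _partner("R", [(0.0, 2.0, 0.0)])
        with pytest.raises(ValueError, match="chain ids"):
            overlap_analysis(rec, a, a)
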