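"""Protein-protein docking post-processing: pose clustering, consensus model
selection, and interface-overlap analysis.

Rigid-body protein-protein docking engines emit thousands of candidate
complex models. The selection rule implemented here picks the model with the
best (lowest) docking score *among members of the largest structural
cluster* — a consensus criterion that discards well-scored but unsupported
outliers. Clustering is greedy centroid clustering on pairwise partner RMSD
with the receptors already in a common frame: repeatedly take the unassigned
pose with the most unassigned neighbors within the RMSD threshold as a
cluster center and assign it together with those neighbors (ties break to
the lower model index).

Overlap analysis quantifies whether two partners can bind the receptor
simultaneously: each partner's receptor footprint (residues within a contact
cutoff) is compared by Jaccard similarity, and footprints above an
exclusivity threshold flag the partners as mutually exclusive binders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import InterfaceSet, Structure, interface_residues

__all__ = [
    "PoseEnsemble",
    "PoseCluster",
    "OverlapReport",
    "cluster_poses",
    "select_model",
    "overlap_analysis",
    "read_pose_ensemble",
    "DEFAULT_ENSEMBLE_SIZE",
]

#: conventional ensemble size produced by rigid-body PP docking runs
DEFAULT_ENSEMBLE_SIZE = 5000

DEFAULT_RMSD_THRESHOLD = 5.0
DEFAULT_EXCLUSIVITY_THRESHOLD = 0.25


@dataclass
class PoseEnsemble:
    receptor: Structure
    coords: np.ndarray  # (n_poses, n_atoms, 3) partner coordinates
    scores: np.ndarray  # (n_poses,), lower = better

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be (n_poses, n_atoms, 3)")
        if len(self.scores) != len(self.coords):
            raise ValueError("scores/poses length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class PoseCluster:
    members: list[int]
    best_member: int  # best score within the cluster
    representative_rmsd: float  # mean member RMSD to the cluster center

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class OverlapReport:
    patchA: set
    patchB: set
    jaccard: float
    mutually_exclusive: bool
    exclusivity_threshold: float = DEFAULT_EXCLUSIVITY_THRESHOLD

    def to_json_dict(self) -> dict:
        return {
            "patchA": sorted([list(r) for r in self.patchA]),
            "patchB": sorted([list(r) for r in self.patchB]),
            "jaccard": self.jaccard,
            "mutually_exclusive": self.mutually_exclusive,
            "exclusivity_threshold": self.exclusivity_threshold,
        }


def read_pose_ensemble(receptor: Structure, poses: Structure, scores: Sequence[float]) -> PoseEnsemble:
    """Build an ensemble from a multi-model partner structure plus scores."""
    counts = {len(m) for m in poses.models}
    if len(counts) != 1:
        raise ValueError(f"partner atom counts differ across models: {sorted(counts)}")
    coords = np.stack([np.array([a.xyz for a in m]) for m in poses.models])
    return PoseEnsemble(receptor=receptor, coords=coords, scores=np.asarray(scores, float))


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    # no re-fitting: receptors are in a common frame, so partner RMSD is the
    # plain coordinate RMSD. Gram-matrix identity keeps this O(n^2) memory
    # even for thousands of poses.
    n, n_atoms = coords.shape[0], coords.shape[1]
    F = coords.reshape(n, -1)
    sq = np.einsum("ij,ij->i", F, F)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * (F @ F.T)) / n_atoms
    return np.sqrt(np.maximum(d2, 0.0))


def cluster_poses(e: PoseEnsemble, rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD) -> list[PoseCluster]:
    """Greedy centroid clustering of the ensemble by partner RMSD.

    Deterministic given the input order: at each round the unassigned pose
    with the most unassigned neighbors within the threshold becomes a center
    (ties to the lower model index) and absorbs those neighbors. Every pose
    lands in exactly one cluster; clusters are returned largest first.
    """
    if len(e) == 0:
        raise ValueError("empty ensemble")
    rmsd = _pairwise_rmsd(e.coords)
    n = len(e)
    within = rmsd <= rmsd_threshold
    unassigned = np.ones(n, dtype=bool)
    clusters: list[PoseCluster] = []
    while unassigned.any():
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax -> lowest index on ties
        members = [int(i) for i in np.nonzero(within[center] & unassigned)[0]]
        if center not in members:
            members.append(center)
        members.sort()
        unassigned[members] = False
        best = min(members, key=lambda i: (e.scores[i], i))
        rep = float(np.mean([rmsd[center, i] for i in members]))
        clusters.append(PoseCluster(members=members, best_member=best, representative_rmsd=rep))
    clusters.sort(key=lambda c: (-c.size, c.members[0]))
    return clusters


def select_model(clusters: Sequence[PoseCluster], e: PoseEnsemble) -> int:
    """Best-scoring member of the largest cluster.

    Cluster-size ties resolve to the cluster holding the globally better
    score among the tied clusters; score ties resolve to the lower model
    index.
    """
    if not clusters:
        raise ValueError("no clusters")
    top_size = max(c.size for c in clusters)
    tied = [c for c in clusters if c.size == top_size]
    winner = min(tied, key=lambda c: (e.scores[c.best_member], c.best_member))
    return winner.best_member


def clusters_to_tsv(clusters: Sequence[PoseCluster], e: PoseEnsemble, selected: int | None = None) -> str:
    lines = ["# model\tcluster\tcluster_size\tscore\tselected"]
    for ci, c in enumerate(clusters):
        for m in c.members:
            sel = "*" if m == selected else "-"
            lines.append(f"{m}\t{ci}\t{c.size}\t{e.scores[m]:.4f}\t{sel}")
    return "\n".join(lines) + "\n"


def _footprint(receptor: Structure, partner: Structure, cutoff: float) -> set:
    """Receptor residues within ``cutoff`` of any partner heavy atom."""
    combined = Structure(models=[list(receptor.atoms) + list(partner.atoms)])
    rec_chains = set(receptor.chains())
    par_chains = set(partner.chains())
    if rec_chains & par_chains:
        raise ValueError("receptor and partner share chain ids; relabel the partner")
    iface = interface_residues(combined, sorted(rec_chains), sorted(par_chains), cutoff)
    return iface.residuesA


def overlap_analysis(
    receptor: Structure,
    partnerA: Structure,
    partnerB: Structure,
    cutoff: float = 5.0,
    exclusivity_threshold: float = DEFAULT_EXCLUSIVITY_THRESHOLD,
) -> OverlapReport:
    """Compare the receptor footprints of two posed partners.

    Both partners must be posed on the *same* receptor frame. jaccard =
    |A∩B| / |A∪B| over receptor residues; at or above the exclusivity
    threshold the two partners are called mutually exclusive binders.
    """
    patchA = _footprint(receptor, partnerA, cutoff)
    patchB = _footprint(receptor, partnerB, cutoff)
    union = patchA | patchB
    jaccard = len(patchA & patchB) / len(union) if union else 0.0
    return OverlapReport(
        patchA=patchA,
        patchB=patchB,
        jaccard=jaccard,
        mutually_exclusive=jaccard >= exclusivity_threshold,
        exclusivity_threshold=exclusivity_threshold,
    )
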