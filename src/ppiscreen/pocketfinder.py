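"""Cavity detection and druggability scoring on protein surfaces.

Pockets are found with a scan-line burial criterion on a regular grid
(LIGSITE-style): a solvent grid point is *buried* when, along at least
``min_buried`` of 7 scan directions (the three axes and four body
diagonals), protein occupancy is found on both sides. Connected components
of buried solvent points above a volume floor are reported as pockets,
ranked by a documented heuristic druggability score on a pKd-like scale.

The druggability formula is an explicit linear heuristic over pocket volume,
enclosure and lining hydrophobicity — it is not a reproduction of any
commercial or published scorer's numerics; only the conventional
"druggable if predicted pKd > 6.5" decision threshold is kept as the
default flag cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structio import InterfaceSet, ResidueSpan, Structure

__all__ = [
    "Pocket",
    "DrugScore",
    "PocketClass",
    "detect_pockets",
    "score_druggability",
    "classify_pockets",
    "pockets_to_tsv",
]

#: van der Waals radii (A) for protein-occupancy marking; fallback 1.7
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.1, "P": 1.8}

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS"}

#: druggability score weights: (w_volume, w_enclosure, w_hydrophobic, bias).
#: Heuristic values chosen so that larger, more enclosed, more hydrophobic
#: pockets score higher; see docs/methods.md.
DEFAULT_WEIGHTS = (1.2, 3.0, 2.0, 0.0)

DEFAULT_PKD_THRESHOLD = 6.5

# 7 scan directions: axes + body diagonals (each used both ways)
_DIRECTIONS = [
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
]


@dataclass
class Pocket:
    grid_points: np.ndarray  # (n, 3) A
    volume: float  # A^3
    lining_residues: set  # {(chain, resnum)}
    centroid: np.ndarray
    enclosure: float
    hydrophobic_fraction: float
    spacing: float

    def __post_init__(self) -> None:
        assert abs(self.volume - len(self.grid_points) * self.spacing**3) < 1e-6


@dataclass
class DrugScore:
    predicted_pkd: float
    druggable: bool
    components: tuple[float, float, float]  # volume, enclosure, hydrophobicity terms
    threshold: float = DEFAULT_PKD_THRESHOLD


@dataclass
class PocketClass:
    label: str  # ppi_interface | annotated_site | other
    interface_overlap: float


def _occupancy_grid(
    coords: np.ndarray, elements: list[str], spacing: float, pad: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean protein-occupancy grid and its origin."""
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = tuple(int(math.floor((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    rmax = max(VDW_RADII.get(e.upper(), 1.7) for e in elements)
    tree = cKDTree(coords)
    occupied = np.zeros(len(pts), dtype=bool)
    # one query at the largest radius, then refine per-atom radius
    radii = np.array([VDW_RADII.get(e.upper(), 1.7) for e in elements])
    dist, idx = tree.query(pts, k=1, distance_upper_bound=rmax)
    hit = np.isfinite(dist)
    occupied[hit] = dist[hit] <= radii[idx[hit]]
    # atoms with smaller radii than the nearest-found atom are a corner case;
    # with near-uniform radii (dummy receptors are all carbon) this is exact
    return occupied.reshape(shape), np.array(lo)


def _directional_cover(occ: np.ndarray, d: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """For each voxel: is there protein strictly before/after along direction d?"""
    before = np.zeros_like(occ)
    after = np.zeros_like(occ)
    steps = max(occ.shape)
    cur_b = occ.copy()
    cur_a = occ.copy()
    for _ in range(steps):
        cur_b = _shift(cur_b, d)
        cur_a = _shift(cur_a, tuple(-x for x in d))
        before |= cur_b
        after |= cur_a
        if not cur_b.any() and not cur_a.any():
            break
    return before, after


def _shift(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for k, s in enumerate(d):
        if s == 1:
            src[k] = slice(0, -1)
            dst[k] = slice(1, None)
        elif s == -1:
            src[k] = slice(1, None)
            dst[k] = slice(0, -1)
    out[tuple(dst)] = a[tuple(src)]
    return out


def detect_pockets(
    s: Structure,
    spacing: float = 0.8,
    probe: float = 1.4,
    min_volume: float = 50.0,
    min_buried: int = 4,
    lining_cutoff: float = 4.0,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    threshold: float = DEFAULT_PKD_THRESHOLD,
) -> list[Pocket]:
    """Detect buried cavities on ``s`` by grid scan.

    Returns pockets sorted by predicted druggability (descending). ``probe``
    pads the grid bounding box; burial requires protein on both sides along
    at least ``min_buried`` of the 7 scan directions.
    """
    if not (0.25 <= spacing <= 2.0):
        raise ValueError("spacing must lie in [0.25, 2.0] A")
    heavy = s.heavy_atoms()
    if not heavy:
        raise ValueError("structure has no heavy atoms")
    coords = np.array([a.xyz for a in heavy])
    elements = [a.element for a in heavy]

    occ, lo = _occupancy_grid(coords, elements, spacing, pad=2.0 * probe)
    solvent = ~occ

    buried_count = np.zeros(occ.shape, dtype=np.int8)
    for d in _DIRECTIONS:
        before, after = _directional_cover(occ, d)
        buried_count += (before & after).astype(np.int8)
    buried = solvent & (buried_count >= min_buried)

    labeled, nlab = ndimage.label(buried, structure=np.ones((3, 3, 3), dtype=int))
    tree = cKDTree(coords)
    pockets: list[Pocket] = []
    for lab in range(1, nlab + 1):
        mask = labeled == lab
        npts = int(mask.sum())
        volume = npts * spacing**3
        if volume < min_volume:
            continue
        ijk = np.argwhere(mask)
        pts = lo + ijk * spacing
        neighbor_lists = tree.query_ball_point(pts, r=lining_cutoff)
        lining = set()
        for nl in neighbor_lists:
            for ai in nl:
                lining.add((heavy[ai].chain, heavy[ai].resnum))
        enclosure = float(buried_count[mask].mean() / 7.0)
        hyd = _hydrophobic_fraction(heavy, lining)
        pockets.append(
            Pocket(
                grid_points=pts,
                volume=volume,
                lining_residues=lining,
                centroid=pts.mean(axis=0),
                enclosure=enclosure,
                hydrophobic_fraction=hyd,
                spacing=spacing,
            )
        )
    pockets.sort(
        key=lambda p: -score_druggability(p, s, threshold=threshold, weights=weights).predicted_pkd
    )
    return pockets


def _hydrophobic_fraction(heavy, lining: set) -> float:
    if not lining:
        return 0.0
    resnames = {}
    for a in heavy:
        resnames[(a.chain, a.resnum)] = a.resname
    hyd = sum(1 for r in lining if resnames.get(r) in HYDROPHOBIC_RESIDUES)
    return hyd / len(lining)


def score_druggability(
    p: Pocket,
    s: Structure | None = None,
    threshold: float = DEFAULT_PKD_THRESHOLD,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> DrugScore:
    """Heuristic pKd-like druggability score.

    predicted_pkd = w_v * ln(volume) + w_e * enclosure + w_h * hydrophobic_fraction + b.
    The pocket is flagged druggable when predicted_pkd exceeds ``threshold``
    (default 6.5, the conventional cutoff for a druggable site).
    """
    if len(p.grid_points) == 0:
        raise ValueError("pocket has no grid points")
    w_v, w_e, w_h, b = weights
    terms = (
        w_v * math.log(p.volume),
        w_e * p.enclosure,
        w_h * p.hydrophobic_fraction,
    )
    pkd = sum(terms) + b
    return DrugScore(
        predicted_pkd=pkd, druggable=pkd > threshold, components=terms, threshold=threshold
    )


def classify_pockets(
    pockets: Sequence[Pocket],
    interface: InterfaceSet,
    annotated: Sequence[ResidueSpan] | None = None,
    overlap_threshold: float = 0.3,
) -> list[tuple[Pocket, PocketClass]]:
    """Label pockets by location: PPI interface, annotated site, or other.

    interface_overlap is the fraction of a pocket's lining residues that are
    interface residues; a pocket at or above ``overlap_threshold`` is labeled
    ``ppi_interface``. Otherwise, if the lining overlaps any annotated span
    (e.g. a known ATP site) at the same threshold it is ``annotated_site``.
    """
    iface = interface.all_residues
    out = []
    for p in pockets:
        lining = p.lining_residues
        overlap = len(lining & iface) / len(lining) if lining else 0.0
        if overlap >= overlap_threshold:
            label = "ppi_interface"
        else:
            label = "other"
            if annotated:
                for span in annotated:
                    frac = sum(1 for r in lining if r in span) / len(lining) if lining else 0.0
                    if frac >= overlap_threshold:
                        label = "annotated_site"
                        break
        out.append((p, PocketClass(label=label, interface_overlap=overlap)))
    return out


def pockets_to_tsv(
    pockets: Sequence[Pocket],
    classes: Sequence[PocketClass] | None = None,
    threshold: float = DEFAULT_PKD_THRESHOLD,
) -> str:
    lines = ["# id\tvolume_A3\tpredicted_pkd\tdruggable\tlabel\tlining_residues"]
    for i, p in enumerate(pockets):
        ds = score_druggability(p, threshold=threshold)
        label = classes[i].label if classes else "-"
        lining = ",".join(f"{c}{r}" for c, r in sorted(p.lining_residues))
        lines.append(
            f"P{i + 1}\t{p.volume:.1f}\t{ds.predicted_pkd:.2f}\t{ds.druggable}\t{label}\t{lining}"
        )
    return "\n".join(lines) + "\n"
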