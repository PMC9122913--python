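"""Tiered virtual-screening funnel with an open geometric scoring core.

The funnel docks a library against one or more candidate sites at three
precision tiers run in series (htvs < sp < xp, differing only in the number
of rigid-body placements sampled). The first tier docks *every* admitted
molecule — full coverage, no pre-docking triage — and each later tier
re-docks only the survivors of the previous one, keeping the top-scoring
fraction (of the previous stage) or an absolute count at each step.

Scoring is a transparent four-term empirical function over heavy-atom pair
geometry (steric clash, close contacts, hydrogen bonds, hydrophobic
contacts), combined as a weighted sum with *lower = better*. It is an open
stand-in for commercial docking scorers: the funnel architecture, coverage
and determinism contracts are the point, not affinity accuracy.

With a fixed seed the placement samples of coarser tiers are a prefix of the
finer tiers', so the best score can only improve (or stay equal) as
precision increases.

The all-around mode searches the entire protein surface with no prior
knowledge of pockets: candidate sites are all detected pockets plus a
uniform scan of surface patches, and the overall best pose wins.
"""

from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .libfilter import Molecule, screen_library
from .pocketfinder import VDW_RADII, detect_pockets
from .structio import Structure
from .synthkit import _fibonacci_sphere

__all__ = [
    "Site",
    "Pose",
    "ScoreBreakdown",
    "FunnelConfig",
    "FunnelReport",
    "score_pose",
    "dock_site",
    "dock_all_around",
    "run_funnel",
    "ligand_conformer",
]

#: score weights (w_clash, w_contact, w_hbond, w_hydrophobic); reward terms
#: carry negative weights so the total is lower-is-better. The clash weight
#: is deliberately steep: a pose with substantial steric overlap must never
#: outscore a clash-free one, whatever its contact count.
DEFAULT_WEIGHTS = (10.0, -0.05, -1.0, -0.1)

PRECISION_SAMPLES = {"htvs": 200, "sp": 2000, "xp": 20000}

CLASH_FACTOR = 0.7
CONTACT_RANGE = (3.0, 4.5)
HBOND_RANGE = (2.5, 3.5)
HBOND_MIN_ANGLE = 120.0  # degrees, at the ligand atom vs its bonded neighbors
HYDROPHOBIC_RANGE = (3.5, 5.0)

_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Site:
    centroid: tuple[float, float, float]
    radius: float
    source: str = "user"  # pocket_<i> | user | surface_scan_<i>

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("site radius must be positive")


@dataclass
class ScoreBreakdown:
    steric_clash: float
    contact: float
    hbond: float
    hydrophobic: float
    weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS

    @property
    def total(self) -> float:
        w = self.weights
        return (
            w[0] * self.steric_clash
            + w[1] * self.contact
            + w[2] * self.hbond
            + w[3] * self.hydrophobic
        )


@dataclass
class Pose:
    ligand_coords: np.ndarray  # (n_heavy, 3)
    site: Site
    score: float
    breakdown: ScoreBreakdown
    hbond_partners: list[tuple[str, int, str]] = field(default_factory=list)
    molecule_id: str = ""
    sample_index: int = -1

    _partner_resnames: list[str] = field(default_factory=list, repr=False)

    def hbond_summary(self) -> str:
        """Residue-level report of H-bonded receptor partners, e.g. 'T47, R50, R150'."""
        tags: list[str] = []
        pairs = sorted(
            {
                (chain, resnum, resname)
                for (chain, resnum, _atom), resname in zip(
                    self.hbond_partners, self._partner_resnames
                )
            }
        )
        for _chain, resnum, resname in pairs:
            tag = f"{_AA1.get(resname, 'X')}{resnum}"
            if tag not in tags:
                tags.append(tag)
        return ", ".join(tags)


# ---------------------------------------------------------------------------
# ligand preparation


@dataclass
class _Ligand:
    coords: np.ndarray  # heavy-atom conformer, centered at origin
    elements: list[str]
    is_polar: np.ndarray  # N/O
    is_donor: np.ndarray  # N/O bearing >= 1 H
    is_carbon: np.ndarray
    neighbors: list[list[int]]  # bonded heavy neighbors
    radii: np.ndarray


def ligand_conformer(m: Molecule, seed: int = 0) -> _Ligand:
    """Single seeded 3D conformer (heavy atoms, centered at the origin)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(m.mol)
    ok = AllChem.EmbedMolecule(mol, randomSeed=int(seed) % (2**31 - 1), useRandomCoords=False)
    if ok != 0:
        ok = AllChem.EmbedMolecule(mol, randomSeed=int(seed) % (2**31 - 1), useRandomCoords=True)
    if ok != 0:
        raise ValueError(f"{m.id}: 3D embedding failed")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    except Exception:
        pass
    conf = mol.GetConformer()
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    idx = {a.GetIdx(): i for i, a in enumerate(heavy)}
    coords = np.array([list(conf.GetAtomPosition(a.GetIdx())) for a in heavy])
    coords -= coords.mean(axis=0)
    elements = [a.GetSymbol() for a in heavy]
    is_polar = np.array([e in ("N", "O") for e in elements])
    is_donor = np.array(
        [e in ("N", "O") and a.GetTotalNumHs() > 0 for e, a in zip(elements, heavy)]
    )
    is_carbon = np.array([e == "C" for e in elements])
    neighbors = [
        [idx[n.GetIdx()] for n in a.GetNeighbors() if n.GetAtomicNum() > 1] for a in heavy
    ]
    radii = np.array([VDW_RADII.get(e, 1.7) for e in elements])
    return _Ligand(coords, elements, is_polar, is_donor, is_carbon, neighbors, radii)


# ---------------------------------------------------------------------------
# scoring


class _ReceptorView:
    """Pre-indexed receptor heavy atoms for repeated pose scoring."""

    def __init__(self, receptor: Structure):
        self.atoms = receptor.heavy_atoms()
        self.coords = np.array([a.xyz for a in self.atoms])
        self.elements = np.array([a.element.upper() for a in self.atoms])
        self.radii = np.array([VDW_RADII.get(e, 1.7) for e in self.elements])
        self.is_polar = np.isin(self.elements, ("N", "O"))
        self.is_carbon = self.elements == "C"
        self.tree = cKDTree(self.coords)

    def near(self, center: np.ndarray, radius: float) -> np.ndarray:
        return np.array(self.tree.query_ball_point(center, radius), dtype=int)


def _score_coords(
    lig: _Ligand,
    lig_coords: np.ndarray,
    rec: _ReceptorView,
    rec_idx: np.ndarray,
    weights=DEFAULT_WEIGHTS,
) -> ScoreBreakdown:
    if rec_idx.size == 0:
        return ScoreBreakdown(0.0, 0.0, 0.0, 0.0, tuple(weights))
    rc = rec.coords[rec_idx]
    d = np.linalg.norm(lig_coords[:, None, :] - rc[None, :, :], axis=2)

    clash_thresh = CLASH_FACTOR * (lig.radii[:, None] + rec.radii[rec_idx][None, :])
    clash_mask = d < clash_thresh
    clash = float(np.sum((clash_thresh - d)[clash_mask]))

    contact = float(np.sum((d >= CONTACT_RANGE[0]) & (d <= CONTACT_RANGE[1])))

    polar_pair = lig.is_polar[:, None] & rec.is_polar[rec_idx][None, :]
    hb_geom = polar_pair & (d >= HBOND_RANGE[0]) & (d <= HBOND_RANGE[1])
    hbond = 0
    if hb_geom.any():
        cos_max = math.cos(math.radians(HBOND_MIN_ANGLE))
        for li, ri in zip(*np.nonzero(hb_geom)):
            # donor-acceptor directionality: the ligand atom must be a donor
            # or an acceptor, and the receptor atom must not be eclipsed by
            # the ligand atom's own bonded neighbors
            if not (lig.is_donor[li] or lig.is_polar[li]):
                continue
            ok = True
            v = rc[ri] - lig_coords[li]
            v = v / np.linalg.norm(v)
            for ni in lig.neighbors[li]:
                u = lig_coords[ni] - lig_coords[li]
                u = u / np.linalg.norm(u)
                # angle(neighbor, ligand atom, receptor atom) >= 120 deg
                if float(np.dot(u, v)) > cos_max:
                    ok = False
                    break
            if ok:
                hbond += 1

    cc = lig.is_carbon[:, None] & rec.is_carbon[rec_idx][None, :]
    hydrophobic = float(np.sum(cc & (d >= HYDROPHOBIC_RANGE[0]) & (d <= HYDROPHOBIC_RANGE[1])))

    return ScoreBreakdown(clash, contact, float(hbond), hydrophobic, tuple(weights))


def _hbond_partners(
    lig: _Ligand, lig_coords: np.ndarray, rec: _ReceptorView, rec_idx: np.ndarray
) -> tuple[list, list]:
    partners, resnames = [], []
    if rec_idx.size == 0:
        return partners, resnames
    rc = rec.coords[rec_idx]
    d = np.linalg.norm(lig_coords[:, None, :] - rc[None, :, :], axis=2)
    polar_pair = lig.is_polar[:, None] & rec.is_polar[rec_idx][None, :]
    hb = polar_pair & (d >= HBOND_RANGE[0]) & (d <= HBOND_RANGE[1])
    cos_max = math.cos(math.radians(HBOND_MIN_ANGLE))
    for li, ri in zip(*np.nonzero(hb)):
        v = rc[ri] - lig_coords[li]
        v = v / np.linalg.norm(v)
        ok = True
        for ni in lig.neighbors[li]:
            u = lig_coords[ni] - lig_coords[li]
            u = u / np.linalg.norm(u)
            if float(np.dot(u, v)) > cos_max:
                ok = False
                break
        if ok:
            a = rec.atoms[rec_idx[ri]]
            partners.append((a.chain, a.resnum, a.name))
            resnames.append(a.resname)
    return partners, resnames


def _score_batch(
    lig: _Ligand,
    coords_b: np.ndarray,  # (B, n, 3)
    rec: _ReceptorView,
    rec_idx: np.ndarray,
    weights=DEFAULT_WEIGHTS,
) -> tuple[np.ndarray, ...]:
    """Vectorized scoring of a batch of poses; returns per-pose term arrays."""
    B = coords_b.shape[0]
    if rec_idx.size == 0:
        z = np.zeros(B)
        return z, z, z, z, z
    rc = rec.coords[rec_idx]
    d = np.linalg.norm(coords_b[:, :, None, :] - rc[None, None, :, :], axis=3)

    thresh = CLASH_FACTOR * (lig.radii[:, None] + rec.radii[rec_idx][None, :])
    clash = np.maximum(0.0, thresh[None] - d).sum(axis=(1, 2))
    contact = ((d >= CONTACT_RANGE[0]) & (d <= CONTACT_RANGE[1])).sum(axis=(1, 2)).astype(float)
    cc = lig.is_carbon[:, None] & rec.is_carbon[rec_idx][None, :]
    hydrophobic = (
        (cc[None] & (d >= HYDROPHOBIC_RANGE[0]) & (d <= HYDROPHOBIC_RANGE[1]))
        .sum(axis=(1, 2))
        .astype(float)
    )

    hbond = np.zeros(B)
    li_idx = np.nonzero(lig.is_polar)[0]
    ri_idx = np.nonzero(rec.is_polar[rec_idx])[0]
    if li_idx.size and ri_idx.size:
        cos_max = math.cos(math.radians(HBOND_MIN_ANGLE))
        dp = d[:, li_idx][:, :, ri_idx]
        ok = (dp >= HBOND_RANGE[0]) & (dp <= HBOND_RANGE[1])
        for a_pos, li in enumerate(li_idx):
            if not ok[:, a_pos, :].any():
                continue
            v = rc[ri_idx][None, :, :] - coords_b[:, li, None, :]  # (B, mp, 3)
            v = v / np.linalg.norm(v, axis=2, keepdims=True)
            for ni in lig.neighbors[li]:
                u = coords_b[:, ni, :] - coords_b[:, li, :]  # (B, 3)
                u = u / np.linalg.norm(u, axis=1, keepdims=True)
                cos = np.einsum("bk,bmk->bm", u, v)
                ok[:, a_pos, :] &= cos <= cos_max
        hbond = ok.sum(axis=(1, 2)).astype(float)

    w = weights
    total = w[0] * clash + w[1] * contact + w[2] * hbond + w[3] * hydrophobic
    return clash, contact, hbond, hydrophobic, total


def score_pose(receptor: Structure, pose: Pose, weights=DEFAULT_WEIGHTS) -> ScoreBreakdown:
    """Score an existing pose against the receptor (same coordinate frame).

    The ligand is treated as all-carbon unless the pose carries element
    metadata; for poses produced by :func:`dock_site` the stored breakdown is
    authoritative and this recomputes it from geometry.
    """
    if pose.ligand_coords is None or len(pose.ligand_coords) == 0:
        raise ValueError("pose has no ligand atoms")
    lig = getattr(pose, "_ligand", None)
    if lig is None:
        n = len(pose.ligand_coords)
        lig = _Ligand(
            coords=pose.ligand_coords,
            elements=["C"] * n,
            is_polar=np.zeros(n, bool),
            is_donor=np.zeros(n, bool),
            is_carbon=np.ones(n, bool),
            neighbors=[[] for _ in range(n)],
            radii=np.full(n, 1.7),
        )
    rec = _ReceptorView(receptor)
    rec_idx = np.arange(len(rec.atoms))
    return _score_coords(lig, pose.ligand_coords, rec, rec_idx, weights)


# ---------------------------------------------------------------------------
# docking


def _mol_rng(seed: int, mol_id: str) -> np.random.Generator:
    # site-independent stream: every site sees the same relative candidate
    # set, so symmetry-equivalent sites score identically and tie-break by
    # site index
    h = zlib.crc32(mol_id.encode())
    return np.random.default_rng([int(seed) % (2**31), h])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _cube_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the cube (deterministic orientation set)."""
    mats = []
    for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    M = np.zeros((3, 3))
                    M[0, perm[0]] = sx
                    M[1, perm[1]] = sy
                    M[2, perm[2]] = sz
                    if np.linalg.det(M) > 0.5:
                        mats.append(M)
    return mats


def enumerate_candidates(site: Site, grid: float, lig_coords: np.ndarray):
    """Deterministic (rotation, translation) candidates on a coarse grid.

    Translations are lattice points of pitch ``grid`` inside the site sphere;
    orientations are the 24 proper cube rotations. Used for the enumerable
    search mode and as the shared candidate set for brute-force checks.
    """
    c = np.asarray(site.centroid)
    r = site.radius
    ax = np.arange(-r, r + 1e-9, grid)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) <= r]
    out = []
    for R in _cube_rotations():
        for t in pts:
            out.append((R, c + t))
    return out


def dock_site(
    receptor: Structure,
    m: Molecule,
    site: Site,
    precision: str = "sp",
    seed: int = 0,
    weights=DEFAULT_WEIGHTS,
    samples: int | None = None,
    search: str = "random",
    grid: float = 2.0,
    _rec: _ReceptorView | None = None,
    _lig: _Ligand | None = None,
) -> Pose:
    """Best-scoring rigid placement of ``m`` inside the site sphere.

    ``search="random"`` draws seeded random translations/orientations
    (sample count set by precision tier; coarser tiers are a prefix of finer
    ones, so refining the precision can only improve the best score).
    ``search="grid"`` enumerates a deterministic coarse candidate set instead.
    """
    if precision not in PRECISION_SAMPLES:
        raise ValueError(f"unknown precision {precision!r}")
    n_samples = samples if samples is not None else PRECISION_SAMPLES[precision]
    rec = _rec if _rec is not None else _ReceptorView(receptor)
    lig = _lig if _lig is not None else ligand_conformer(m, seed=seed)

    center = np.asarray(site.centroid, dtype=float)
    lig_extent = float(np.linalg.norm(lig.coords, axis=1).max(initial=0.0))
    rec_idx = rec.near(center, site.radius + lig_extent + HYDROPHOBIC_RANGE[1] + 0.5)

    if search == "grid":
        candidates = enumerate_candidates(site, grid, lig.coords)
    else:
        rng = _mol_rng(seed, m.id)
        candidates = []
        for _ in range(n_samples):
            R = _random_rotation(rng)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            t = center + u * site.radius * rng.random() ** (1 / 3)
            candidates.append((R, t))

    best = None  # (total, index, coords, breakdown terms)
    chunk = 64
    for start in range(0, len(candidates), chunk):
        block = candidates[start : start + chunk]
        coords_b = np.stack([lig.coords @ R.T + t for R, t in block])
        clash, contact, hbond, hydrophobic, total = _score_batch(
            lig, coords_b, rec, rec_idx, weights
        )
        j = int(np.argmin(total))
        if best is None or total[j] < best[0] - 1e-12:
            bd = ScoreBreakdown(
                float(clash[j]), float(contact[j]), float(hbond[j]), float(hydrophobic[j]),
                tuple(weights),
            )
            best = (float(total[j]), start + j, coords_b[j], bd)
    total, i, coords, bd = best
    total = bd.total  # exact re-summation so score == weighted breakdown
    partners, resnames = _hbond_partners(lig, coords, rec, rec_idx)
    pose = Pose(
        ligand_coords=coords,
        site=site,
        score=total,
        breakdown=bd,
        hbond_partners=partners,
        molecule_id=m.id,
        sample_index=i,
    )
    pose._partner_resnames = resnames
    pose._ligand = lig
    return pose


def surface_sites(receptor: Structure, n_patches: int = 32, radius: float = 5.0) -> list[Site]:
    """Uniform surface-patch scan: sites just outside the protein along
    evenly distributed directions from the center of geometry."""
    heavy = receptor.heavy_atoms()
    if not heavy:
        raise ValueError("receptor has no surface points")
    coords = np.array([a.xyz for a in heavy])
    cog = coords.mean(axis=0)
    rel = coords - cog
    sites = []
    for k, u in enumerate(_fibonacci_sphere(n_patches)):
        proj = rel @ u
        extent = proj.max()
        centroid = cog + u * (extent + 1.0)
        sites.append(Site(tuple(np.round(centroid, 3)), radius, source=f"surface_scan_{k}"))
    return sites


def dock_all_around(
    receptor: Structure,
    m: Molecule,
    precision: str = "sp",
    seed: int = 0,
    weights=DEFAULT_WEIGHTS,
    site_radius: float = 5.0,
    n_patches: int = 32,
    pocket_kwargs: dict | None = None,
    samples: int | None = None,
) -> Pose:
    """Blind whole-surface docking: best pose over every detected pocket plus
    a uniform surface-patch scan, with no prior site knowledge.

    Ties between sites (within 1e-6) break to the lower site index.
    """
    pockets = detect_pockets(receptor, **(pocket_kwargs or {}))
    sites = [
        Site(tuple(np.round(p.centroid, 3)), site_radius, source=f"pocket_{i}")
        for i, p in enumerate(pockets)
    ]
    sites += surface_sites(receptor, n_patches=n_patches, radius=site_radius)
    rec = _ReceptorView(receptor)
    lig = ligand_conformer(m, seed=seed)
    best: Pose | None = None
    for site in sites:
        pose = dock_site(
            receptor, m, site, precision, seed, weights, samples=samples, _rec=rec, _lig=lig
        )
        if best is None or pose.score < best.score - 1e-6:
            best = pose
    return best


# ---------------------------------------------------------------------------
# the funnel


@dataclass
class FunnelConfig:
    stages: list[tuple[str, float, int]] = field(
        default_factory=lambda: [
            ("htvs", 0.1, PRECISION_SAMPLES["htvs"]),
            ("sp", 0.1, PRECISION_SAMPLES["sp"]),
            ("xp", 10, PRECISION_SAMPLES["xp"]),
        ]
    )
    seed: int = 0
    filters_first: bool = True
    weights: tuple = DEFAULT_WEIGHTS

    def __post_init__(self):
        if not self.stages:
            raise ValueError("need at least one stage")
        samples = [s[2] for s in self.stages]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("stage sample counts must strictly increase")
        for _, keep, _ in self.stages:
            if keep <= 0:
                raise ValueError("keep must be positive")


@dataclass
class FunnelReport:
    stages: list[dict]  # [{precision, survivors: [(id, score)], coverage}]
    hits: list[tuple[str, float]]  # final ranked (id, score)
    provenance: dict  # per-molecule: filter verdicts, best site, notes
    config_seed: int
    admitted: list[str]
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.config_seed,
                "admitted": self.admitted,
                "stages": self.stages,
                "hits": self.hits,
                "provenance": self.provenance,
                "notes": self.notes,
            },
            indent=2,
            sort_keys=True,
        )

    def sha256(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _n_keep(keep: float, pool: int) -> int:
    if keep < 1:
        return max(1, int(math.floor(keep * pool)))
    return min(int(keep), pool)


def run_funnel(
    receptor: Structure,
    lib: list[Molecule],
    sites: Sequence[Site],
    config: FunnelConfig | None = None,
) -> FunnelReport:
    """Run the tiered screen: admission filters, then serial docking stages.

    Stage 1 docks 100% of the admitted library; later stages re-dock the
    previous stage's survivors at higher precision. Fractional ``keep``
    retains that fraction of the previous stage's survivors; integer keeps
    are absolute counts. A keep larger than the pool keeps everything (with
    a warning note).
    """
    config = config or FunnelConfig()
    notes: list[str] = []
    provenance: dict = {}

    if config.filters_first:
        verdicts = screen_library(lib)
        admitted_ids = {mid for mid, vs in verdicts.items() if all(v.passed for v in vs.values())}
        for m in lib:
            provenance[m.id] = {
                "filters": {
                    rule: {"passed": v.passed, "violations": v.violations}
                    for rule, v in verdicts[m.id].items()
                },
                "admitted": m.id in admitted_ids,
            }
        pool = [m for m in lib if m.id in admitted_ids]
    else:
        pool = list(lib)
        for m in lib:
            provenance[m.id] = {"filters": None, "admitted": True}
    admitted_list = sorted(m.id for m in pool)

    if not pool:
        notes.append("0 admitted molecules; empty funnel (zero coverage)")
        return FunnelReport([], [], provenance, config.seed, admitted_list, notes)

    rec = _ReceptorView(receptor)
    ligands: dict[str, _Ligand] = {}
    for m in pool:
        try:
            ligands[m.id] = ligand_conformer(m, seed=config.seed)
        except ValueError as exc:
            provenance[m.id]["skipped"] = str(exc)
            notes.append(f"skipped {m.id}: conformer generation failed")
    pool = [m for m in pool if m.id in ligands]

    survivors = sorted(pool, key=lambda m: m.id)
    stage_records = []
    for si, (precision, keep, samples) in enumerate(config.stages):
        scored = []
        for m in survivors:
            best_pose: Pose | None = None
            for site in sites:
                pose = dock_site(
                    receptor,
                    m,
                    site,
                    precision,
                    config.seed,
                    config.weights,
                    samples=samples,
                    _rec=rec,
                    _lig=ligands[m.id],
                )
                if best_pose is None or pose.score < best_pose.score - 1e-12:
                    best_pose = pose
            scored.append((m, best_pose))
            prov = provenance[m.id].setdefault("stages", {})
            prov[precision] = {"score": best_pose.score, "site": best_pose.site.source}
        scored.sort(key=lambda t: (t[1].score, t[0].id))
        nk = _n_keep(keep, len(scored))
        if keep >= 1 and int(keep) > len(scored):
            notes.append(
                f"stage {si + 1} ({precision}): keep {int(keep)} exceeds pool "
                f"{len(scored)}; keeping all"
            )
        kept = scored[:nk]
        stage_records.append(
            {
                "precision": precision,
                "n_scored": len(scored),
                "coverage": len(scored) / len(pool) if si == 0 else None,
                "survivors": [(m.id, p.score) for m, p in kept],
            }
        )
        if si == 0:
            assert len(scored) == len(pool), "full coverage violated"
        survivors = [m for m, _ in kept]
        last_scored = kept

    hits = [(m.id, p.score) for m, p in last_scored]
    for mid, _score in hits:
        provenance[mid]["hit"] = True
    for m, p in last_scored:
        provenance[m.id]["best_site"] = p.site.source
        provenance[m.id]["hbond_partners"] = p.hbond_summary()
    return FunnelReport(stage_records, hits, provenance, config.seed, admitted_list, notes)
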