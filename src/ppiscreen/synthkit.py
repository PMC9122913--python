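"""Deterministic synthetic fixtures with recorded ground truth.

Every generator here is a pure function of its parameters and a seed, and
returns a :class:`FixtureTruth` sidecar recording what was planted (cavity
centres and radii, per-molecule filter labels, the planted binder, cluster
assignments, the true half-life). Regenerating with the same seed reproduces
the fixture bit-identically, so tests can compare detector output against
construction truth rather than against frozen files.

The pseudo-protein receptors are cubic lattices of carbon dummy atoms (one
residue per atom) with spherical voids carved out; a dense shell of atoms is
placed on each cavity wall so the void the pocket detector sees has the
nominal radius. This is a deliberate abstraction from real folds: it gives
analytically known cavity volumes and controllable lining chemistry, at the
price of realism (no backbone, no sidechain geometry, no charge).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import Atom, Structure

__all__ = [
    "FixtureTruth",
    "CARBON_VDW",
    "make_cavity_receptor",
    "make_dimer_receptor",
    "make_random_dimer",
    "make_filter_library",
    "make_binder_library",
    "make_pose_ensemble",
    "make_decay_series",
]

#: van der Waals radius used for the carbon dummy atoms, Angstroms.  The
#: cavity generator carves atoms out to (radius + CARBON_VDW) so that the
#: solvent-visible void has the nominal radius.
CARBON_VDW = 1.7


@dataclass
class FixtureTruth:
    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "params": self.params,
                "labels": self.labels,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        d = json.loads(text)
        return cls(d["generator"], d["seed"], d["params"], d["labels"])


# ---------------------------------------------------------------------------
# receptors


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic golden-angle set)."""
    i = np.arange(n, dtype=float)
    phi = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    theta = 2 * np.pi * i / phi
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _lattice_points(lo: np.ndarray, hi: np.ndarray, a: float) -> np.ndarray:
    axes = [np.arange(lo[k], hi[k] + 1e-9, a) for k in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([x.ravel() for x in g], axis=1)


def _build_block(
    lo,
    hi,
    cavity_centers: np.ndarray,
    cavity_radii: Sequence[float],
    lattice: float,
    chain: str,
    resname: str,
    start_resnum: int = 1,
    shell_spacing: float = 0.5,
) -> list[Atom]:
    """Lattice block with spherical voids; dense shell atoms smooth each wall."""
    pts = _lattice_points(np.asarray(lo, float), np.asarray(hi, float), lattice)
    carve = np.zeros(len(pts), dtype=bool)
    for c, r in zip(cavity_centers, cavity_radii):
        d = np.linalg.norm(pts - c, axis=1)
        carve |= d < (r + CARBON_VDW)
    kept = pts[~carve]

    shell_pts: list[np.ndarray] = []
    for c, r in zip(cavity_centers, cavity_radii):
        # discrete shell atoms leave the solvent boundary slightly outside the
        # nominal radius (nearest-atom distance exceeds the radial distance by
        # an in-plane offset term); shrink the shell by the empirically
        # measured offset so the void's effective radius equals r
        rs = r + CARBON_VDW - 0.049 * shell_spacing**1.4
        n = max(16, int(np.ceil(4 * np.pi * rs**2 / shell_spacing**2)))
        sp = c + rs * _fibonacci_sphere(n)
        # only shell points inside the block volume (cavity may touch a face)
        inside = np.all((sp >= np.asarray(lo) - lattice) & (sp <= np.asarray(hi) + lattice), axis=1)
        shell_pts.append(sp[inside])
    allpts = np.vstack([kept] + shell_pts) if shell_pts else kept

    atoms = []
    for i, p in enumerate(allpts):
        atoms.append(
            Atom(
                serial=start_resnum + i,
                element="C",
                name="CA",
                chain=chain,
                resnum=start_resnum + i,
                icode="",
                resname=resname,
                xyz=(round(float(p[0]), 3), round(float(p[1]), 3), round(float(p[2]), 3)),
            )
        )
    return atoms


def make_cavity_receptor(
    radii: Sequence[float],
    spacing: float = 1.2,
    seed: int = 0,
    lining: str = "hydrophobic",
    separation: float = 12.0,
    wall: float = 3.6,
) -> tuple[Structure, FixtureTruth]:
    """Pseudo-protein block with spherical cavities of the given radii.

    ``spacing`` is the dummy-atom lattice constant; ``lining`` ("hydrophobic"
    -> ALA, "polar" -> SER) sets the residue identity of every dummy atom so
    the lining hydrophobic fraction is 1.0 or 0.0 by construction. Cavity
    centres are placed on the x axis, ``separation`` apart edge-to-edge.
    """
    for r in radii:
        if not (2.0 <= r <= 8.0):
            raise ValueError(f"cavity radius {r} outside [2, 8] A")
    resname = {"hydrophobic": "ALA", "polar": "SER"}[lining]

    centers = []
    x = 0.0
    for i, r in enumerate(radii):
        if i > 0:
            x += radii[i - 1] + r + 2 * CARBON_VDW + separation
        centers.append([x, 0.0, 0.0])
    centers = np.array(centers) if centers else np.zeros((0, 3))
    for i in range(len(radii)):
        for j in range(i + 1, len(radii)):
            d = np.linalg.norm(centers[i] - centers[j])
            if d < (radii[i] + radii[j] + 2 * CARBON_VDW):
                raise ValueError("cavities overlap")

    if len(radii):
        rmax = max(r + CARBON_VDW for r in radii)
        lo = np.array([centers[:, 0].min() - rmax - wall, -rmax - wall, -rmax - wall])
        hi = np.array([centers[:, 0].max() + rmax + wall, rmax + wall, rmax + wall])
    else:
        lo = np.array([-6.0, -6.0, -6.0])
        hi = np.array([6.0, 6.0, 6.0])

    atoms = _build_block(lo, hi, centers, list(radii), spacing, "A", resname)
    truth = FixtureTruth(
        generator="make_cavity_receptor",
        seed=seed,
        params={
            "radii": list(map(float, radii)),
            "spacing": spacing,
            "lining": lining,
            "separation": separation,
        },
        labels={
            "cavity_centers": centers.tolist(),
            "cavity_radii": list(map(float, radii)),
        },
    )
    return Structure(models=[atoms], name="cavity_receptor"), truth


def make_dimer_receptor(
    cavity_at: str | None = "seam",
    radius: float = 4.0,
    spacing: float = 1.2,
    seed: int = 0,
    wall: float = 3.6,
) -> tuple[Structure, FixtureTruth]:
    """Two touching lattice blocks (chains A, B) with an optional cavity.

    ``cavity_at="seam"`` carves the cavity straddling the chain-chain contact
    plane (x = 0); ``"distal"`` buries it inside chain A far enough from the
    seam that no lining atom is within contact range of chain B; ``None``
    gives a solid dimer.
    """
    rmax = radius + CARBON_VDW
    yz = rmax + wall  # half-extent perpendicular to the seam normal
    if cavity_at == "seam":
        centers = np.array([[0.0, 0.0, 0.0]])
        depth = rmax + wall
    elif cavity_at == "distal":
        # cavity edge at least 6 A from the seam plane keeps its lining
        # outside any conventional interface cutoff
        cx = -(rmax + 6.0)
        centers = np.array([[cx, 0.0, 0.0]])
        depth = -cx + rmax + wall
    elif cavity_at is None:
        centers = np.zeros((0, 3))
        depth = rmax + wall
    else:
        raise ValueError("cavity_at must be 'seam', 'distal' or None")
    radii = [radius] * len(centers)
    half_gap = spacing / 2
    atomsA = _build_block(
        [-depth, -yz, -yz], [-half_gap, yz, yz],
        centers, radii, spacing, "A", "ALA", start_resnum=1,
    )
    atomsB = _build_block(
        [half_gap, -yz, -yz], [depth, yz, yz],
        centers, radii, spacing, "B", "ALA", start_resnum=1,
    )
    truth = FixtureTruth(
        generator="make_dimer_receptor",
        seed=seed,
        params={"cavity_at": cavity_at, "radius": radius, "spacing": spacing},
        labels={"cavity_centers": centers.tolist()},
    )
    return Structure(models=[atomsA + atomsB], name="dimer_receptor"), truth


def make_random_dimer(
    n_per_chain: int = 20, seed: int = 1, gap: float = 2.0, spread: float = 6.0
) -> tuple[Structure, FixtureTruth]:
    """Two random point clouds (one CA per residue) facing across a gap.

    Useful for brute-force contact-map oracles: some residue pairs land
    within typical contact cutoffs, others do not, with no structure imposed.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    for chain, sign in (("A", -1.0), ("B", 1.0)):
        xyz = rng.normal(0.0, spread, size=(n_per_chain, 3))
        xyz[:, 0] = sign * (gap / 2 + np.abs(xyz[:, 0]))
        for i in range(n_per_chain):
            atoms.append(
                Atom(
                    serial=len(atoms) + 1,
                    element="C",
                    name="CA",
                    chain=chain,
                    resnum=i + 1,
                    icode="",
                    resname="GLY",
                    xyz=tuple(round(float(v), 3) for v in xyz[i]),
                )
            )
    truth = FixtureTruth(
        "make_random_dimer", seed, {"n_per_chain": n_per_chain, "gap": gap, "spread": spread}, {}
    )
    return Structure(models=[atoms], name="random_dimer"), truth


# ---------------------------------------------------------------------------
# chemical libraries

# (name, SMILES, lipinski_pass, pains_pass, alarm_pass) — labels assigned by
# construction against the bundled PAINS/reactive pattern sets.
_CLEAN = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", True, True, True),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", True, True, True),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", True, True, True),
    ("acetaminophen", "CC(=O)Nc1ccc(O)cc1", True, True, True),
    ("nicotinamide", "NC(=O)c1cccnc1", True, True, True),
    ("pyridine", "c1ccncc1", True, True, True),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O", True, True, True),
    ("ethanol", "CCO", True, True, True),
]
_LIPINSKI_VIOLATORS = [
    # C40 alkane: MW 563, logP >> 5 (two violations)
    ("tetracontane", "C" * 40, False, True, True),
    # dodecahydroxy chain: 12 donors, 12 acceptors (two violations)
    ("polyol12", "OCC(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)CO", False, True, True),
    # C36 diacid-ish greasy chain, MW > 500 and logP > 5
    ("hexatriacontane", "C" * 36, False, True, True),
]
_PAINS_BEARING = [
    ("rhodanine", "O=C1CSC(=S)N1", True, False, True),
    ("catechol", "Oc1ccccc1O", True, False, True),
    ("methylcatechol", "Cc1ccc(O)c(O)c1", True, False, True),
    ("azobenzene", "c1ccc(cc1)/N=N/c1ccccc1", True, False, True),
    ("phenolic_hydrazone", "Oc1ccc(/C=N/N)cc1", True, False, True),
]
_REACTIVE = [
    ("acetyl_chloride", "CC(=O)Cl", True, True, False),
    ("benzyl_bromide", "BrCc1ccccc1", True, True, False),
    ("glycidol", "OCC1CO1", True, True, False),
    ("mvk", "CC(=O)C=C", True, True, False),
    ("tosyl_chloride", "Cc1ccc(cc1)S(=O)(=O)Cl", True, True, False),
    ("dtbp", "CC(C)(C)OOC(C)(C)C", True, True, False),
    # quinone is both a frequent hitter and a Michael acceptor/oxidizer
    ("benzoquinone", "O=C1C=CC(=O)C=C1", True, False, False),
]


def make_filter_library(
    n: int = 50,
    seed: int = 3,
    fractions: tuple[float, float, float, float] = (0.55, 0.15, 0.15, 0.15),
) -> tuple[list[tuple[str, str]], FixtureTruth]:
    """Labeled SMILES library mixing clean, Lipinski-violating, frequent-hitter
    and reactive structures in the given proportions.

    Returns ``([(id, smiles), ...], truth)`` where the truth labels record the
    expected pass/fail verdict of each molecule under each of the three
    admission filters.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    rng = np.random.default_rng(seed)
    pools = [_CLEAN, _LIPINSKI_VIOLATORS, _PAINS_BEARING, _REACTIVE]
    probs = np.asarray(fractions, dtype=float)
    probs = probs / probs.sum()
    lib: list[tuple[str, str]] = []
    labels: dict[str, dict] = {}
    for i in range(n):
        pool = pools[int(rng.choice(4, p=probs))]
        name, smi, lip, pains, alarm = pool[int(rng.integers(len(pool)))]
        mid = f"M{i + 1:04d}_{name}"
        lib.append((mid, smi))
        labels[mid] = {"lipinski": lip, "pains": pains, "alarm": alarm, "template": name}
    truth = FixtureTruth(
        "make_filter_library", seed, {"n": n, "fractions": list(fractions)}, {"verdicts": labels}
    )
    return lib, truth


def make_binder_library(n_decoys: int = 19, seed: int = 11) -> tuple[list[tuple[str, str]], FixtureTruth]:
    """Planted-binder screening library for a 4-Angstrom hydrophobic cavity.

    The binder is adamantane: a rigid, compact ten-carbon cage that fits the
    cavity snugly and collects far more favourable contacts than any decoy.
    Decoys are either tiny (1-4 heavy atoms, too few contacts) or oversized
    rigid/greasy structures that cannot fit the cavity without steric clash.
    """
    binder = ("BINDER_adamantane", "C1C2CC3CC1CC(C2)C3")
    tiny = [("methane", "C"), ("ethane", "CC"), ("propane", "CCC"), ("isobutane", "CC(C)C")]
    # oversized decoys: every conformer is far larger than the cavity, so any
    # placement inside the site carries prohibitive steric overlap
    huge = [
        ("icosane", "C" * 20),
        ("tetracosane", "C" * 24),
        ("terphenyl", "c1ccc(cc1)-c1ccc(cc1)-c1ccccc1"),
        ("hexadecane", "C" * 16),
    ]
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n_decoys):
        pool = tiny if rng.random() < 0.5 else huge
        name, smi = pool[int(rng.integers(len(pool)))]
        decoys.append((f"D{i + 1:03d}_{name}", smi))
    lib = [binder] + decoys
    order = rng.permutation(len(lib))
    lib = [lib[int(k)] for k in order]
    truth = FixtureTruth(
        "make_binder_library", seed, {"n_decoys": n_decoys}, {"binder_id": binder[0]}
    )
    return lib, truth


# ---------------------------------------------------------------------------
# pose ensembles


def _partner_template() -> np.ndarray:
    # small rigid asymmetric 5-atom body
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [0.0, 1.5, 0.0],
            [0.0, 0.0, 1.5],
            [1.0, 1.0, 1.0],
        ]
    )


def make_pose_ensemble(
    sizes: Sequence[int],
    jitter: float = 1.0,
    separation: float = 20.0,
    seed: int = 5,
    best_cluster: int | None = None,
):
    """Clustered rigid-partner pose ensemble with planted truth.

    Cluster centres sit ``separation`` apart; members are translational
    jitters of the partner template with displacement norm <= ``jitter``.
    Scores are seeded uniforms (lower = better); the globally best score is
    forced into ``best_cluster`` (default: the largest cluster).

    Returns ``(receptor, partner_coords [n_poses, n_atoms, 3], scores, truth)``.
    """
    if not sizes:
        raise ValueError("need at least one cluster size")
    rng = np.random.default_rng(seed)
    base = _partner_template()
    receptor_atoms = _build_block([-4, -4, -4], [4, 4, 4], np.zeros((0, 3)), [], 1.6, "R", "GLY")
    receptor = Structure(models=[receptor_atoms], name="ensemble_receptor")

    coords, assign = [], []
    for ci, size in enumerate(sizes):
        center = np.array([12.0 + ci * separation, 0.0, 0.0])
        for _ in range(size):
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * (jitter * rng.random())
            coords.append(base + center + v)
            assign.append(ci)
    coords = np.array(coords)
    n = len(assign)
    scores = rng.uniform(-20.0, -5.0, size=n)
    target = int(np.argmax(np.bincount(assign))) if best_cluster is None else int(best_cluster)
    members = [i for i, c in enumerate(assign) if c == target]
    chosen = members[int(rng.integers(len(members)))]
    scores[chosen] = scores.min() - 1.0  # global best lives in the target cluster
    truth = FixtureTruth(
        "make_pose_ensemble",
        seed,
        {"sizes": list(map(int, sizes)), "jitter": jitter, "separation": separation},
        {
            "assignments": list(map(int, assign)),
            "global_best_index": int(np.argmin(scores)),
            "best_cluster": target,
        },
    )
    return receptor, coords, scores, truth


# ---------------------------------------------------------------------------
# decay series


def make_decay_series(
    halflife: float, sigma: float = 0.05, n: int = 7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy first-order decay time course, normalized to its t=0 value.

    y_i = exp(-ln2 * t_i / halflife) * eps_i with eps lognormal(0, sigma),
    then divided by y_0 — emulating chase data normalized to the zero-hour
    band, so y(0) = 1 exactly and the normalizer's noise propagates.
    Time points are evenly spaced on [0, 3 * halflife].
    """
    if halflife <= 0:
        raise ValueError("halflife must be positive")
    if n < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 3.0 * halflife, n)
    eps = np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)
    y = np.exp(-np.log(2.0) * t / halflife) * eps
    y = y / y[0]
    return t, y
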