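"""Macromolecular structure I/O and geometry primitives.

Reads PDB/mmCIF files (via gemmi) into a light atom-table representation,
writes fixed-column PDB (including multi-model pose ensembles), and computes
the two geometric quantities every downstream module needs: interface residue
sets between chain groups and least-squares rigid superpositions.

Conventions: coordinates are Angstroms throughout; residues are addressed by
author numbering (chain id, residue number, insertion code); contacts are
heavy-atom (non-hydrogen) distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "ResidueSpan",
    "InterfaceSet",
    "Superposition",
    "read_structure",
    "write_structure",
    "interface_residues",
    "superpose",
]

#: default heavy-atom distance defining an interface contact, in Angstroms
DEFAULT_CONTACT_CUTOFF = 5.0


@dataclass(frozen=True)
class Atom:
    serial: int
    element: str
    name: str
    chain: str
    resnum: int
    icode: str
    resname: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    het: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


@dataclass
class Structure:
    """An ordered list of models, each an ordered list of atoms."""

    models: list[list[Atom]] = field(default_factory=list)
    name: str = ""

    @property
    def atoms(self) -> list[Atom]:
        """Atoms of the first model (the common single-model case)."""
        return self.models[0] if self.models else []

    def coords(self, model: int = 0) -> np.ndarray:
        return np.array([a.xyz for a in self.models[model]], dtype=float)

    def chains(self, model: int = 0) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.models[model]:
            seen.setdefault(a.chain, None)
        return list(seen)

    def heavy_atoms(self, model: int = 0) -> list[Atom]:
        return [a for a in self.models[model] if a.element.upper() != "H"]

    def select_chains(self, chains: Iterable[str], model: int = 0) -> list[Atom]:
        want = set(chains)
        return [a for a in self.models[model] if a.chain in want]


@dataclass(frozen=True)
class ResidueSpan:
    """Inclusive author-numbered residue range on one chain."""

    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} > end {self.end}")

    def __contains__(self, key: tuple[str, int]) -> bool:
        chain, resnum = key
        return chain == self.chain and self.start <= resnum <= self.end


@dataclass
class InterfaceSet:
    residuesA: set[tuple[str, int]]
    residuesB: set[tuple[str, int]]
    contact_pairs: list[tuple[tuple[str, int], tuple[str, int], float]]
    cutoff: float

    @property
    def all_residues(self) -> set[tuple[str, int]]:
        return self.residuesA | self.residuesB

    def to_tsv(self) -> str:
        lines = ["# chain\tresnum\tpartner_chain\tpartner_resnum\tmin_distance_A"]
        best: dict[tuple, float] = {}
        for ra, rb, d in self.contact_pairs:
            k = (ra, rb)
            if k not in best or d < best[k]:
                best[k] = d
        for (ra, rb), d in sorted(best.items()):
            lines.append(f"{ra[0]}\t{ra[1]}\t{rb[0]}\t{rb[1]}\t{d:.3f}")
        return "\n".join(lines) + "\n"


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # length-3
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# reading / writing


def _from_gemmi(st) -> Structure:
    out = Structure(name=st.name)
    for model in st:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                for at in res:
                    el = at.element.name if at.element else "X"
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            element=el,
                            name=at.name,
                            chain=chain.name,
                            resnum=res.seqid.num,
                            icode=(res.seqid.icode or "").strip(),
                            resname=res.name,
                            xyz=(at.pos.x, at.pos.y, at.pos.z),
                            occupancy=at.occ,
                            het=res.het_flag == "H",
                        )
                    )
        out.models.append(atoms)
    return out


def _dedupe_altloc(atoms: list[Atom]) -> list[Atom]:
    # keep highest-occupancy conformer per (chain, resnum, icode, name); ties
    # resolve to first in file
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.resnum, a.icode, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        elif a.occupancy > best[key].occupancy:
            best[key] = a
    return [best[k] for k in order]


def read_structure(path: str, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``format`` may be ``"pdb"``, ``"mmcif"`` or ``None`` (detect from the
    file extension). All models are kept; HETATM records are retained with
    ``het=True``; alternate locations are collapsed to the highest-occupancy
    conformer.
    """
    import gemmi

    fmt = format
    if fmt is None:
        low = str(path).lower()
        fmt = "mmcif" if low.endswith((".cif", ".mmcif", ".cif.gz")) else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {fmt!r}; expected 'pdb' or 'mmcif'")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    out = _from_gemmi(st)
    out.models = [_dedupe_altloc(m) for m in out.models]
    if not out.models or not out.models[0]:
        raise ValueError(f"{path}: no atoms parsed")
    for m in out.models:
        for a in m:
            if not all(math.isfinite(c) for c in a.xyz):
                raise ValueError(f"non-finite coordinate at atom serial {a.serial}")
    return out


def _pdb_atom_line(a: Atom, serial: int) -> str:
    record = "HETATM" if a.het else "ATOM  "
    name = a.name
    # columns 13-16: element-aligned name layout
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    name = name.ljust(4)[:4]
    x, y, z = a.xyz
    return (
        f"{record}{serial:5d} {name} {a.resname:>3s} {a.chain[:1]}"
        f"{a.resnum:4d}{(a.icode or ' '):1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
        f"          {a.element.rjust(2)[:2]}"
    )


def write_structure(s: Structure, path: str) -> None:
    """Write a Structure as fixed-column PDB; multi-model when >1 model."""
    lines: list[str] = []
    multi = len(s.models) > 1
    for i, model in enumerate(s.models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for j, a in enumerate(model, start=1):
            lines.append(_pdb_atom_line(a, j))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# interface residues


def interface_residues(
    s: Structure,
    groupA: Iterable[str],
    groupB: Iterable[str],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    model: int = 0,
) -> InterfaceSet:
    """Residues of each chain group with a heavy atom within ``cutoff`` of the
    other group.

    Hydrogens are ignored. A residue enters ``residuesA`` iff at least one of
    its heavy atoms lies within ``cutoff`` Angstroms of any heavy atom of
    ``groupB`` (and symmetrically for B). Contact pairs carry the minimum
    heavy-atom distance for each residue pair in contact.
    """
    setA, setB = set(groupA), set(groupB)
    if not setA or not setB:
        raise ValueError("chain groups must be non-empty")
    if setA & setB:
        raise ValueError(f"chain groups overlap: {sorted(setA & setB)}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    avail = set(s.chains(model))
    missing = (setA | setB) - avail
    if missing:
        raise ValueError(
            f"chains {sorted(missing)} not in structure; available: {sorted(avail)}"
        )

    heavy = [a for a in s.models[model] if a.element.upper() != "H"]
    atomsA = [a for a in heavy if a.chain in setA]
    atomsB = [a for a in heavy if a.chain in setB]
    if not atomsA or not atomsB:
        return InterfaceSet(set(), set(), [], cutoff)

    xyzA = np.array([a.xyz for a in atomsA])
    xyzB = np.array([a.xyz for a in atomsB])
    pairs = cKDTree(xyzA).query_ball_tree(cKDTree(xyzB), r=cutoff)

    best: dict[tuple, float] = {}
    for ia, neighbors in enumerate(pairs):
        for ib in neighbors:
            ra = (atomsA[ia].chain, atomsA[ia].resnum)
            rb = (atomsB[ib].chain, atomsB[ib].resnum)
            d = float(np.linalg.norm(xyzA[ia] - xyzB[ib]))
            k = (ra, rb)
            if k not in best or d < best[k]:
                best[k] = d
    contact_pairs = [(ra, rb, d) for (ra, rb), d in sorted(best.items())]
    resA = {ra for ra, _, _ in contact_pairs}
    resB = {rb for _, rb, _ in contact_pairs}
    return InterfaceSet(resA, resB, contact_pairs, cutoff)


# ---------------------------------------------------------------------------
# superposition


def _as_coords(x) -> np.ndarray:
    if isinstance(x, Structure):
        return x.coords()
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1 and arr.size % 3 == 0:
        arr = arr.reshape(-1, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array or a Structure")
    return arr


def superpose(mobile, reference) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm: the returned rotation/translation minimise the RMSD
    between the transformed mobile coordinates and the reference over all
    proper rigid transforms. Inputs are matched atom lists (equal length,
    n >= 3, non-collinear).
    """
    P = _as_coords(mobile)
    Q = _as_coords(reference)
    if P.shape != Q.shape:
        raise ValueError(f"atom count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 matched atoms")

    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear/degenerate point sets leave the rotation underdetermined
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) atom selection")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)
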