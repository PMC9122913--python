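"""Chemical library ingestion and funnel admission filters.

Three filters gate entry to the screening funnel:

* **Lipinski's rule of five** — oral drug-likeness: MW <= 500, logP <= 5,
  H-bond donors <= 5, acceptors <= 10; the classic policy passes a molecule
  with at most one violation.
* **Frequent-hitter (PAINS) screen** — substructure match against a bundled,
  versioned set of pan-assay interference motifs; any match fails.
* **Reactive-chemistry screen** — protein-reactive electrophile/oxidizer
  substructures (alkylators, acylators, Michael acceptors, oxidizers). This
  is a structural stand-in for a reactivity assay: any match fails.

Property conventions follow Lipinski's original counting: donors are N/O
heteroatoms bearing at least one hydrogen (counted once per heteroatom),
acceptors are all N and O atoms; logP is the Crippen atom-contribution
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

__all__ = [
    "Molecule",
    "PropertySet",
    "FilterVerdict",
    "load_library",
    "load_smiles_file",
    "compute_properties",
    "lipinski_filter",
    "pains_screen",
    "alarm_screen",
    "screen_library",
    "verdicts_to_tsv",
]


@dataclass
class PropertySet:
    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable_bonds: int


@dataclass
class Molecule:
    id: str
    smiles: str  # canonical
    mol: object = field(repr=False, default=None)  # RDKit Mol
    properties: PropertySet | None = None
    _fingerprint: object = field(repr=False, default=None)

    @classmethod
    def from_smiles(cls, mid: str, smiles: str) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"{mid}: unparseable SMILES {smiles!r}")
        m = cls(id=mid, smiles=Chem.MolToSmiles(mol), mol=mol)
        m.properties = compute_properties(m)
        return m

    def fingerprint(self, radius: int = 2, n_bits: int = 2048):
        """Hashed circular (Morgan) fingerprint; cached per molecule."""
        if self._fingerprint is None:
            from rdkit.Chem import rdFingerprintGenerator

            gen = _morgan_generator(radius, n_bits)
            self._fingerprint = gen.GetFingerprint(self.mol)
        return self._fingerprint


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, n_bits: int):
    from rdkit.Chem import rdFingerprintGenerator

    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


@dataclass
class FilterVerdict:
    rule: str  # lipinski | pains | alarm
    passed: bool
    violations: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ingestion


def load_smiles_file(path: str) -> list[Molecule]:
    """Read a one-per-line ``SMILES[<whitespace>id]`` file."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            mid = parts[1] if len(parts) > 1 else f"mol{ln}"
            out.append(Molecule.from_smiles(mid, smi))
    return out


def load_library(path: str) -> list[Molecule]:
    """Load a library from .smi/.smiles or .sdf."""
    low = str(path).lower()
    if low.endswith(".sdf"):
        out = []
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                continue
            mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
            m = Molecule(id=mid, smiles=Chem.MolToSmiles(mol), mol=mol)
            m.properties = compute_properties(m)
            out.append(m)
        return out
    return load_smiles_file(path)


# ---------------------------------------------------------------------------
# properties


def compute_properties(m: Molecule) -> PropertySet:
    """Lipinski-convention property set for one molecule."""
    mol = m.mol
    return PropertySet(
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NOCount(mol)),  # plain N+O count, Lipinski's convention
        rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
    )


# ---------------------------------------------------------------------------
# filters

LIPINSKI_LIMITS = {"mw": 500.0, "logp": 5.0, "hbd": 5, "hba": 10}


def lipinski_filter(p: PropertySet, max_violations: int = 1) -> FilterVerdict:
    """Rule-of-five verdict; passes with at most ``max_violations`` breaches."""
    violations = [
        name
        for name, limit in LIPINSKI_LIMITS.items()
        if getattr(p, name) > limit
    ]
    return FilterVerdict("lipinski", passed=len(violations) <= max_violations, violations=violations)


def _load_patterns(filename: str, with_class: bool):
    pats = []
    text = resources.files("ppiscreen.data").joinpath(filename).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if with_class:
            name, cls, smarts = parts
        else:
            (name, smarts), cls = parts, None
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"{filename}: malformed SMARTS for pattern {name!r}")
        pats.append((name, cls, q))
    return pats


@lru_cache(maxsize=2)
def pains_patterns():
    return tuple(_load_patterns("pains_smarts.tsv", with_class=False))


@lru_cache(maxsize=2)
def reactive_patterns():
    return tuple(_load_patterns("reactive_smarts.tsv", with_class=True))


def pains_screen(m: Molecule, patterns=None) -> FilterVerdict:
    """Fail if any frequent-hitter motif matches; matched names are listed."""
    pats = patterns if patterns is not None else pains_patterns()
    hits = [name for name, _, q in pats if m.mol.HasSubstructMatch(q)]
    return FilterVerdict("pains", passed=not hits, violations=hits)


def alarm_screen(m: Molecule, patterns=None) -> FilterVerdict:
    """Fail if any protein-reactive pattern matches; reports name and class."""
    pats = patterns if patterns is not None else reactive_patterns()
    hits = [f"{name}[{cls}]" for name, cls, q in pats if m.mol.HasSubstructMatch(q)]
    return FilterVerdict("alarm", passed=not hits, violations=hits)


def screen_library(
    lib: list[Molecule], max_violations: int = 1
) -> dict[str, dict[str, FilterVerdict]]:
    """All three verdicts for every molecule, keyed by molecule id."""
    out: dict[str, dict[str, FilterVerdict]] = {}
    for m in lib:
        out[m.id] = {
            "lipinski": lipinski_filter(m.properties, max_violations=max_violations),
            "pains": pains_screen(m),
            "alarm": alarm_screen(m),
        }
    return out


def admitted(verdicts: dict[str, dict[str, FilterVerdict]]) -> set[str]:
    """Ids passing all three filters."""
    return {mid for mid, vs in verdicts.items() if all(v.passed for v in vs.values())}


def verdicts_to_tsv(verdicts: dict[str, dict[str, FilterVerdict]]) -> str:
    lines = ["# id\trule\tpassed\tviolations"]
    for mid in sorted(verdicts):
        for rule in ("lipinski", "pains", "alarm"):
            v = verdicts[mid][rule]
            lines.append(f"{mid}\t{rule}\t{v.passed}\t{','.join(v.violations) or '-'}")
    return "\n".join(lines) + "\n"
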