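"""Size-independent library diversity scoring and diverse subset selection.

The diversity score of a library is ``1 - mean pairwise Tanimoto similarity``
computed over all distinct unordered pairs of *unique* structures (duplicates
collapsed by canonical SMILES). Averaging over pairs of uniques makes the
score independent of library size and trivially invariant under duplication;
a library with a single unique structure scores 0 by definition.

This formulation is a reconstruction: the score it implements is a
conventional mean-dissimilarity diversity index chosen for its boundedness
and duplication invariance, not a published algorithm.

Subset selection is deterministic MaxMin: seed with the globally most
dissimilar pair, then greedily add the molecule maximizing its minimum
distance (1 - Tanimoto) to the chosen set, breaking ties by lexicographic id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import DataStructs

from .libfilter import Molecule

__all__ = ["DiversityScore", "udscore", "select_diverse"]

FP_RADIUS = 2
FP_BITS = 2048


@dataclass
class DiversityScore:
    value: float
    n_unique: int
    fingerprint_params: tuple[str, int, int] = ("morgan", FP_RADIUS, FP_BITS)


def _unique(lib: list[Molecule]) -> list[Molecule]:
    seen: dict[str, Molecule] = {}
    for m in lib:
        seen.setdefault(m.smiles, m)
    return list(seen.values())


def _similarity_matrix(mols: list[Molecule]) -> np.ndarray:
    fps = [m.fingerprint(FP_RADIUS, FP_BITS) for m in mols]
    n = len(fps)
    sim = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
            sim[i, i + 1:] = row
            sim[i + 1:, i] = row
    return sim


def udscore(lib: list[Molecule]) -> DiversityScore:
    """Diversity of a library on [0, 1]; 0 for one unique structure."""
    if not lib:
        raise ValueError("library is empty")
    uniq = _unique(lib)
    n = len(uniq)
    if n == 1:
        return DiversityScore(value=0.0, n_unique=1)
    sim = _similarity_matrix(uniq)
    iu = np.triu_indices(n, k=1)
    value = float(1.0 - sim[iu].mean())
    return DiversityScore(value=value, n_unique=n)


def select_diverse(lib: list[Molecule], k: int) -> list[Molecule]:
    """Deterministic MaxMin selection of ``k`` mutually dissimilar molecules."""
    uniq = _unique(lib)
    n = len(uniq)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}] (library has {n} unique structures)")
    if k == n:
        return list(uniq)
    if k == 1:
        return [min(uniq, key=lambda m: m.id)]

    dist = 1.0 - _similarity_matrix(uniq)
    ids = [m.id for m in uniq]

    # seed: globally most dissimilar pair; ties by lexicographic id pair
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            key = (-dist[i, j], *sorted((ids[i], ids[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
    chosen = [best[1], best[2]]

    while len(chosen) < k:
        remaining = [i for i in range(n) if i not in chosen]
        mind = {i: min(dist[i, j] for j in chosen) for i in remaining}
        nxt = min(remaining, key=lambda i: (-mind[i], ids[i]))
        chosen.append(nxt)
    chosen_set = set(chosen)
    return [m for i, m in enumerate(uniq) if i in chosen_set]
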