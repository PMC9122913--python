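"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from ppiscreen import synthkit
from ppiscreen.libfilter import Molecule


@pytest.fixture(scope="session")
def cavity_receptor():
    """Block receptor with one carved 4-A spherical cavity at the origin."""
    s, truth = synthkit.make_cavity_receptor([4.0])
    return s, truth


@pytest.fixture(scope="session")
def slim_cavity_receptor():
    """Thin-walled single-cavity receptor for docking-heavy tests."""
    s, truth = synthkit.make_cavity_receptor([4.0], wall=2.4)
    return s, truth


@pytest.fixture(scope="session")
def binder_library():
    lib, truth = synthkit.make_binder_library(19, seed=11)
    mols = [Molecule.from_smiles(mid, smi) for mid, smi in lib]
    return mols, truth


@pytest.fixture(scope="session")
def filter_library():
    lib, truth = synthkit.make_filter_library(50, seed=3)
    mols = [Molecule.from_smiles(mid, smi) for mid, smi in lib]
    return mols, truth


@pytest.fixture(scope="session")
def pose_ensemble_60_30_10():
    rec, coords, scores, truth = synthkit.make_pose_ensemble(
        [60, 30, 10], jitter=1.0, separation=20.0, seed=5, best_cluster=2
    )
    return rec, coords, scores, truth


def brute_force_select(assignments, scores):
    """Independent restatement of the largest-cluster/best-score rule."""
    from collections import Counter

    counts = Counter(assignments)
    top = max(counts.values())
    candidates = [i for i, a in enumerate(assignments) if counts[a] == top]
    return min(candidates, key=lambda i: (scores[i], i))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
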