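"""Scoring geometry, site docking, blind docking and the tiered funnel."""

import numpy as np
import pytest

from ppiscreen import synthkit
from ppiscreen.dockfunnel import (
    CLASH_FACTOR,
    CONTACT_RANGE,
    DEFAULT_WEIGHTS,
    HBOND_RANGE,
    HYDROPHOBIC_RANGE,
    FunnelConfig,
    Pose,
    ScoreBreakdown,
    Site,
    _Ligand,
    _ReceptorView,
    _score_coords,
    dock_all_around,
    dock_site,
    enumerate_candidates,
    run_funnel,
    score_pose,
)
from ppiscreen.libfilter import Molecule
from ppiscreen.structio import Atom, Structure

SMALL_STAGES = [("htvs", 0.5, 50), ("sp", 0.4, 200), ("xp", 5, 600)]


def _receptor_single_atom(element, xyz):
    return Structure(
        models=[[Atom(1, element, element, "A", 47, "", "THR", tuple(map(float, xyz)))]]
    )


def _polar_ligand():
    """Two-atom C-O ligand with the O a donor; neighbors known."""
    coords = np.array([[0.0, 0.0, 0.0], [1.43, 0.0, 0.0]])  # C, O
    return _Ligand(
        coords=coords,
        elements=["C", "O"],
        is_polar=np.array([False, True]),
        is_donor=np.array([False, True]),
        is_carbon=np.array([True, False]),
        neighbors=[[1], [0]],
        radii=np.array([1.7, 1.52]),
    )


class TestScoring:
    def test_single_hbond_counted_at_ideal_geometry(self):
        lig = _polar_ligand()
        # receptor O collinear with the C-O bond, 2.9 A past the O: the
        # neighbor angle C-O-O(rec) is 180 degrees
        rec = _ReceptorView(_receptor_single_atom("O", (1.43 + 2.9, 0.0, 0.0)))
        bd = _score_coords(lig, lig.coords, rec, np.array([0]))
        assert bd.hbond == 1.0

    def test_hbond_rejected_at_eclipsed_angle(self):
        lig = _polar_ligand()
        # receptor O on the same side as the bonded neighbor: angle ~ 0
        rec = _ReceptorView(_receptor_single_atom("O", (1.43 - 2.9, 0.0, 0.0)))
        bd = _score_coords(lig, lig.coords, rec, np.array([0]))
        assert bd.hbond == 0.0

    def test_clash_monotonicity(self):
        rec = _receptor_single_atom("C", (0.0, 0.0, 0.0))
        near = Pose(np.array([[0.5, 0.0, 0.0]]), Site((0, 0, 0), 5.0), 0.0, None)
        far = Pose(np.array([[4.0, 0.0, 0.0]]), Site((0, 0, 0), 5.0), 0.0, None)
        bd_near = score_pose(rec, near)
        bd_far = score_pose(rec, far)
        assert bd_near.steric_clash > 0.0
        assert bd_far.steric_clash == 0.0
        assert bd_near.total > bd_far.total

    def test_no_clash_term_when_separated(self):
        rec = _receptor_single_atom("C", (0.0, 0.0, 0.0))
        pose = Pose(np.array([[3.9, 0.0, 0.0]]), Site((0, 0, 0), 5.0), 0.0, None)
        assert score_pose(rec, pose).steric_clash == 0.0

    def test_total_is_weighted_resummation(self, slim_cavity_receptor, rng):
        s, _ = slim_cavity_receptor
        for _ in range(100):
            coords = rng.uniform(-3, 3, size=(5, 3))
            bd = score_pose(s, Pose(coords, Site((0, 0, 0), 5.0), 0.0, None))
            manual = float(
                np.dot(
                    bd.weights,
                    [bd.steric_clash, bd.contact, bd.hbond, bd.hydrophobic],
                )
            )
            assert bd.total == pytest.approx(manual, abs=1e-9)

    def test_empty_pose_rejected(self, slim_cavity_receptor):
        s, _ = slim_cavity_receptor
        with pytest.raises(ValueError):
            score_pose(s, Pose(np.zeros((0, 3)), Site((0, 0, 0), 5.0), 0.0, None))


def _independent_pose_score(lig, lig_coords, rec_atoms, weights=DEFAULT_WEIGHTS):
    """Independent re-implementation of the scoring terms (one ligand atom at
    a time against the full receptor table) used as a brute-force oracle."""
    from ppiscreen.pocketfinder import VDW_RADII

    rxyz = np.array([a.xyz for a in rec_atoms])
    rel = np.array([a.element for a in rec_atoms])
    rrad = np.array([VDW_RADII.get(e, 1.7) for e in rel])
    clash = contact = hydrophobic = 0.0
    hbond = 0
    for i, (xi, el_i) in enumerate(zip(lig_coords, lig.elements)):
        d = np.linalg.norm(rxyz - xi, axis=1)
        thresh = CLASH_FACTOR * (VDW_RADII.get(el_i, 1.7) + rrad)
        clash += float(np.sum(np.clip(thresh - d, 0.0, None)))
        contact += int(np.sum((d >= CONTACT_RANGE[0]) & (d <= CONTACT_RANGE[1])))
        if el_i == "C":
            hydrophobic += int(
                np.sum((rel == "C") & (d >= HYDROPHOBIC_RANGE[0]) & (d <= HYDROPHOBIC_RANGE[1]))
            )
        if el_i in ("N", "O"):
            cand = np.nonzero(
                np.isin(rel, ("N", "O")) & (d >= HBOND_RANGE[0]) & (d <= HBOND_RANGE[1])
            )[0]
            for j in cand:
                ok = True
                v = rxyz[j] - xi
                v = v / np.linalg.norm(v)
                for ni in lig.neighbors[i]:
                    u = np.subtract(lig_coords[ni], xi)
                    u = u / np.linalg.norm(u)
                    if float(np.dot(u, v)) > np.cos(np.radians(120.0)):
                        ok = False
                        break
                if ok:
                    hbond += 1
    w = weights
    return w[0] * clash + w[1] * contact + w[2] * hbond + w[3] * hydrophobic


class TestDockSite:
    def test_grid_search_equals_exhaustive_enumeration(self, slim_cavity_receptor):
        from ppiscreen.dockfunnel import ligand_conformer

        s, _ = slim_cavity_receptor
        site = Site((0.0, 0.0, 0.0), 2.0, "pocket_0")
        rec_atoms = s.heavy_atoms()
        for seed, smi in enumerate(["CC", "CCO", "CCC", "C1CCCCC1", "CO"]):
            m = Molecule.from_smiles(f"m{seed}", smi)
            pose = dock_site(s, m, site, "htvs", seed=seed, search="grid", grid=1.0)
            lig = ligand_conformer(m, seed=seed)
            best = None
            for R, t in enumerate_candidates(site, 1.0, lig.coords):
                coords = lig.coords @ R.T + t
                sc = _independent_pose_score(lig, coords, rec_atoms)
                if best is None or sc < best - 1e-12:
                    best = sc
            assert pose.score == pytest.approx(best, abs=1e-6)

    def test_same_seed_bit_identical(self, slim_cavity_receptor):
        s, _ = slim_cavity_receptor
        site = Site((0.0, 0.0, 0.0), 4.0, "pocket_0")
        m = Molecule.from_smiles("m", "CCO")
        p1 = dock_site(s, m, site, "htvs", seed=7, samples=50)
        p2 = dock_site(s, m, site, "htvs", seed=7, samples=50)
        assert np.array_equal(p1.ligand_coords, p2.ligand_coords)
        assert p1.score == p2.score and p1.sample_index == p2.sample_index

    def test_prefix_sampling_improves_with_precision(self, slim_cavity_receptor):
        s, _ = slim_cavity_receptor
        site = Site((0.0, 0.0, 0.0), 4.0, "pocket_0")
        smis = ["CC", "CCO", "CCC", "CCCC", "C1CCCCC1", "CCN", "CCCO", "CC(C)C", "CCCC(C)C", "CCOC"]
        for seed, smi in enumerate(smis):
            m = Molecule.from_smiles(f"m{seed}", smi)
            scores = [
                dock_site(s, m, site, "htvs", seed=seed, samples=n).score
                for n in (25, 100, 400)
            ]
            assert scores[1] <= scores[0] + 1e-12
            assert scores[2] <= scores[1] + 1e-12

    def test_score_equals_breakdown_total(self, slim_cavity_receptor):
        s, _ = slim_cavity_receptor
        pose = dock_site(
            s, Molecule.from_smiles("m", "CCO"), Site((0, 0, 0), 4.0, "p"), "htvs",
            seed=1, samples=50,
        )
        assert pose.score == pytest.approx(pose.breakdown.total, abs=1e-9)


class TestAllAround:
    def test_blind_docking_finds_the_cavity(self, slim_cavity_receptor):
        s, truth = slim_cavity_receptor
        m = Molecule.from_smiles("m", "C1CCCCC1")
        pose = dock_all_around(
            s, m, "htvs", seed=3, samples=60, n_patches=12,
            pocket_kwargs={"spacing": 0.8},
        )
        assert pose.site.source == "pocket_0"
        center = np.array(truth.labels["cavity_centers"][0])
        assert np.linalg.norm(pose.ligand_coords.mean(axis=0) - center) < 4.0

    def test_symmetric_cavities_tie_break_to_lower_index(self):
        # separation chosen so the two cavity environments are identical by a
        # lattice translation; the site-independent sampling stream then
        # yields exactly equal best scores
        s, _ = synthkit.make_cavity_receptor([4.0, 4.0], separation=12.6)
        m = Molecule.from_smiles("m", "CCC")
        pose = dock_all_around(
            s, m, "htvs", seed=5, samples=40, n_patches=8,
            pocket_kwargs={"spacing": 0.8},
        )
        assert pose.site.source == "pocket_0"

    def test_hbond_report_format(self):
        pose = Pose(
            np.zeros((1, 3)), Site((0, 0, 0), 5.0), 0.0,
            ScoreBreakdown(0, 0, 0, 0),
            hbond_partners=[("A", 47, "OG1"), ("A", 50, "NH1"), ("A", 150, "NH2")],
        )
        pose._partner_resnames = ["THR", "ARG", "ARG"]
        assert pose.hbond_summary() == "T47, R50, R150"


class TestFunnel:
    def test_stage_arithmetic(self, slim_cavity_receptor):
        s, _ = slim_cavity_receptor
        site = Site((0.0, 0.0, 0.0), 4.0, "pocket_0")
        smis = ["CC", "CCO", "CCC", "CCCC", "C1CCCCC1", "CCN", "CCCO", "CC(C)C", "CCCCC", "CCOC"]
        mols = [Molecule.from_smiles(f"m{i}", s_) for i, s_ in enumerate(smis)]
        cfg = FunnelConfig(
            stages=[("htvs", 0.5, 20), ("sp", 0.4, 50)], seed=1, filters_first=False
        )
        rep = run_funnel(s, mols, [site], cfg)
        assert [len(st["survivors"]) for st in rep.stages] == [5, 2]
        assert rep.stages[0]["n_scored"] == 10
        assert rep.stages[0]["coverage"] == 1.0

    def test_survivors_nested_and_coverage_full(self, slim_cavity_receptor, binder_library):
        s, _ = slim_cavity_receptor
        mols, _ = binder_library
        cfg = FunnelConfig(stages=SMALL_STAGES, seed=11, filters_first=False)
        rep = run_funnel(s, mols, [Site((0.0, 0.0, 0.0), 4.0, "pocket_0")], cfg)
        ids = [set(mid for mid, _ in st["survivors"]) for st in rep.stages]
        for a, b in zip(ids, ids[1:]):
            assert b <= a
        assert rep.stages[0]["n_scored"] == len(mols)

    def test_empty_library_reports_zero_coverage(self, slim_cavity_receptor):
        s, _ = slim_cavity_receptor
        rep = run_funnel(s, [], [Site((0, 0, 0), 4.0, "p")], FunnelConfig(seed=0))
        assert rep.hits == []
        assert any("0 admitted" in n for n in rep.notes)

    def test_keep_larger_than_pool_warns_and_keeps_all(self, slim_cavity_receptor):
        s, _ = slim_cavity_receptor
        mols = [Molecule.from_smiles("a", "CC"), Molecule.from_smiles("b", "CCC")]
        cfg = FunnelConfig(stages=[("htvs", 10, 20)], seed=0, filters_first=False)
        rep = run_funnel(s, mols, [Site((0, 0, 0), 4.0, "p")], cfg)
        assert len(rep.hits) == 2
        assert any("keeping all" in n for n in rep.notes)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            FunnelConfig(stages=[])
        with pytest.raises(ValueError):
            FunnelConfig(stages=[("htvs", 0.5, 200), ("sp", 0.5, 100)])
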