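"""Command-line interface and end-to-end screen orchestration.

``ppiscreen run`` drives the full screen — pocket detection, admission
filters, the tiered docking funnel, ranked hits — from a YAML config, and
the subcommands expose each stage standalone. Defaults mirror the
conventional screening setup: druggability threshold pKd 6.5, three
docking tiers in series, final hit list of 10, protein-protein ensembles of
5000 models.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import dockfunnel, kinetics, libfilter, pocketfinder, ppimodel, structio, synthkit, udscore

log = logging.getLogger("ppiscreen")


@dataclass
class ScreenConfig:
    receptor: str
    library: str
    target: str = "ppi_interface"  # ppi_interface | all_around | explicit site
    site: tuple[float, float, float] | None = None
    site_radius: float = 5.0
    interface_groups: tuple[list[str], list[str]] | None = None
    pkd_threshold: float = pocketfinder.DEFAULT_PKD_THRESHOLD
    spacing: float = 0.8
    min_volume: float = 50.0
    max_violations: int = 1
    stages: list = field(
        default_factory=lambda: [["htvs", 0.1, 200], ["sp", 0.1, 2000], ["xp", 10, 20000]]
    )
    seed: int = 0
    out: str = "screen_out"

    @classmethod
    def from_yaml(cls, path: str) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "receptor" not in raw or "library" not in raw:
            raise ValueError("config must set 'receptor' and 'library'")
        return cls(**raw)

    def echo(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)


def run_screen(cfg: ScreenConfig) -> int:
    """Full screen: pockets -> filters -> funnel -> ranked hits.

    Writes pockets.tsv, filters.tsv, funnel_report.json, hits.tsv, poses.pdb,
    run.log and a config echo into the output directory. Returns 0 on
    success; on a stage failure, partial outputs are retained and the failing
    stage is named in run.log and the exit code category.
    """
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    (out / "config_echo.yaml").write_text(cfg.echo())
    stage = "setup"
    try:
        stage = "read_inputs"
        receptor = structio.read_structure(cfg.receptor)
        lib = libfilter.load_library(cfg.library)
        log.info("loaded receptor %s (%d atoms), library %d molecules",
                 cfg.receptor, len(receptor.atoms), len(lib))

        stage = "pockets"
        sites: list[dockfunnel.Site] = []
        if cfg.target == "explicit" and cfg.site is not None:
            sites = [dockfunnel.Site(tuple(cfg.site), cfg.site_radius, "user")]
            (out / "pockets.tsv").write_text("# explicit user site; no pocket scan\n")
        else:
            pockets = pocketfinder.detect_pockets(
                receptor, spacing=cfg.spacing, min_volume=cfg.min_volume,
                threshold=cfg.pkd_threshold,
            )
            classes = None
            if cfg.interface_groups is not None:
                iface = structio.interface_residues(
                    receptor, cfg.interface_groups[0], cfg.interface_groups[1]
                )
                classified = pocketfinder.classify_pockets(pockets, iface)
                classes = [c for _, c in classified]
            (out / "pockets.tsv").write_text(
                pocketfinder.pockets_to_tsv(pockets, classes, threshold=cfg.pkd_threshold)
            )
            chosen = list(range(len(pockets)))
            if cfg.target == "ppi_interface" and classes is not None:
                chosen = [i for i, c in enumerate(classes) if c.label == "ppi_interface"]
            sites = [
                dockfunnel.Site(tuple(np.round(pockets[i].centroid, 3)), cfg.site_radius,
                                f"pocket_{i}")
                for i in chosen
            ]
            if cfg.target == "all_around":
                sites += dockfunnel.surface_sites(receptor, radius=cfg.site_radius)
            log.info("pockets: %d detected, %d sites targeted", len(pockets), len(sites))
        if not sites:
            log.warning("no target sites; docking every detected pocket is empty")

        stage = "filters"
        verdicts = libfilter.screen_library(lib, max_violations=cfg.max_violations)
        (out / "filters.tsv").write_text(libfilter.verdicts_to_tsv(verdicts))
        n_admitted = len(libfilter.admitted(verdicts))
        log.info("%d admitted of %d after Lipinski/PAINS/reactive filters",
                 n_admitted, len(lib))
        if n_admitted == 0:
            log.info("0 admitted molecules; writing empty hit list")

        stage = "funnel"
        fcfg = dockfunnel.FunnelConfig(
            stages=[(p, k, s) for p, k, s in cfg.stages], seed=cfg.seed
        )
        report = dockfunnel.run_funnel(receptor, lib, sites, fcfg)
        (out / "funnel_report.json").write_text(report.to_json())
        hits_lines = ["# rank\tid\tscore\tsite\thbond_partners"]
        for rank, (mid, score) in enumerate(report.hits, start=1):
            prov = report.provenance[mid]
            hits_lines.append(
                f"{rank}\t{mid}\t{score:.4f}\t{prov.get('best_site', '-')}\t"
                f"{prov.get('hbond_partners', '') or '-'}"
            )
        (out / "hits.tsv").write_text("\n".join(hits_lines) + "\n")
        log.info("funnel: %d hits ranked", len(report.hits))

        stage = "poses"
        _write_hit_poses(out, receptor, lib, report, sites, fcfg)
        log.info("screen complete")
        return 0
    except Exception as exc:  # pragma: no cover - error path exercised in tests
        log.error("stage %s failed: %s", stage, exc)
        (out / "error.json").write_text(json.dumps({"stage": stage, "error": str(exc)}))
        return 1
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_hit_poses(out, receptor, lib, report, sites, fcfg):
    by_id = {m.id: m for m in lib}
    models = []
    for mid, _score in report.hits:
        m = by_id[mid]
        best_site, best_pose = None, None
        for site in sites:
            pose = dockfunnel.dock_site(
                receptor, m, site, fcfg.stages[-1][0], fcfg.seed,
                samples=fcfg.stages[-1][2],
            )
            if best_pose is None or pose.score < best_pose.score - 1e-12:
                best_pose, best_site = pose, site
        if best_pose is None:
            continue
        atoms = [
            structio.Atom(i + 1, "C", "C", "L", i + 1, "", "LIG",
                          tuple(map(float, xyz)), het=True)
            for i, xyz in enumerate(best_pose.ligand_coords)
        ]
        models.append(atoms)
    if models:
        structio.write_structure(structio.Structure(models=models), out / "poses.pdb")


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level):
    """Desk-scale toolkit for PPI druggability and virtual-screening funnels."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", default=None, type=int, help="override config seed")
@click.option("--out", default=None, help="override output directory")
def run(config_path, seed, out):
    """Run the full screen from a YAML config."""
    cfg = ScreenConfig.from_yaml(config_path)
    if seed is not None:
        cfg.seed = seed
    if out is not None:
        cfg.out = out
    sys.exit(run_screen(cfg))


@cli.command()
@click.argument("receptor", type=click.Path(exists=True))
@click.option("--spacing", default=0.8, show_default=True)
@click.option("--min-volume", default=50.0, show_default=True)
@click.option("--threshold", default=6.5, show_default=True,
              help="druggable-pocket pKd cutoff [paper default]")
@click.option("--out", default="-")
def pockets(receptor, spacing, min_volume, threshold, out):
    """Detect and score druggable pockets."""
    s = structio.read_structure(receptor)
    ps = pocketfinder.detect_pockets(s, spacing=spacing, min_volume=min_volume,
                                     threshold=threshold)
    text = pocketfinder.pockets_to_tsv(ps, threshold=threshold)
    click.echo(text) if out == "-" else Path(out).write_text(text)


@cli.command("filter")
@click.argument("library", type=click.Path(exists=True))
@click.option("--max-violations", default=1, show_default=True)
@click.option("--out", default="-")
def filter_cmd(library, max_violations, out):
    """Lipinski / frequent-hitter / reactive-chemistry verdicts."""
    lib = libfilter.load_library(library)
    verdicts = libfilter.screen_library(lib, max_violations=max_violations)
    text = libfilter.verdicts_to_tsv(verdicts)
    click.echo(text) if out == "-" else Path(out).write_text(text)


@cli.command("udscore")
@click.argument("library", type=click.Path(exists=True))
def udscore_cmd(library):
    """Library diversity score (JSON to stdout)."""
    lib = libfilter.load_library(library)
    ds = udscore.udscore(lib)
    click.echo(json.dumps({"value": ds.value, "n_unique": ds.n_unique,
                           "fingerprint": list(ds.fingerprint_params)}))


@cli.command()
@click.argument("receptor", type=click.Path(exists=True))
@click.argument("library", type=click.Path(exists=True))
@click.option("--site", nargs=3, type=float, default=None, help="site centroid x y z")
@click.option("--radius", default=5.0, show_default=True)
@click.option("--precision", default="sp", show_default=True)
@click.option("--seed", default=0, show_default=True)
def dock(receptor, library, site, radius, precision, seed):
    """Dock each library molecule at one site (or blind, all around)."""
    s = structio.read_structure(receptor)
    lib = libfilter.load_library(library)
    for m in lib:
        if site:
            pose = dockfunnel.dock_site(s, m, dockfunnel.Site(tuple(site), radius, "user"),
                                        precision, seed)
        else:
            pose = dockfunnel.dock_all_around(s, m, precision, seed, site_radius=radius)
        click.echo(f"{m.id}\t{pose.score:.4f}\t{pose.site.source}\t"
                   f"{pose.hbond_summary() or '-'}")


@cli.command("ppidock-select")
@click.argument("receptor", type=click.Path(exists=True))
@click.argument("poses", type=click.Path(exists=True))
@click.argument("scores", type=click.Path(exists=True))
@click.option("--rmsd-threshold", default=5.0, show_default=True)
@click.option("--out", default="-")
def ppidock_select(receptor, poses, scores, rmsd_threshold, out):
    """Cluster a pose ensemble and select the consensus model."""
    rec = structio.read_structure(receptor)
    pos = structio.read_structure(poses)
    sc = [float(x) for x in Path(scores).read_text().split()]
    e = ppimodel.read_pose_ensemble(rec, pos, sc)
    clusters = ppimodel.cluster_poses(e, rmsd_threshold)
    sel = ppimodel.select_model(clusters, e)
    text = ppimodel.clusters_to_tsv(clusters, e, selected=sel)
    click.echo(text) if out == "-" else Path(out).write_text(text)


@cli.command("kinetics")
@click.argument("tsv", type=click.Path(exists=True))
@click.option("--intercept", default="fixed", type=click.Choice(["fixed", "free"]),
              show_default=True)
@click.option("--seed", default=0, show_default=True)
def kinetics_cmd(tsv, intercept, seed):
    """Fit half-lives from a (t, y[, replicate]) TSV; JSON to stdout."""
    out = {}
    for tc in kinetics.read_timecourse_tsv(tsv):
        fit = kinetics.fit_decay(tc, intercept=intercept, seed=seed)
        out[tc.replicate] = fit.to_json_dict()
    click.echo(json.dumps(out, indent=2))


@cli.command()
@click.argument("what", type=click.Choice(["receptor", "library", "ensemble", "decay"]))
@click.option("--seed", default=0, show_default=True)
@click.option("--out", default="synth_out")
def synth(what, seed, out):
    """Generate a synthetic fixture plus its truth sidecar."""
    outp = Path(out)
    outp.mkdir(parents=True, exist_ok=True)
    if what == "receptor":
        s, truth = synthkit.make_cavity_receptor([4.0], seed=seed)
        structio.write_structure(s, outp / "receptor.pdb")
    elif what == "library":
        lib, truth = synthkit.make_filter_library(50, seed=seed)
        (outp / "library.smi").write_text(
            "".join(f"{smi}\t{mid}\n" for mid, smi in lib)
        )
    elif what == "ensemble":
        rec, coords, scores, truth = synthkit.make_pose_ensemble([60, 30, 10], seed=seed)
        structio.write_structure(rec, outp / "receptor.pdb")
        models = [
            [structio.Atom(i + 1, "C", "CA", "P", i + 1, "", "GLY", tuple(map(float, c)))
             for i, c in enumerate(pose)]
            for pose in coords
        ]
        structio.write_structure(structio.Structure(models=models), outp / "poses.pdb")
        (outp / "scores.txt").write_text("\n".join(f"{x:.6f}" for x in scores) + "\n")
    else:
        t, y = synthkit.make_decay_series(5.0, 0.05, 7, seed=seed)
        (outp / "decay.tsv").write_text(
            "t\ty\n" + "".join(f"{a:.4f}\t{b:.6f}\n" for a, b in zip(t, y))
        )
        truth = synthkit.FixtureTruth("make_decay_series", seed,
                                      {"halflife": 5.0, "sigma": 0.05, "n": 7}, {})
    (outp / "truth.json").write_text(truth.to_json())
    click.echo(str(outp))


if __name__ == "__main__":
    cli()
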