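# ppiscreen

A desk-scale, fully open toolkit for the computational side of finding
small-molecule disruptors of a protein–protein interaction (PPI), of the
kind used to hunt for compounds that break a kinase–cyclin complex at its
binding interface rather than at the ATP site.

It is aimed at computational chemists and structural biologists who want a
transparent, scriptable, deterministic version of a screening workflow that
is usually assembled from commercial black boxes:

* **Pocket detection and druggability** (`pocketfinder`) — scan-line cavity
  detection on a grid (LIGSITE-style burial test), a documented pKd-like
  druggability score with the conventional *druggable if pKd > 6.5* flag,
  and classification of pockets as PPI-interface / annotated-site / other by
  lining-residue overlap with an interface residue set.
* **Admission filters** (`libfilter`) — Lipinski's rule of five
  (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10, ≤ 1 violation passes),
  a bundled frequent-hitter (PAINS-family) SMARTS screen, and a
  reactive-chemistry screen (alkylators, acylators, Michael acceptors,
  oxidizers).
* **Library diversity** (`udscore`) — a size-independent diversity score,
  `UD = 1 − mean pairwise Tanimoto similarity` over unique structures
  (Morgan fingerprints, radius 2, 2048 bits), and deterministic MaxMin
  diverse-subset selection.
* **Tiered docking funnel** (`dockfunnel`) — three precision tiers
  (htvs/sp/xp) run in series over an open four-term geometric scorer
  (clash, contacts, H-bonds, hydrophobic contacts; lower = better), with
  *full first-stage coverage* (every admitted molecule is docked), nested
  survivor sets, seeded determinism, and a blind "all-around" mode that
  searches every detected pocket plus a uniform surface scan with no prior
  site knowledge.
* **PP docking post-processing** (`ppimodel`) — RMSD clustering of pose
  ensembles and the consensus rule *best score within the largest cluster*,
  plus Jaccard interface-overlap analysis to call mutually exclusive
  binders.
* **Decay kinetics** (`kinetics`) — half-life estimation from chase time
  courses by the exponential line equation `ln y = −k t`,
  `t½ = ln 2 / k`, with seeded bootstrap confidence intervals and
  treated-vs-control half-life ratios.
* **Synthetic fixtures** (`synthkit`) — deterministic generators (carved-
  cavity receptors, labeled chemical libraries, planted-binder screens,
  clustered pose ensembles, noisy decay series) with ground-truth sidecars;
  these power the entire test surface.

Scores produced by the open docking scorer are *not* commercial docking
scores, and no binding-affinity accuracy is claimed; the funnel
architecture, its contracts (coverage, nestedness, determinism) and the
post-processing rules are the point.

## Worked example

Generate a synthetic receptor with one 4 Å spherical cavity plus a labeled
library, then inspect it:

```
$ ppiscreen synth receptor --seed 1 --out r1
$ ppiscreen synth library  --seed 3 --out l1
$ ppiscreen pockets r1/receptor.pdb --spacing 0.6 | cut -f1-4
# id    volume_A3   predicted_pkd   druggable
P1      268.1       11.71           True
```

The detected pocket volume (268.1 ų) matches the analytic volume of the
carved 4 Å sphere (4/3·π·4³ = 268.1 ų); its heuristic druggability score
11.71 is far above the 6.5 cutoff, so the pocket is flagged druggable.

```
$ ppiscreen udscore l1/library.smi
{"value": 0.9115089540038889, "n_unique": 18, "fingerprint": ["morgan", 2, 2048]}
```

The 50-entry library collapses to 18 unique structures whose mean pairwise
Tanimoto similarity is ≈ 0.09 — a highly diverse set (UD ≈ 0.91 on the 0–1
scale).

```
$ ppiscreen synth decay --seed 2 --out d1
$ ppiscreen kinetics d1/decay.tsv
{"r1": {"k_per_hour": 0.1390, "halflife_hours": 4.987,
        "ci_hours": [4.821, 5.166], "r2": 0.991, ...}}
```

The decay series was generated with a true half-life of 5 h and 5%
multiplicative noise; the log-linear fit recovers 4.99 h with a bootstrap
interval that covers the truth.

A full screen (pockets → filters → funnel → ranked hits) runs from a YAML
config:

```
$ ppiscreen run --config screen.yaml --seed 11 --out out/
$ head -3 out/hits.tsv
# rank  id                  score      site      hbond_partners
1       BINDER_adamantane   -527.2     pocket_0  -
```

On the planted-binder fixture the one molecule constructed to complement
the cavity ranks first, ahead of 19 decoys.

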