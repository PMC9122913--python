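# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic fixtures emulate (and do not), and the
design decisions taken where the design was genuinely open.

## Structures and interfaces (`structio`)

Structures are flat atom tables (serial, element, name, chain, author
residue number + insertion code, residue name, xyz in Å, occupancy, HETATM
flag), grouped into ordered models. PDB and mmCIF parsing is delegated to
gemmi; writing uses a small fixed-column PDB writer so that regenerating a
fixture with the same seed reproduces the file byte-for-byte. Author
residue numbering is the canonical addressing scheme everywhere; sequential
indices never leak into reported results. Alternate locations collapse to
the highest-occupancy conformer (ties: first in file).

**Interface residues.** A residue of group A is an interface residue iff at
least one of its heavy atoms lies within a cutoff of any heavy atom of
group B (hydrogens are ignored). The default cutoff is 5.0 Å — a
conventional heavy-atom contact definition — and is a parameter, not a
constant; reported interface sizes should always be read together with the
cutoff used. Contact pairs carry minimum heavy-atom distances for export.

**Superposition.** Rigid least-squares fitting is the Kabsch algorithm via
SVD, with the reflection branch corrected so det(R) = +1. Degenerate inputs
(n < 3, collinear or coincident points) are rejected rather than silently
fit; the degeneracy test is a relative threshold of 1e-9 on the second
singular value of the cross-covariance.

## Pocket detection and druggability (`pocketfinder`)

Cavity detection is a scan-line burial test on a regular grid (the
LIGSITE family of methods). Grid points within the van der Waals radius of
any heavy atom are protein; remaining points are solvent. A solvent point
is *buried* when protein occupancy exists on both sides along at least 4 of
7 scan directions (three axes, four body diagonals). Pockets are
26-connected components of buried points with volume `n · spacing³` above a
floor (default 50 ų). Defaults: spacing 0.8 Å, probe 1.4 Å (used as grid
padding), all exposed as parameters. Lining residues are those with a heavy
atom within 4.0 Å of any pocket grid point; enclosure is the mean fraction
of buried directions over the pocket's points; hydrophobic fraction uses
the residue set {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, CYS}.

**Druggability score.** An explicit linear heuristic on a pKd-like scale:

    predicted_pkd = 1.2 · ln(volume) + 3.0 · enclosure + 2.0 · hydrophobic_fraction

(bias 0). The weights were set once so that larger, more enclosed, more
hydrophobic pockets order correctly on carved-cavity fixtures; the formula
is documented as a heuristic and is *not* a reproduction of any published
or commercial scorer's numerics. The only value carried over from practice
is the decision threshold: a pocket is flagged druggable when
predicted_pkd > 6.5. Pocket-level classification against a PPI interface
uses `interface_overlap = |lining ∩ interface| / |lining|` with a default
overlap threshold of 0.3.

Determinism and invariances checked by the tests: identical rescoring,
refinement convergence of the carved-sphere volume toward the analytic
value as spacing halves, and exact invariance of the pocket set under
axis-aligned rigid transforms (the grid is re-derived from the atoms).

## Admission filters (`libfilter`)

Property conventions follow Lipinski's original counting: donors are N/O
heteroatoms bearing ≥ 1 hydrogen (counted once per heteroatom); acceptors
are all N and O atoms (plain N+O count); molecular weight from standard
atomic masses; logP is the Crippen atom-contribution estimate (RDKit's
parameterization). The rule-of-five verdict passes with at most one
violation by default (`max_violations` exposed), and names each violated
criterion.

The frequent-hitter screen matches a bundled, versioned set of well-known
pan-assay interference motifs (rhodanines, catechols, quinones,
aryl hydrazones/azo compounds, Mannich phenols, ene-rhodanines, and
related families) written as SMARTS; any match fails. The
reactive-chemistry screen is a *structural stand-in* for a protein-
reactivity assay: SMARTS for electrophiles and oxidizers (acyl/sulfonyl
halides, anhydrides, iso(thio)cyanates, aldehydes, alkyl halides, epoxides,
aziridines, Michael acceptors, quinones, peroxides, N-halamines,
diazonium), each tagged with a reactive class that is reported on failure.
Both pattern files are data assets (`name<TAB>[class<TAB>]SMARTS`), loaded
and validated at first use; a malformed pattern fails loudly with its name.
The bundled sets are curated subsets — adding patterns can only shrink the
pass set (verified as a monotonicity test).

## Library diversity (`udscore`)

The diversity score of a library is

    UD = 1 − mean pairwise Tanimoto similarity

over all distinct unordered pairs of *unique* structures (deduplicated by
canonical SMILES); a single unique structure scores 0 by definition.
Averaging over unique pairs makes the score independent of library size in
expectation and exactly invariant under duplication — the one property the
score is required to have — and bounds it to [0, 1]. This formulation is a
reconstruction: it is a conventional mean-dissimilarity index chosen for
those properties, not a published algorithm. Fingerprints are hashed
circular (Morgan) fingerprints, radius 2, 2048 bits; the parameters are
recorded inside every score object.

Diverse subset selection is deterministic MaxMin on distance
`1 − Tanimoto`: seed with the globally most dissimilar pair, then greedily
add the molecule maximizing its minimum distance to the chosen set; all
ties break by lexicographic molecule id.

## Docking funnel (`dockfunnel`)

**Scorer.** Four geometric terms over heavy-atom pairs between ligand pose
and receptor:

* steric clash: Σ (0.7·(rᵢ+rⱼ) − d) over pairs closer than 0.7× the sum of
  vdW radii (zero when no pair is that close);
* contacts: count of pairs in [3.0, 4.5] Å;
* hydrogen bonds: N/O–N/O pairs in [2.5, 3.5] Å whose angle at the ligand
  atom against each of its bonded heavy neighbors is ≥ 120° (receptor-side
  connectivity is not available in a plain coordinate file and is not
  constrained; this is documented, not hidden);
* hydrophobic contacts: C–C pairs in [3.5, 5.0] Å.

The total is the weighted sum with weights (10, −0.05, −1, −0.1) —
lower is better. The clash weight is deliberately steep so that a pose
with substantial steric overlap can never outscore a clash-free one
regardless of its contact count; the reward weights set the relative value
of one hydrogen bond ≈ 20 contacts ≈ 10 hydrophobic pairs. These are
transparent, documented defaults for an open stand-in scorer; they are not
fitted to affinity data and carry no accuracy claim.

**Site docking.** Each molecule gets a single seeded 3D conformer (ETKDG +
MMFF cleanup; heavy atoms, centered); docking is rigid-body placement:
uniform random translations inside the site sphere × uniform random
orientations. Precision tiers differ only in sample count (htvs 200,
sp 2000, xp 20000 by default; all configurable). The sample stream is a
deterministic function of (seed, molecule id) only — not of the site or the
tier — which yields two contracts: (i) coarser tiers are prefixes of finer
tiers, so the best score can only improve with precision; (ii)
symmetry-equivalent sites receive identical relative candidate sets and
therefore tie exactly, with ties broken to the lower site index. A
deterministic enumerable mode (grid translations × the 24 proper cube
rotations) exists for oracle comparisons. Conformer failures are recorded
and skipped, never fatal.

**All-around (blind) mode.** Candidate sites are every detected pocket plus
a uniform surface scan (evenly distributed directions from the center of
geometry, one patch site just outside the surface along each); the best
pose over all sites wins. H-bond partners of the returned pose are reported
residue-wise in the conventional one-letter+number style (e.g. "T47, R50,
R150").

**Funnel.** Admission filters run first by default (switchable). Stage 1
docks every admitted molecule — coverage is asserted at 100% every run —
and each later stage re-docks the previous stage's survivors at higher
precision. A fractional `keep` retains that fraction of the previous
stage's survivor pool (the worked stage arithmetic 10 → 5 → 2 under keeps
(0.5, 0.4) fixes this reading); an integer `keep` is an absolute count,
with a warning when it exceeds the pool. The final ranked list defaults to
10. Reports carry per-stage survivors and scores, per-molecule provenance
(filter verdicts, per-stage scores, best site, H-bond partners), and a
SHA-256 hash of the canonical JSON for determinism checks.

## PP-docking post-processing (`ppimodel`)

Pose ensembles hold one receptor and n partner placements with scores
(lower better); the conventional generation size for rigid-body PP docking,
5000 models, is the default ensemble-size parameter. Pairwise partner RMSD
is computed without re-fitting (receptors are already in one frame), via
the Gram-matrix identity so 5000-pose ensembles stay O(n²) memory.
Clustering is greedy centroid clustering: repeatedly promote the unassigned
pose with the most unassigned neighbors within the RMSD threshold (default
5.0 Å; ties to the lower model index) and assign it with its neighbors.
Clusters partition the ensemble by construction.

Model selection implements the consensus rule: *the best-scoring member of
the largest cluster* — explicitly not the globally best score, which is
discarded when it sits in a minor cluster. Size ties go to the tied cluster
holding the better score; score ties to the lower model index. The rule is
continuously cross-checked against a brute-force restatement in the tests.

Overlap analysis computes each partner's receptor footprint (residues
within a cutoff, default 5.0 Å, via the interface machinery) and their
Jaccard index; at or above the exclusivity threshold (default 0.25) the
partners are called mutually exclusive binders. Both thresholds are
reconstructions of an unstated convention and are parameters.

## Decay kinetics (`kinetics`)

The default fit is log-linear ("exponential line equation"): least squares
on ln y = −k·t, with the intercept fixed through ln y(0) = 0. The fixed-
intercept mode requires genuinely normalized data (y(0) = 1 within 1e-6 is
asserted); a free-intercept mode and a nonlinear least-squares mode are
provided. Half-life is ln 2 / k bit-exactly; non-positive rates are flagged
as growth with an infinite half-life rather than an error. Confidence
intervals are seeded case-resampling bootstraps (1000 resamples by default,
when ≥ 4 points), with repeated draws kept (they re-weight points);
resamples that leave the rate unidentifiable are skipped.

One statistical subtlety is documented and exploited in the tests:
normalizing a series by its noisy t = 0 value shifts every log-residual by
the same amount. The fixed-intercept fit absorbs that shared term into the
slope, so point-resampling bootstraps understate the variance of the
half-life *ratio*; the free-intercept fit absorbs it into the intercept and
restores nominal interval coverage. The ratio-coverage checks therefore use
free-intercept fits; point estimation on normalized data may use either.

## Synthetic fixtures (`synthkit`)

Every generator is a pure function of (parameters, seed) and ships a truth
sidecar (JSON) recording what was planted.

* **Cavity receptors** are cubic lattices (1.2 Å pitch) of carbon dummy
  atoms, one residue per atom (ALA or SER to pin the lining chemistry),
  with spherical voids carved at recorded centers. A dense shell of atoms
  (0.5 Å spacing) smooths each cavity wall; the shell radius is shrunk by
  an empirically measured offset (0.049·s^1.4 for shell spacing s) so the
  solvent-visible void has the nominal radius — without it the discrete
  wall sits systematically a few hundredths of an Å too far out and the
  detected volume is biased high. This makes the analytic sphere volume a
  valid oracle at the few-percent level.
* **Dimer receptors** are two touching blocks (chains A/B) with an optional
  cavity at the seam (its lining residues are interface residues) or buried
  distally (≥ 6 Å from the seam, outside any conventional contact cutoff).
* **Filter libraries** sample from a curated template table (clean drugs,
  rule-of-five violators, frequent-hitter motifs, reactive electrophiles)
  whose filter labels are fixed by construction and verified against the
  bundled pattern sets.
* **Binder libraries** plant adamantane — a rigid ten-carbon cage that fits
  a 4 Å hydrophobic cavity snugly — among decoys that are either tiny
  (≤ 4 heavy atoms, too few contacts) or far larger than the cavity (every
  placement carries prohibitive steric overlap). The binder's rank-1 finish
  is a designed property of the fixture, not a tuning outcome.
* **Pose ensembles** place a rigid 5-atom partner at cluster centers a
  controlled separation apart, with translational jitter bounded well below
  the clustering threshold; scores are seeded uniforms with the global best
  forced into a chosen cluster (including clusters other than the largest,
  the adversarial case for the selection rule).
* **Decay series** are y = exp(−ln2·t/t½)·ε with lognormal ε, normalized to
  the t = 0 value as chase data are; time points span [0, 3·t½].

What these fixtures do *not* emulate: real protein folds, backbone
geometry, sidechain chemistry beyond a hydrophobic/polar toggle, receptor
flexibility, tautomers/protomers, or realistic score landscapes. Passing
tests demonstrate the correctness of the algorithms' geometry, contracts
and determinism — not predictive accuracy on real complexes.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is meaningfully
exercised: carved-sphere volume at 0.25–1.6 Å grid spacings; 50-molecule
labeled libraries; a 20-molecule planted-binder screen with funnel sample
counts (50, 200, 600) and keeps (0.5, 0.4, 5); brute-force docking oracles
on a 2 Å-radius site with a 1 Å grid × 24 orientations; 100–1000 seeded
ensembles of ~6–30 poses plus one 100-pose 60/30/10 ensemble; 200 decay
replicates and 200 ratio-coverage trials at 300 bootstrap resamples. The
library defaults (htvs/sp/xp = 200/2000/20000 samples, final keep 10,
ensemble size 5000) are unchanged by any of this.

## Known limitations

* The docking scorer is geometric and rigid-body; no electrostatics,
  desolvation, torsional strain, or receptor flexibility. Scores are
  comparative within a run only.
* Receptor-side H-bond geometry is distance-gated only (no connectivity).
* One conformer per molecule by default; highly flexible ligands are
  under-sampled (a multi-conformer mode is a config away but costs
  linearly).
* The druggability scale is heuristic; only its 6.5 decision threshold is
  conventional.
* The reactive-chemistry screen is structural, not an assay; it cannot see
  reactivity that has no substructure signature.
* Greedy centroid clustering depends on input order only through its
  documented tie-breaks, but it is not a global optimum partition.
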