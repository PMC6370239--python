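# Methods

This note documents the analysis model, the conventions and numerical
choices behind each stage, what the synthetic data generator does and does
not emulate, and the design decisions that were genuinely open.

## The comparison being made

Every protein family contributes structures in two states: apo (no
biologically relevant ligand) and holo (one valid ligand). Three pairing
classes are compared — apo–apo (AA), holo–holo (HH) and apo–holo (AH). AA
and HH measure *inherent* variation: how much structures of the same state
differ from one another through crystallisation conditions, crystal
contacts and thermal motion. AH adds the *induced* component of ligand
binding on top. A per-family statistic (the maximum over pairs, or the mean
range over site residues) keeps heavily crystallised proteins from
dominating the dataset-level comparison; the hypothesis tests then pair
those family values across classes.

## Curation model

* **Families**: structures share a family iff their sets of chain sequences
  are string-identical. An optional merge pass
  (`merge_terminal_extensions`, default off) joins a family into another
  whose sequences contain its own as contiguous substrings — i.e. the
  longer family only adds residues at the termini, the typical
  expression-tag situation. The merge is a deliberate approximation of a
  similarity-clustering step that in practice involves judgment; internal
  insertions or substitutions never merge.
* **Reference numbering**: the best-resolved member (ties: smallest PDB id)
  is the reference. Member chains are aligned to reference chains with a
  Needleman–Wunsch global alignment (match +1, mismatch −1, gap open −10,
  extend −0.5 — Needle-like parameters, nearly moot at 100 % identity) via
  `Bio.Align.PairwiseAligner`; each member chain is assigned to its
  best-scoring reference chain, ties broken by chain-id order. A member is
  discarded (`RENUMBER_FAIL`) if any aligned residue name mismatches the
  reference or two of its chains claim overlapping reference ranges: an
  ambiguous numbering cannot be trusted to address binding-site residues.
* **Holo validity**: resolution ≤ 2.5 Å; exactly one declared ligand
  instance (multi-HET ligands — e.g. peptidic inhibitors split across
  several component codes — count as one instance); no non-water HET heavy
  atom within 4.5 Å of the structure's own contact residues
  (`SITE_CONTAMINATION`).
* **Apo validity**: resolution ≤ 2.5 Å; every non-water HET must have
  molecular weight ≤ 100 Da or appear on the permissible-HET allow-list
  (`HET_DISALLOWED` otherwise); no non-water HET heavy atom within 4.5 Å of
  any unified-site residue heavy atom. Waters are always permitted.
  HET molecular weights come from the bundle's `het_weights.csv` metadata
  table when present, otherwise from the atomic composition of the stored
  heavy atoms with standard atomic weights.
* **Filter order** is fixed: holo filtering → unified site (from accepted
  holo members) → apo filtering → the ≥ 2 apo and ≥ 2 holo survival rule.
  Members of a family that falls below 2+2 are marked `NO_FAMILY` even when
  individually valid.
* **Crystallographic defects**: alternate locations are collapsed to the
  highest-occupancy copy (first-listed on ties) before anything else.
  Hydrogens (and deuteriums) and waters are stripped. Modified amino acids
  inside chains (e.g. selenomethionine) are kept for backbone RMSD but
  excluded from χ1 analysis. Residues with missing coordinates are simply
  absent from pairwise intersections (RMSD) but trigger a *family-wide*
  drop in the χ1 analysis (below).

## Geometry

* **Kabsch superposition** is computed by SVD of the covariance matrix with
  the determinant correction, so the rotation is always proper — a
  mirror-image pair is never "solved" by a reflection. Point sets with
  fewer than 3 atoms or rank < 2 (collinear) are flagged and excluded from
  family maxima rather than scored.
* **Cα RMSD** uses alpha-carbons only (not the full backbone), over the
  intersection of reference indices resolved in both structures. The
  unified-site variant restricts to site residues and by default superposes
  *on the site atoms themselves* (local fit). The fit frame is genuinely
  undetermined by the definition of a site-restricted RMSD; the local fit
  isolates pocket-shape change from whole-body motion, and
  `site_rmsd_fit: global` is available for the alternative
  (global-fit-then-measure) reading.
* **χ1** is the N–CA–CB–γ torsion under the IUPAC sign convention, stored
  in [−180°, 180°). γ is SG (Cys), OG (Ser), OG1 (Thr), CG1 (Ile — the
  longer carbon branch), otherwise CG. Valine is symmetric at γ and
  contributes both CG1 and CG2 angles as two separate observation streams
  (`merge_valine_chi1` pools them; kept separate by default, since the two
  branches are distinct physical substituents that happen to share an
  axis). Gly, Pro and Ala have no χ1.
* **χ1 range** is the smallest circular arc containing all observed
  angles: 360° minus the largest gap between circularly adjacent sorted
  angles. The definition is circular, so {−170°, 170°} spans 20°, not
  340°; a single observation spans 0°.
* **Family-wide χ1 drop**: if any member of a family fails to yield a χ1
  for a site residue (residue unresolved, or a required atom missing), the
  residue is removed from the χ1 analysis for *all* members. Ranges are
  only comparable across sets when every set draws on the same residues.

## SASA

Shrake–Rupley with a 1.4 Å probe and NACCESS-style Chothia radii
(C 1.87, N 1.65, O 1.40, S 1.85, P 1.80, Se 1.90 Å; element-based).
Test points are generated by a deterministic golden-spiral (Fibonacci)
lattice — no RNG, so a given point count always yields the same areas —
with 960 points per atom by default; the isolated-sphere error is < 0.5 %
and the two-sphere occlusion error ≈ 0.3 % against the exact lens formula.
The calculation sees protein heavy atoms only (ligands, waters and other
HET groups are removed first); whole-protein SASA is computed and the
unified-site residues extracted afterwards, so site residues are occluded
by their real protein environment. ΔSASA = max holo site total − min apo
site total: positive when some holo structure exposes more site surface
than the most closed apo structure.

Known numerical caveat: the quadrature grid is fixed in the laboratory
frame, so total SASA is invariant under rigid motion only to grid noise
(≈ 1 % at 960 points); the z-slice algorithm of NACCESS differs from
Shrake–Rupley at a similar magnitude, and exact NACCESS replication is not
attempted.

## Statistics

* **Wilcoxon signed-rank**, two-sided. Zero differences are dropped before
  ranking (Wilcoxon's original treatment; the count is reported). For
  n ≤ 12 surviving pairs the null is enumerated exactly over all 2ⁿ sign
  assignments of the observed (mid-)ranks — ties need no special casing —
  and the p-value is the doubled smaller tail, capped at 1. Above n = 12 a
  normal approximation with tie-corrected variance and a 0.5 continuity
  correction is used. All-zero differences report p = 1 and are flagged
  degenerate.
* **R² screens** are squared Pearson correlations over finite pairs;
  constant inputs yield a missing value, never 0.
* **Jackknife bands**: 1000 resamples without replacement at 90 % of the
  sample size; the 95 % band is the 2.5/97.5 percentile interval of the
  resample statistics. Seeded and reproducible.
* **Amino-acid flexibility classes**: per residue type, the cumulative
  distribution of combined (apo+holo) χ1 ranges over unique binding-site
  residues, with jackknife bands per threshold. At the 40° threshold,
  types whose 95 % bands overlap are chained into groups; with three or
  more distinct groups the labels are relative (most rigid group → rigid,
  most flexible → very flexible, middle → semi-flexible), with fewer
  groups they anchor on the absolute fraction captured at 40° (≥ 0.8
  rigid, ≤ 0.45 very flexible). The chaining rule means classes are a
  partition by statistical indistinguishability, not fixed cutoffs.
* **χ1 occupancy histograms**: each unique residue's angles are binned
  (10° bins over [−180°, 180°)) and normalized to 1, then averaged over
  all residues of the type — every unique residue carries equal weight
  regardless of how many structures its family has.

## Synthetic data

The generator builds idealized chains with standard bond lengths and
angles by natural-extension (NeRF) placement: requested φ/ψ (default an
extended strand, which keeps residues spatially separated so ligand
placement is unambiguous), ω = 180°, side chains complete through the γ
atom(s) at a requested χ1 (default −60°, the most common rotamer).
Controlled deformations:

* **Backbone**: a displacement field of 3 low-frequency sinusoids along
  the chain, applied rigidly per residue and rescaled until the achieved
  Cα RMSD after superposition hits the target within 0.1 %. Per-residue
  rigid displacement leaves intra-residue torsions (hence χ1) untouched.
* **χ1**: rotation of all atoms distal to CB about the CA–CB axis, exact
  to 1e−6°, backbone bitwise unchanged.
* **Ligands**: rigid carbon fragments with one atom per intended contact
  residue, placed at a controlled distance (default 4.2 Å) along the
  outward side-chain direction; a boundary-pair option plants atoms at
  exactly 4.49 Å and 4.51 Å to pin the inclusive-cutoff behaviour. Decoy
  HET groups are planted near the site (contamination) or 30 Å away
  (innocuous), with declared molecular weights.

All coordinates are frozen to PDB file precision (3 decimals) *before* any
ground truth is measured, so the manifest matches what a consumer of the
written bundle can recover exactly. Manifest χ1 ranges are measured with an
independent torsion formula and a brute-force minimal-arc scan; contact
sets with an all-pairs double loop — none of which share code with the
pipeline paths they validate.

Default cohort conditions: 30-residue single-chain families, three apo and
three holo members, 0.3 Å planted backbone RMSD in both states, inherent
χ1 jitter of σ = 8° identically in both states, and a binding-induced
+100° χ1 shift applied to a random half of the site residues in the holo
set only; resolutions ~U(1.4, 2.3) Å and ligand masses ~U(120, 650) g/mol.
These emulate the *statistical shape* the analysis assumes — equal inherent
variation in both states plus an induced apo↔holo displacement — at desk
scale. They do not emulate crystallographic noise, B-factors, real rotamer
distributions, ligand chemistry, or realistic pocket sizes (planted sites
have ~3–5 residues, real unified sites average ~21), so passing tests
demonstrate correctness of the measurement machinery and the direction of
the statistical pattern, not field-realistic effect sizes.

## Problem sizes

The test suite and the acceptance script run on cohorts of 2–10 families
of six 30–32-residue structures, 960 SASA points per atom, 10⁴-set oracle
sweeps and exact Wilcoxon enumeration to n = 10; a full run of everything
takes a few minutes on one CPU. Dataset-scale benchmarks (hundreds of
families from public structures) use the same code paths unchanged; only
the bundle differs.

## Known limitations

* Biological assemblies are taken as given in the input file; symmetry
  expansion is not performed, and the first model containing the declared
  ligand is used for multi-model files.
* No mmCIF input; fixed-column PDB only.
* The terminal-extension family merge is a stated approximation of a
  judgment-based similarity merge.
* χ2+ torsions, rotamer-library classification and φ/ψ analyses are out of
  scope by design; χ1 carries the dominant side-chain signal but misses
  distal-only motions.
* Relative (percent) accessibility and interface decompositions are not
  computed.
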