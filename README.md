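# apoholo

Quantifying how ligand binding changes protein flexibility, by comparing
crystal structures of the same protein solved with a ligand (*holo*) and
without one (*apo*).

Structure-based drug design has to decide how much protein flexibility to
model. The key question is not just "do structures move between apo and
holo?" but "do they move *more* between apo and holo than they already vary
within each state?" — induced change only means something against the
baseline of inherent variation. `apoholo` implements that comparison for
cohorts of protein families (sets of sequence-identical structures with at
least two apo and two holo members each):

* **Curation** — families are clustered at 100 % sequence identity, every
  member is renumbered onto a shared reference by global alignment, and
  validity filters are applied: resolution ≤ 2.5 Å; holo structures must
  contain exactly one valid ligand and no foreign molecules in the pocket;
  apo structures may carry only waters and innocuous HET groups (molecular
  weight ≤ 100 Da or on an allow-list), none of them within 4.5 Å of the
  binding site.
* **Unified binding sites** — the union of all residues within 4.5 Å
  (heavy atoms only, inclusive) of *any* ligand across *all* holo members,
  so apo structures can be scored on a site they do not themselves define.
* **Backbone flexibility** — for every structure pair in a family, the Cα
  RMSD after optimal (Kabsch) superposition; each family is summarised by
  its *maximum* RMSD per pairing class (apo–apo, holo–holo, apo–holo), over
  the whole chain and over the unified site.
* **Side-chain flexibility** — per binding-site residue, the χ1 torsion
  (N–CA–CB–γ; valine contributes both branches, isoleucine uses the longer
  chain) across all structures of a set, summarised as the *minimal
  circular range*: the smallest arc containing every observed angle, e.g.
  {30°, 45°, 100°} → 70°. Ranges are compared across the apo set, the holo
  set and the combined apo+holo set.
* **SASA** — Shrake–Rupley solvent accessible surface area of the
  unified-site residues (1.4 Å probe, NACCESS-style radii), with the family
  statistic ΔSASA = max holo site SASA − min apo site SASA.
* **Statistics** — one value per family; Wilcoxon signed-rank tests (exact
  for small samples) between sets, R² screens against ligand mass and
  resolution, delete-10 % jackknife confidence bands, per-amino-acid
  cumulative flexibility curves with rigid / semi-flexible / very-flexible
  classes at a 40° threshold.

A synthetic-structure generator (`apoholo.synthetic`) builds idealized
polypeptide families with exactly known ground truth — planted backbone
RMSDs, planted χ1 settings, ligands placed at controlled contact distances,
decoy HET groups — so the full pipeline is testable end-to-end without any
downloads.

## Worked example

```bash
apoholo generate --out bundle --families 3 --seed 5
apoholo run --in bundle --out report --seed 5
python - <<'EOF'
import json
stats = json.load(open("report/stats.json"))
print({k: round(v["p"], 4) for k, v in stats["wilcoxon"].items()})
print({k: round(v, 1) for k, v in stats["median_of_mean_chi1_ranges"].items()})
EOF
```

prints (seed 5):

```
{'chi1_apo_vs_holo': 0.75, 'chi1_combined_vs_apo': 0.25, 'chi1_combined_vs_holo': 0.25,
 'rmsd_apo_vs_holo': 0.75, 'rmsd_apoholo_vs_apo': 0.25, 'rmsd_apoholo_vs_holo': 0.25}
{'apo': 15.4, 'apo_holo': 50.9, 'holo': 13.0}
```

Read: within each state the binding-site side chains vary by ~13–15° of χ1
(inherent variation, apo vs holo not distinguishable), but pooling apo and
holo structures widens the median range to ~51° — ligand binding pushed
side chains into orientations never seen within either state alone. With
only three families the exact Wilcoxon p-values cannot drop below 0.25;
on larger cohorts (≥ 9 families, e.g. `--families 10`) the combined-vs-
single-set comparison reaches p < 0.01 while apo-vs-holo stays
non-significant.

The `report/` directory also contains `decisions.csv` (every curation
verdict with rule codes), `unified_sites.csv`, `pairs.csv` (all pairwise
RMSDs), `chi1_angles.csv` / `chi1_ranges.csv`, `sasa.csv`, `profiles.csv`
(per-amino-acid cumulative curves with jackknife bands) and `summaries.csv`
(one row per family).

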