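"""End-to-end orchestration: input bundle -> curated families -> metrics ->
statistics -> report bundle.

The stage order is fixed: holo filtering, unified sites, apo filtering,
geometry/SASA metrics, statistics.  Every stage is deterministic for a fixed
config and input bundle; outputs are sorted before writing so reruns are
byte-identical.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .binding_site import UnifiedSite
from .config import RunConfig
from .curation import Family, curate_cohort
from .geometry import family_max, family_pair_scores, family_range_stats, site_chi1_tables
from .sasa import family_sasa_summary, structure_sasa
from .structure import LigandSpec, parse_structure, resolve_altlocs, strip_for_analysis

__all__ = ["load_bundle", "load_allowlist", "analyze_families", "run"]


def load_allowlist(path: str | Path) -> set[str]:
    df = pd.read_csv(path)
    return set(df["component_code"].astype(str))


def load_bundle(indir: str | Path):
    """Read an input bundle (pdb/ dir + index.csv + ligands.csv + allowlist.csv)
    into stripped, altloc-resolved StructureRecords grouped by declared family."""
    indir = Path(indir)
    index = pd.read_csv(indir / "index.csv")
    lig_path = indir / "ligands.csv"
    lig_specs: dict[str, list[LigandSpec]] = {}
    if lig_path.exists():
        lig_df = pd.read_csv(lig_path)
        for (pdb_id, inst), grp in lig_df.groupby(["pdb_id", "instance_id"]):
            mw = grp["mol_weight"].dropna()
            lig_specs.setdefault(str(pdb_id), []).append(LigandSpec(
                str(inst),
                [(str(r.component_code), str(r.chain_id), int(r.auth_seq))
                 for r in grp.itertuples()],
                float(mw.iloc[0]) if len(mw) else None))
    # HET metadata: molecular weights by component code (PDB files carry
    # none); absent entries fall back to atomic-composition weights
    het_w: dict[str, float] = {}
    hw_path = indir / "het_weights.csv"
    if hw_path.exists():
        hw = pd.read_csv(hw_path)
        het_w = dict(zip(hw["component_code"].astype(str),
                         hw["mol_weight"].astype(float)))
    structures = []
    declared_families = {}
    for row in index.itertuples():
        pdb_id = str(row.pdb_id)
        text = (indir / "pdb" / f"{pdb_id}.pdb").read_text()
        s = parse_structure(text, str(row.role), pdb_id=pdb_id,
                            resolution=float(row.resolution)
                            if "resolution" in index.columns else None,
                            ligand_specs=lig_specs.get(pdb_id, []))
        resolve_altlocs(s)
        strip_for_analysis(s)
        for het in s.hets:
            if het.component_code in het_w:
                het.mol_weight = het_w[het.component_code]
        structures.append(s)
        declared_families[pdb_id] = str(row.family_id)
    return structures, declared_families


def analyze_families(families: list[Family], config: RunConfig) -> dict:
    """Per-family metrics: pair RMSDs, chi1 tables/ranges, SASA, summaries."""
    pair_rows, chi1_rows, range_rows, sasa_rows, dropped_rows = [], [], [], [], []
    summaries: list[st.FamilySummary] = []
    for fam in sorted(families, key=lambda f: f.family_id):
        site: UnifiedSite = fam.unified_site
        site_ids = site.residue_ids if site else set()

        scores = family_pair_scores(fam.members, site_ids, config.site_rmsd_fit)
        for sc in scores:
            pair_rows.append({
                "family_id": fam.family_id, "pdb_a": sc.pdb_a, "pdb_b": sc.pdb_b,
                "pairing_class": sc.pairing_class, "rmsd_global": sc.rmsd_global,
                "rmsd_site": sc.rmsd_site, "n_atoms_global": sc.n_atoms_global,
                "n_atoms_site": sc.n_atoms_site, "flagged": sc.flagged})

        records, rsummaries, dropped = site_chi1_tables(
            fam.family_id, fam.members, site_ids, config.merge_valine_chi1)
        for r in records:
            chi1_rows.append(vars(r).copy())
        for r in rsummaries:
            range_rows.append(vars(r).copy())
        for ch, idx, reason in dropped:
            dropped_rows.append({"family_id": fam.family_id, "ref_chain": ch,
                                 "ref_index": idx, "reason": reason})

        srecords = [structure_sasa(m, site_ids, config.probe_radius,
                                   config.sasa_points) for m in fam.members]
        fam_sasa = family_sasa_summary(srecords)
        for rec in srecords:
            sasa_rows.append({"family_id": fam.family_id, "pdb_id": rec.pdb_id,
                              "role": rec.role, "site_sasa": rec.site_total})

        summ = st.FamilySummary(fam.family_id, fam.n_apo, fam.n_holo)
        summ.site_size = site.size if site else 0
        for pc in st.PAIRING_CLASSES:
            for metric, store_max, store_mean, store_med in (
                    ("rmsd_global", summ.max_rmsd, summ.mean_rmsd, summ.median_rmsd),
                    ("rmsd_site", summ.max_rmsd_site, summ.mean_rmsd_site,
                     summ.median_rmsd_site)):
                vals = [getattr(sc, metric) for sc in scores
                        if sc.pairing_class == pc and getattr(sc, metric) is not None]
                if vals:
                    store_max[pc] = float(max(vals))
                    store_mean[pc] = float(np.mean(vals))
                    store_med[pc] = float(np.median(vals))
        rstats = family_range_stats(rsummaries)
        for lbl, d in rstats.items():
            summ.max_chi1_range[lbl] = d["max"]
            summ.mean_chi1_range[lbl] = d["mean"]
        summ.sasa = {k: v for k, v in fam_sasa.items() if k in ("apo", "holo")}
        summ.delta_sasa = fam_sasa.get("delta_sasa")
        masses = [m.ligand.mol_weight for m in fam.members_by_role("holo")
                  if m.ligand is not None]
        summ.mean_ligand_mass = float(np.mean(masses)) if masses else None
        for role in ("apo", "holo"):
            res = [m.resolution for m in fam.members_by_role(role)]
            if res:
                summ.mean_resolution[role] = float(np.mean(res))
        summaries.append(summ)

    return {
        "summaries": summaries,
        "pair_rows": pd.DataFrame(pair_rows),
        "chi1_rows": pd.DataFrame(chi1_rows),
        "range_rows": pd.DataFrame(range_rows),
        "sasa_rows": pd.DataFrame(sasa_rows),
        "dropped_rows": pd.DataFrame(dropped_rows),
    }


def dataset_statistics(table: pd.DataFrame, metrics: dict, config: RunConfig) -> dict:
    """Dataset-level tests and screens over the per-family table."""
    out: dict = {}
    for prefix, label in (("max_rmsd", "backbone"), ("max_rmsd_site", "site")):
        ds = st.dataset_stats(table, prefix)
        out[f"{label}_rmsd_table"] = ds.to_dict(orient="records")

    def paired(col_a, col_b):
        sub = table[[col_a, col_b]].dropna()
        return list(zip(sub[col_a], sub[col_b]))

    tests = {}
    comparisons = {
        "rmsd_apo_vs_holo": ("max_rmsd_AA", "max_rmsd_HH"),
        "rmsd_apoholo_vs_apo": ("max_rmsd_AH", "max_rmsd_AA"),
        "rmsd_apoholo_vs_holo": ("max_rmsd_AH", "max_rmsd_HH"),
        "chi1_apo_vs_holo": ("mean_chi1_range_apo", "mean_chi1_range_holo"),
        "chi1_combined_vs_apo": ("mean_chi1_range_apo_holo", "mean_chi1_range_apo"),
        "chi1_combined_vs_holo": ("mean_chi1_range_apo_holo", "mean_chi1_range_holo"),
    }
    for name, (ca, cb) in comparisons.items():
        if ca not in table or cb not in table:
            continue
        pairs = paired(ca, cb)
        if not pairs:
            continue
        w, p, meta = st.wilcoxon_signed_rank(pairs)
        tests[name] = {"W_plus": w, "p": p, **meta}
    out["wilcoxon"] = tests

    screens = {}
    for metric in ("max_rmsd_AH", "mean_chi1_range_apo_holo"):
        if metric not in table:
            continue
        for covar in ("mean_ligand_mass", "mean_resolution_holo"):
            if covar not in table:
                continue
            sub = table[[metric, covar]].dropna()
            r2 = st.r_squared(sub[metric], sub[covar]) if len(sub) else float("nan")
            screens[f"{metric}__vs__{covar}"] = None if np.isnan(r2) else r2
    out["r_squared_screens"] = screens

    medians = {}
    for lbl in st.SET_LABELS:
        col = f"mean_chi1_range_{lbl}"
        if col in table and table[col].notna().any():
            medians[lbl] = float(table[col].median())
    out["median_of_mean_chi1_ranges"] = medians

    if "delta_sasa" in table and table["delta_sasa"].notna().any():
        ds = table["delta_sasa"].dropna()
        out["delta_sasa"] = {
            "fraction_le_100": float((ds <= 100.0).mean()),
            "fraction_negative": float((ds < 0.0).mean()),
            "median": float(ds.median()),
        }
    if "site_size" in table and len(table):
        out["unified_site_size"] = {"mean": float(table["site_size"].mean()),
                                    "std": float(table["site_size"].std(ddof=0))}
    return out


def run(indir: str | Path, outdir: str | Path,
        config: RunConfig | None = None) -> dict:
    """Execute the full pipeline on an input bundle and write the report
    bundle.  Returns the in-memory results (families, tables, stats)."""
    cfg = config or RunConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    structures, _ = load_bundle(indir)
    allowlist = load_allowlist(Path(indir) / "allowlist.csv") \
        if (Path(indir) / "allowlist.csv").exists() else set()
    families, decisions = curate_cohort(structures, allowlist, cfg)

    with open(out / "decisions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pdb_id", "role", "family_id", "accepted", "reasons"])
        for d in sorted(decisions, key=lambda d: (d.family_id, d.pdb_id)):
            w.writerow([d.pdb_id, d.role, d.family_id, int(d.accepted),
                        ";".join(d.reasons)])

    site_rows = []
    for fam in sorted(families, key=lambda f: f.family_id):
        for (ch, idx) in fam.unified_site.sorted_ids():
            site_rows.append({"family_id": fam.family_id, "ref_chain": ch,
                              "ref_index": idx,
                              "residue_name": fam.unified_site.residue_names.get((ch, idx), "")})
    pd.DataFrame(site_rows).to_csv(out / "unified_sites.csv", index=False)

    metrics = analyze_families(families, cfg)
    table = st.aggregate(metrics["summaries"])
    stats = dataset_statistics(table, metrics, cfg)
    stats["n_families"] = len(families)
    stats["n_structures"] = int(sum(len(f.members) for f in families))
    stats["seed"] = cfg.seed
    stats["config_hash"] = cfg.config_hash

    range_rows = metrics["range_rows"]
    profiles = {}
    if not range_rows.empty:
        combined = range_rows[(range_rows.set_label == "apo_holo")
                              & (range_rows.which.isin(["primary", "merged"]))]
        profiles = st.amino_acid_profiles(
            combined.rename(columns={"res_name": "res_name"}),
            classify_at=cfg.flex_threshold,
            n_resamples=cfg.jackknife_resamples,
            keep_fraction=cfg.jackknife_fraction,
            seed=cfg.seed)
        stats["flexibility_classes"] = {
            name: p.flexibility_class for name, p in sorted(profiles.items())}

    bins = pd.DataFrame()
    if not metrics["chi1_rows"].empty:
        bins = st.bin_chi1(metrics["chi1_rows"], cfg.bin_width)
        bins.to_csv(out / "chi1_bins.csv", index=False, float_format="%.6f")

    st.make_reports(out, table, metrics["pair_rows"], metrics["chi1_rows"],
                    range_rows, metrics["sasa_rows"], profiles, stats,
                    cfg.to_dict())
    cfg.save(out / "config.json")
    return {"families": families, "decisions": decisions, "table": table,
            "stats": stats, **metrics}
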