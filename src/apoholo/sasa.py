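"""Shrake-Rupley solvent accessible surface area of unified-site residues.

SASA is computed for the stripped protein only (no hydrogens, waters, ligands
or other HET groups), with a 1.4 A probe and NACCESS-style Chothia van der
Waals radii.  Test points are placed by a deterministic golden-spiral
construction, so results are exactly reproducible for a fixed point count.
The family statistic is dSASA = (maximum holo site SASA) - (minimum apo site
SASA): positive when ligand binding is accompanied by a more open pocket
somewhere in the holo set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureRecord

__all__ = ["SasaRecord", "shrake_rupley", "structure_sasa",
           "family_sasa_summary", "VDW_RADII", "PROBE_RADIUS"]

PROBE_RADIUS = 1.4  # A, water probe (NACCESS default)
DEFAULT_N_POINTS = 960

# Chothia radii as used by NACCESS (A); element-based assignment.
VDW_RADII = {
    "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85,
    "P": 1.80, "SE": 1.90,
}


@dataclass
class SasaRecord:
    pdb_id: str
    role: str
    per_residue: dict[tuple[str, int], float] = field(default_factory=dict)
    site_total: float = 0.0


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (deterministic Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    xyz: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area (A^2).

    For each atom, ``n_points`` test points on its expanded sphere
    (radius + probe) are tested for occlusion by every neighbouring expanded
    sphere; the accessible fraction times the expanded-sphere area is the
    atom's SASA.
    """
    xyz = np.asarray(xyz, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = xyz.shape[0]
    if n_atoms == 0:
        return np.zeros(0)
    expanded = radii + probe
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(xyz)
    max_r = float(expanded.max())
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        ri = expanded[i]
        pts = xyz[i] + ri * sphere
        # any neighbour within ri + max_r could occlude a test point
        nbrs = [j for j in tree.query_ball_point(xyz[i], ri + max_r) if j != i]
        if nbrs:
            nxyz = xyz[nbrs]
            nr = expanded[np.asarray(nbrs)]
            d2 = ((pts[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr * nr)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ri * ri
    return areas


def _atom_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise ValueError(f"no van der Waals radius for element {element!r}") from None


def structure_sasa(
    s: StructureRecord,
    site_ids: set[tuple[str, int]] | None = None,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaRecord:
    """Whole-protein SASA, then the unified-site residues are extracted.

    Only protein-chain heavy atoms enter the calculation (the structure must
    already be stripped of hydrogens, waters, ligands; remaining HET groups
    are ignored here).  ``site_total`` sums per-residue SASA over site
    residues resolved in this structure.
    """
    atoms = []
    owners = []
    for res in s.residues():
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            atoms.append(a)
            owners.append(res)
    if not atoms:
        return SasaRecord(s.pdb_id, s.role)
    xyz = np.array([a.position for a in atoms])
    radii = np.array([_atom_radius(a.element) for a in atoms])
    areas = shrake_rupley(xyz, radii, probe, n_points)

    per_res: dict[tuple[str, int], float] = {}
    for area, res in zip(areas, owners):
        if res.ref_index is None:
            continue
        rid = (res.ref_chain, res.ref_index)
        per_res[rid] = per_res.get(rid, 0.0) + float(area)
    rec = SasaRecord(s.pdb_id, s.role)
    if site_ids is not None:
        rec.per_residue = {k: v for k, v in per_res.items() if k in site_ids}
    else:
        rec.per_residue = per_res
    rec.site_total = float(sum(rec.per_residue.values()))
    return rec


def family_sasa_summary(records: list[SasaRecord]) -> dict:
    """Median/min/max site SASA per role and dSASA = max(holo) - min(apo)."""
    out: dict = {}
    for role in ("apo", "holo"):
        totals = sorted(r.site_total for r in records if r.role == role)
        if totals:
            out[role] = {
                "median": float(np.median(totals)),
                "min": float(min(totals)),
                "max": float(max(totals)),
                "n": len(totals),
            }
    if "apo" in out and "holo" in out:
        out["delta_sasa"] = out["holo"]["max"] - out["apo"]["min"]
    return out
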