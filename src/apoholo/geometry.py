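"""Superposition RMSD and side-chain chi1 dihedral statistics.

The two flexibility metrics of the analysis live here: least-squares (Kabsch)
Calpha superposition RMSD between structure pairs, and the minimal circular
range of chi1 angles observed for a binding-site residue across a structure
set.  Conventions:

* chi1 = dihedral N-CA-CB-G, where G is SG (Cys), OG (Ser), OG1 (Thr),
  CG1 (Ile, the longer carbon branch) and CG otherwise.  Valine is symmetric
  at the gamma position and contributes both CG1 and CG2 angles.  Gly, Pro
  and Ala have no chi1.
* Angles live in [-180, 180) degrees; ranges in [0, 360).
* A chi1 range is the smallest circular arc containing every observed angle,
  i.e. 360 minus the largest gap between circularly adjacent angles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .structure import Residue, StructureRecord

__all__ = [
    "PairScore",
    "Chi1Record",
    "RangeSummary",
    "kabsch",
    "dihedral",
    "chi1_of_residue",
    "chi1_range",
    "ca_rmsd",
    "family_pair_scores",
    "family_max",
    "site_chi1_tables",
    "CHI1_GAMMA_ATOM",
    "NO_CHI1",
]

NO_CHI1 = {"GLY", "PRO", "ALA"}
# gamma atom defining chi1 per residue type; Val handled specially (both).
CHI1_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "SER": "OG", "THR": "OG1", "TRP": "CG",
    "TYR": "CG",
}


class DegenerateGeometry(ValueError):
    """Point set unsuitable for superposition or torsion measurement."""


# ---------------------------------------------------------------------------
# superposition

def kabsch(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of Y onto X.

    Returns ``(R, t, rmsd)`` with the proper rotation R (det = +1) and
    translation t minimising ``||X - (Y @ R.T + t)||`` in the least-squares
    sense, and the resulting root-mean-square deviation.

    Parameters are N x 3 coordinate arrays with fixed row correspondence,
    N >= 3.  Collinear/degenerate sets raise :class:`DegenerateGeometry`.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("kabsch expects matching N x 3 arrays")
    n = X.shape[0]
    if n < 3:
        raise DegenerateGeometry(f"need >= 3 points, got {n}")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    X0 = X - xc
    Y0 = Y - yc
    # rank < 2 means all points (nearly) collinear: rotation underdetermined
    if np.linalg.matrix_rank(X0, tol=1e-8) < 2 or np.linalg.matrix_rank(Y0, tol=1e-8) < 2:
        raise DegenerateGeometry("collinear point set")
    H = Y0.T @ X0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = xc - R @ yc
    diff = X - (Y @ R.T + t)
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# torsions

def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Looking from p2 towards p3, a clockwise rotation of p4 relative to p1 is
    positive.  Result lies in [-180, 180).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) < 1e-9 or np.linalg.norm(b2) < 1e-9 or np.linalg.norm(b3) < 1e-9:
        raise DegenerateGeometry("coincident consecutive points in torsion")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = -np.degrees(np.arctan2(y, x))
    # map +180 to -180 so the domain is the half-open interval
    if ang >= 180.0 - 1e-12:
        ang -= 360.0
    return float(ang)


def chi1_of_residue(r: Residue) -> list[tuple[str, float]]:
    """chi1 angle(s) of one residue as ``(which, degrees)`` records.

    ``which`` is ``"primary"`` for the standard gamma atom and
    ``"valine_alt"`` for valine's second branch (CG2).  Residues without a
    defined chi1 return an empty list; a residue *with* a defined chi1 whose
    required atoms are missing raises KeyError (callers use this to trigger
    the family-wide drop rule).
    """
    if r.name in NO_CHI1:
        return []
    if r.name == "VAL":
        gammas = [("primary", "CG1"), ("valine_alt", "CG2")]
    elif r.name in CHI1_GAMMA_ATOM:
        gammas = [("primary", CHI1_GAMMA_ATOM[r.name])]
    else:
        return []  # modified residues (e.g. MSE): not part of chi1 analysis
    n, ca, cb = r.atom("N"), r.atom("CA"), r.atom("CB")
    out = []
    for which, gname in gammas:
        g = r.atom(gname)
        if n is None or ca is None or cb is None or g is None:
            missing = [nm for nm, at in
                       (("N", n), ("CA", ca), ("CB", cb), (gname, g)) if at is None]
            raise KeyError(
                f"{r.chain_id}{r.auth_seq}{r.icode} {r.name}: chi1 atoms "
                f"missing: {','.join(missing)}"
            )
        out.append((which, dihedral(n.position, ca.position, cb.position,
                                    g.position)))
    return out


def chi1_range(angles) -> float:
    """Smallest circular arc (degrees, in [0, 360)) containing all angles.

    Computed as 360 minus the largest gap between circularly adjacent sorted
    angles; e.g. {30, 45, 100} -> 70.
    """
    a = np.asarray(list(angles), dtype=float)
    if a.size == 0:
        raise ValueError("chi1_range of empty angle set")
    if a.size == 1:
        return 0.0
    a = np.sort(np.mod(a, 360.0))
    gaps = np.diff(a)
    wrap = 360.0 - a[-1] + a[0]
    largest = max(float(gaps.max()) if gaps.size else 0.0, float(wrap))
    return float(360.0 - largest)


# ---------------------------------------------------------------------------
# family-level RMSD

@dataclass
class PairScore:
    pdb_a: str
    pdb_b: str
    pairing_class: str  # "AA" | "HH" | "AH"
    rmsd_global: float | None
    rmsd_site: float | None
    n_atoms_global: int
    n_atoms_site: int
    flagged: bool = False


def _ca_map(s: StructureRecord) -> dict[tuple[str, int], np.ndarray]:
    """Map (ref_chain, ref_index) -> Calpha position for numbered residues."""
    out = {}
    for res in s.residues():
        if res.ref_index is None:
            continue
        ca = res.atom("CA")
        if ca is not None:
            out[(res.ref_chain, res.ref_index)] = ca.position
    return out


def ca_rmsd(
    a: StructureRecord,
    b: StructureRecord,
    selection: str = "all",
    site_ids: set[tuple[str, int]] | None = None,
    site_fit: str = "local",
) -> tuple[float | None, int]:
    """Calpha RMSD between two family members after optimal superposition.

    Uses the intersection of reference indices resolved with a Calpha in both
    structures.  ``selection="unified_site"`` restricts to ``site_ids``;
    ``site_fit="local"`` superposes on the site atoms themselves, ``"global"``
    fits on all shared Calpha and measures over the site.  Returns
    ``(rmsd, n_atoms)``; fewer than 3 shared atoms yields ``(None, n)``
    (flagged, excluded from family maxima).
    """
    ma, mb = _ca_map(a), _ca_map(b)
    shared = sorted(set(ma) & set(mb))
    if selection == "unified_site":
        if site_ids is None:
            raise ValueError("unified_site selection requires site_ids")
        sel = [k for k in shared if k in site_ids]
    else:
        sel = shared
    if len(sel) < 3:
        return None, len(sel)
    X = np.array([ma[k] for k in sel])
    Y = np.array([mb[k] for k in sel])
    if selection == "unified_site" and site_fit == "global":
        Xf = np.array([ma[k] for k in shared])
        Yf = np.array([mb[k] for k in shared])
        try:
            R, t, _ = kabsch(Xf, Yf)
        except DegenerateGeometry:
            return None, len(sel)
        diff = X - (Y @ R.T + t)
        return float(np.sqrt((diff * diff).sum() / len(sel))), len(sel)
    try:
        _, _, rmsd = kabsch(X, Y)
    except DegenerateGeometry:
        return None, len(sel)
    return rmsd, len(sel)


def _pairing_class(role_a: str, role_b: str) -> str:
    if role_a == role_b:
        return "AA" if role_a == "apo" else "HH"
    return "AH"


def family_pair_scores(
    members: list[StructureRecord],
    site_ids: set[tuple[str, int]] | None = None,
    site_fit: str = "local",
) -> list[PairScore]:
    """Score every unordered member pair (global and binding-site RMSD)."""
    scores = []
    for a, b in itertools.combinations(sorted(members, key=lambda s: s.pdb_id), 2):
        g, ng = ca_rmsd(a, b, "all")
        if site_ids is not None:
            s_, ns = ca_rmsd(a, b, "unified_site", site_ids, site_fit)
        else:
            s_, ns = None, 0
        scores.append(PairScore(a.pdb_id, b.pdb_id, _pairing_class(a.role, b.role),
                                g, s_, ng, ns,
                                flagged=(g is None)))
    return scores


def family_max(scores: list[PairScore], pairing_class: str,
               metric: str = "rmsd_global") -> float | None:
    """Maximum RMSD over one pairing class; None when no valid pair exists."""
    vals = [getattr(s, metric) for s in scores
            if s.pairing_class == pairing_class and getattr(s, metric) is not None]
    return max(vals) if vals else None


# ---------------------------------------------------------------------------
# chi1 tables

@dataclass
class Chi1Record:
    family_id: str
    ref_chain: str
    ref_index: int
    res_name: str
    pdb_id: str
    role: str
    which: str  # "primary" | "valine_alt"
    chi1: float


@dataclass
class RangeSummary:
    family_id: str
    ref_chain: str
    ref_index: int
    res_name: str
    which: str
    set_label: str  # "apo" | "holo" | "apo_holo"
    range: float
    n_observations: int


def site_chi1_tables(
    family_id: str,
    members: list[StructureRecord],
    site_ids: set[tuple[str, int]],
    merge_valine: bool = False,
) -> tuple[list[Chi1Record], list[RangeSummary], list[tuple]]:
    """chi1 angles and minimal circular ranges for unified-site residues.

    For each site residue with a defined chi1, angles are collected across all
    members; if any member fails to provide a computable chi1 for that residue
    (residue unresolved or required atoms missing) the residue is dropped from
    the chi1 analysis for the whole family.  Ranges are reported per structure
    set (apo, holo, apo+holo); valine's two branches are kept as separate
    observation streams unless ``merge_valine``.

    Returns ``(records, summaries, dropped)`` where dropped lists
    ``(ref_chain, ref_index, reason)``.
    """
    members = sorted(members, key=lambda s: s.pdb_id)
    # residue name per site id, from whichever member resolves it
    site_name: dict[tuple[str, int], str] = {}
    inverse: dict[str, dict[tuple[str, int], Residue]] = {}
    for m in members:
        inv = {}
        for res in m.residues():
            if res.ref_index is not None:
                inv[(res.ref_chain, res.ref_index)] = res
        inverse[m.pdb_id] = inv
        for k in site_ids:
            if k in inv and k not in site_name:
                site_name[k] = inv[k].name

    records: list[Chi1Record] = []
    dropped: list[tuple] = []
    per_residue: dict[tuple, list[Chi1Record]] = {}
    for k in sorted(site_ids):
        name = site_name.get(k)
        if name is None or name in NO_CHI1 or (
                name != "VAL" and name not in CHI1_GAMMA_ATOM):
            continue  # no chi1 defined for this residue type
        angle_rows = []
        drop_reason = None
        for m in members:
            res = inverse[m.pdb_id].get(k)
            if res is None:
                drop_reason = f"unresolved in {m.pdb_id}"
                break
            try:
                angles = chi1_of_residue(res)
            except KeyError as exc:
                drop_reason = f"missing atoms in {m.pdb_id}: {exc}"
                break
            for which, ang in angles:
                angle_rows.append(Chi1Record(family_id, k[0], k[1], name,
                                             m.pdb_id, m.role, which, ang))
        if drop_reason is not None:
            dropped.append((k[0], k[1], drop_reason))
            continue
        records.extend(angle_rows)
        for rec in angle_rows:
            which = "merged" if merge_valine else rec.which
            per_residue.setdefault((k, rec.res_name, which), []).append(rec)

    summaries: list[RangeSummary] = []
    for (k, name, which), recs in sorted(per_residue.items(),
                                         key=lambda kv: (kv[0][0], kv[0][2])):
        for set_label, roles in (("apo", {"apo"}), ("holo", {"holo"}),
                                 ("apo_holo", {"apo", "holo"})):
            angles = [r.chi1 for r in recs if r.role in roles]
            if not angles:
                continue
            summaries.append(RangeSummary(family_id, k[0], k[1], name, which,
                                          set_label, chi1_range(angles),
                                          len(angles)))
    return records, summaries, dropped


def family_range_stats(summaries: list[RangeSummary]) -> dict[str, dict[str, float]]:
    """Per-set max and mean chi1 range over a family's site residues."""
    out: dict[str, dict[str, float]] = {}
    for set_label in ("apo", "holo", "apo_holo"):
        vals = [s.range for s in summaries if s.set_label == set_label]
        if vals:
            out[set_label] = {"max": float(max(vals)),
                              "mean": float(np.mean(vals)),
                              "n_residues": len(vals)}
    return out
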