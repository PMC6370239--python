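"""Synthetic structure families with exactly known ground truth.

Every pipeline stage is testable without downloads: this module builds
idealized polypeptide chains (standard bond lengths/angles, requested
backbone and chi1 torsions), perturbs backbones by a smooth low-frequency
displacement field rescaled to an exact target Calpha RMSD, places rigid
ligand fragments at controlled distances from chosen contact residues, plants
decoy HET groups, and writes the same input bundle the pipeline consumes
(PDB files + index/ligand/allow-list CSVs) next to a manifest recording the
planted truth: expected curation decisions, unified-site membership, pairwise
RMSDs and per-set chi1 ranges.

The fixtures emulate the statistical shape of the real cohorts — families
with at least two apo and two holo members, inherent backbone variation of a
few tenths of an Angstrom within each set, and binding-induced side-chain
displacements — not crystallographic noise or ligand chemistry.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import geometry
from .structure import (Atom, HetRecord, LigandSpec, Residue, StructureRecord,
                        THREE_TO_ONE, write_pdb)

__all__ = [
    "FamilyFixtureSpec",
    "FamilyFixture",
    "make_ideal_chain",
    "set_chi1",
    "perturb_backbone",
    "make_family",
    "make_cohort",
    "write_bundle",
]

# backbone geometry (Engh-Huber-like averages)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB = 111.2, 116.2, 121.7, 120.5, 110.4
T_N_C_CA_CB = 122.6  # improper fixing L-chirality of CB
OMEGA = 180.0

# gamma-atom build parameters: name, bond from CB, CA-CB-G angle
GAMMA_BUILD = {
    "SER": ("OG", 1.417, 110.8), "CYS": ("SG", 1.808, 113.8),
    "THR": ("OG1", 1.433, 109.6), "ILE": ("CG1", 1.530, 110.4),
    "VAL": ("CG1", 1.527, 110.5), "ARG": ("CG", 1.520, 113.8),
    "ASN": ("CG", 1.516, 112.6), "ASP": ("CG", 1.516, 112.6),
    "GLN": ("CG", 1.520, 113.8), "GLU": ("CG", 1.520, 113.8),
    "HIS": ("CG", 1.497, 113.8), "LEU": ("CG", 1.530, 116.3),
    "LYS": ("CG", 1.520, 113.8), "MET": ("CG", 1.520, 113.8),
    "PHE": ("CG", 1.502, 113.8), "TRP": ("CG", 1.498, 113.6),
    "TYR": ("CG", 1.512, 113.8),
}
# second gamma branch (exactly +/-120 deg from the primary chi1)
SECOND_GAMMA = {"VAL": ("CG2", 1.527, 110.5, +120.0),
                "ILE": ("CG2", 1.521, 110.5, -120.0),
                "THR": ("CG2", 1.521, 110.5, -120.0)}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement: the returned point d satisfies
    |cd| = bond, angle(b,c,d) = angle_deg and dihedral(a,b,c,d) = torsion_deg
    under the package's torsion convention."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_ideal_chain(
    sequence: str,
    phi: float = -120.0,
    psi: float = 120.0,
    chi1: float = -60.0,
    chain_id: str = "A",
    start_seq: int = 1,
    pdb_id: str = "synt",
    resolution: float = 1.5,
    role: str = "apo",
) -> StructureRecord:
    """Build an idealized chain with the requested backbone torsions.

    Side chains are minimal but chi1-complete: CB plus the gamma atom(s), all
    built at the requested chi1 (default -60, the most common rotamer).  The
    default (phi, psi) is an extended strand, which keeps residues spatially
    separated and makes controlled ligand placement unambiguous.
    """
    seq3 = [ONE_TO_THREE[c] for c in sequence]
    n_prev = np.array([0.0, 0.0, 0.0])
    ca_prev = np.array([B_N_CA, 0.0, 0.0])
    c_prev = place_atom(np.array([0.0, 0.0, 1.0]), n_prev, ca_prev,
                        B_CA_C, A_N_CA_C, 37.0)  # arbitrary frame for residue 1
    residues: list[Residue] = []
    for i, name in enumerate(seq3):
        if i == 0:
            n_i, ca_i, c_i = n_prev, ca_prev, c_prev
        else:
            n_i = place_atom(n_prev, ca_prev, c_prev, B_C_N, A_CA_C_N, psi)
            ca_i = place_atom(ca_prev, c_prev, n_i, B_N_CA, A_C_N_CA, OMEGA)
            c_i = place_atom(c_prev, n_i, ca_i, B_CA_C, A_N_CA_C, phi)
        o_i = place_atom(n_i, ca_i, c_i, B_C_O, A_CA_C_O, psi + 180.0)
        atoms = [Atom("N", "N", n_i.copy()), Atom("CA", "C", ca_i.copy()),
                 Atom("C", "C", c_i.copy()), Atom("O", "O", o_i.copy())]
        if name != "GLY":
            cb = place_atom(n_i, c_i, ca_i, B_CA_CB, A_N_CA_CB, T_N_C_CA_CB)
            atoms.append(Atom("CB", "C", cb))
            if name in GAMMA_BUILD and name != "PRO":
                gname, bond, ang = GAMMA_BUILD[name]
                g = place_atom(n_i, ca_i, cb, bond, ang, chi1)
                atoms.append(Atom(gname, "S" if gname == "SG" else gname[0], g))
                if name in SECOND_GAMMA:
                    g2name, bond2, ang2, off = SECOND_GAMMA[name]
                    g2 = place_atom(n_i, ca_i, cb, bond2, ang2, chi1 + off)
                    atoms.append(Atom(g2name, g2name[0], g2))
        residues.append(Residue(chain_id, start_seq + i, "", name, atoms))
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i
    return StructureRecord(pdb_id=pdb_id, resolution=resolution, role=role,
                           chains={chain_id: residues})


BACKBONE_NAMES = {"N", "CA", "C", "O", "CB"}


def set_chi1(s: StructureRecord, key: tuple[str, int, str], angle: float) -> StructureRecord:
    """Rotate all atoms distal to CB about the CA-CB axis so the primary chi1
    equals ``angle`` (in place).  The backbone (and CB) is untouched bitwise;
    valine's second branch shifts by the same amount."""
    res = s.residue_by_key(key)
    if res is None:
        raise KeyError(f"no residue {key}")
    chis = dict(geometry.chi1_of_residue(res))
    if "primary" not in chis:
        raise ValueError(f"{res.name} has no chi1")
    delta = angle - chis["primary"]
    ca, cb = res.atom("CA"), res.atom("CB")
    u = cb.position - ca.position
    u = u / np.linalg.norm(u)
    # +delta in chi1 is a +delta right-handed rotation about the CA->CB axis
    rot = Rotation.from_rotvec(np.radians(delta) * u)
    for a in res.atoms:
        if a.name not in BACKBONE_NAMES:
            a.position = cb.position + rot.apply(a.position - cb.position)
    return s


def perturb_backbone(
    s: StructureRecord,
    target_rmsd: float,
    seed: int = 0,
    n_modes: int = 3,
) -> tuple[StructureRecord, float]:
    """Smooth random deformation with an exact Calpha-RMSD ground truth.

    A displacement field built from low-frequency sinusoids along the chain
    (protein-like collective motion rather than per-atom noise) is applied
    rigidly to each residue and rescaled until the all-Calpha RMSD after
    optimal superposition matches ``target_rmsd`` within 0.1 %.  Returns the
    perturbed copy and the achieved RMSD.
    """
    out = copy.deepcopy(s)
    if target_rmsd == 0.0:
        return out, 0.0
    rng = np.random.default_rng(seed)
    res_list = list(out.residues())
    n = len(res_list)
    t = np.arange(n) / max(1, n)
    amps = rng.normal(size=(n_modes, 3))
    phases = rng.uniform(0, 2 * np.pi, size=(n_modes, 3))
    disp = np.zeros((n, 3))
    for k in range(n_modes):
        disp += amps[k] * np.sin(2 * np.pi * (k + 1) * t[:, None] + phases[k])
    if not np.any(np.linalg.norm(disp, axis=1) > 1e-9):
        disp[:, 0] = t  # pathological draw: fall back to a linear stretch

    ca0 = np.array([r.atom("CA").position for r in res_list])

    def achieved(scale: float) -> float:
        _, _, rmsd = geometry.kabsch(ca0, ca0 + scale * disp)
        return rmsd

    scale = target_rmsd / achieved(1.0)
    for _ in range(100):
        a = achieved(scale)
        if abs(a - target_rmsd) <= 1e-3 * target_rmsd:
            break
        scale *= target_rmsd / a
    for r, d in zip(res_list, scale * disp):
        for atom in r.atoms:
            atom.position = atom.position + d
    ca1 = np.array([r.atom("CA").position for r in res_list])
    _, _, ach = geometry.kabsch(ca0, ca1)
    return out, float(ach)


# ---------------------------------------------------------------------------
# family fixtures

@dataclass
class DecoyHet:
    code: str
    mol_weight: float
    placement: str = "remote"      # "near_site" | "remote"
    member: int = 0                # index into the apo members
    distance: float = 4.0          # A from the nearest site-residue atom


@dataclass
class FamilyFixtureSpec:
    """Recipe for one synthetic family.

    Defaults emulate a modest desk-scale family: three apo and three holo
    members of a 30-residue chain, inherent backbone variation of ~0.3 A
    within each set, a ligand touching a handful of residues, and no induced
    side-chain changes unless ``chi1_settings`` says otherwise.
    """

    family_id: str = "F0001"
    sequence: str = "ARNDEQGHILKMFPSTWYVCARNDEQHILK"
    n_apo: int = 3
    n_holo: int = 3
    phi: float = -120.0
    psi: float = 120.0
    backbone_rmsd: float | list[float] = 0.3
    # auth_seq -> {"apo": angle | [per-member], "holo": ...} (degrees)
    chi1_settings: dict = field(default_factory=dict)
    ligand_contacts: list[int] = field(default_factory=lambda: [8, 9, 11])
    # optional per-holo-member contact lists (cycled); overrides ligand_contacts
    ligand_contacts_per_member: list[list[int]] | None = None
    contact_distance: float = 4.2
    ligand_code: str = "LIG"
    ligand_mw: float = 250.0
    decoy_hets: list[DecoyHet] = field(default_factory=list)
    # (auth_seq at 4.49 A, auth_seq at 4.51 A) exact boundary ligand atoms
    boundary_pair: tuple[int, int] | None = None
    numbering_offsets: list[int] | None = None  # per member, added to auth_seq
    resolutions: list[float] | None = None
    seed: int = 0


@dataclass
class FamilyFixture:
    spec: FamilyFixtureSpec
    structures: list[StructureRecord]
    ligand_specs: dict[str, list[LigandSpec]]
    manifest: dict


def _anchor(res: Residue) -> tuple[np.ndarray, np.ndarray]:
    """Most distal side-chain atom and the outward unit direction from CA."""
    ca = res.atom("CA").position
    for name in ("OG", "OG1", "SG", "CG", "CG1", "CB"):
        a = res.atom(name)
        if a is not None:
            u = a.position - ca
            return a.position, u / np.linalg.norm(u)
    # glycine: point away from the backbone plane
    n, c = res.atom("N").position, res.atom("C").position
    u = np.cross(n - ca, c - ca)
    return ca, u / np.linalg.norm(u)


def _contact_set(struct: StructureRecord, lig_xyz: np.ndarray,
                 cutoff: float = 4.5) -> set[int]:
    """Brute-force double loop over heavy atoms (independent of the pipeline's
    neighbour-search path); returns contacting auth_seq numbers."""
    out = set()
    for res in struct.residues():
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            d = np.linalg.norm(lig_xyz - a.position[None, :], axis=1)
            if float(d.min()) <= cutoff:
                out.add(res.auth_seq)
                break
    return out


def _dihedral_alt(p1, p2, p3, p4) -> float:
    """Independent torsion formula (Praxeolitic atan2 form) used only for
    manifest ground truth, distinct from the pipeline's implementation."""
    b0 = np.asarray(p1) - np.asarray(p2)
    b1 = np.asarray(p3) - np.asarray(p2)
    b2 = np.asarray(p4) - np.asarray(p3)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang >= 180.0:
        ang -= 360.0
    if ang < -180.0:
        ang += 360.0
    return ang


def _measure_chi1(res: Residue) -> float:
    name = res.name
    gname = {"SER": "OG", "CYS": "SG", "THR": "OG1", "ILE": "CG1",
             "VAL": "CG1"}.get(name, "CG")
    return _dihedral_alt(res.atom("N").position, res.atom("CA").position,
                         res.atom("CB").position, res.atom(gname).position)


def _minimal_arc(angles: list[float]) -> float:
    """Brute-force minimal covering arc: try every angle as the arc start."""
    if len(angles) <= 1:
        return 0.0
    a = np.mod(np.asarray(angles, dtype=float), 360.0)
    best = 360.0
    for start in a:
        span = float(np.max(np.mod(a - start, 360.0)))
        best = min(best, span)
    return best


def _member_chi1(spec: FamilyFixtureSpec, auth_seq: int, role: str,
                 idx: int) -> float | None:
    setting = spec.chi1_settings.get(auth_seq)
    if setting is None:
        return None
    val = setting.get(role)
    if val is None:
        return None
    if isinstance(val, (list, tuple)):
        return float(val[idx % len(val)])
    return float(val)


def make_family(spec: FamilyFixtureSpec) -> FamilyFixture:
    """Build one synthetic family and its ground-truth manifest."""
    base = make_ideal_chain(spec.sequence, spec.phi, spec.psi)
    members: list[StructureRecord] = []
    roles = [("apo", i) for i in range(spec.n_apo)] + \
            [("holo", i) for i in range(spec.n_holo)]
    rmsds = spec.backbone_rmsd
    if not isinstance(rmsds, (list, tuple)):
        rmsds = [rmsds] * len(roles)
    fam_num = int("".join(filter(str.isdigit, spec.family_id)) or 0)

    achieved_rmsd: dict[str, float] = {}
    member_index: dict[str, int] = {}
    for m_idx, (role, i) in enumerate(roles):
        pdb_id = f"{fam_num % 100:02d}{role[0]}{i}"
        member_index[pdb_id] = i
        target = float(rmsds[m_idx % len(rmsds)])
        pert, ach = perturb_backbone(base, target,
                                     seed=spec.seed * 1000 + m_idx + 1)
        pert.pdb_id = pdb_id
        pert.role = role
        if spec.resolutions:
            pert.resolution = float(spec.resolutions[m_idx % len(spec.resolutions)])
        achieved_rmsd[pdb_id] = ach
        for auth_seq in sorted(spec.chi1_settings):
            ang = _member_chi1(spec, auth_seq, role, i)
            if ang is not None:
                set_chi1(pert, ("A", auth_seq, ""), ang)
        members.append(pert)

    # ligand placement per holo member, against that member's coordinates
    ligand_specs: dict[str, list[LigandSpec]] = {}
    holo_counter = 0
    for m in members:
        if m.role != "holo":
            continue
        if spec.ligand_contacts_per_member is not None:
            contacts = spec.ligand_contacts_per_member[
                holo_counter % len(spec.ligand_contacts_per_member)]
        else:
            contacts = spec.ligand_contacts
        holo_counter += 1
        lig_atoms: list[Atom] = []
        for k, auth_seq in enumerate(contacts):
            res = m.residue_by_key(("A", auth_seq, ""))
            pos, u = _anchor(res)
            lig_atoms.append(Atom(f"C{k + 1}", "C",
                                  pos + spec.contact_distance * u))
        if spec.boundary_pair is not None:
            r_in, r_out = spec.boundary_pair
            for k, (auth_seq, dist) in enumerate(((r_in, 4.49), (r_out, 4.51))):
                res = m.residue_by_key(("A", auth_seq, ""))
                pos, u = _anchor(res)
                lig_atoms.append(Atom(f"B{k + 1}", "C", pos + dist * u))
        het = HetRecord(spec.ligand_code, "L", 901, "", lig_atoms,
                        mol_weight=spec.ligand_mw)
        m.hets.append(het)
        ligand_specs[m.pdb_id] = [LigandSpec(
            "1", [(spec.ligand_code, "L", 901)], spec.ligand_mw)]

    # decoy HETs on apo members, anchored at the first intended contact residue
    decoy_truth: dict[str, list[dict]] = {}
    anchor_seq = spec.ligand_contacts[0] if spec.ligand_contacts else 1
    for d_idx, decoy in enumerate(spec.decoy_hets):
        apo_members = [m for m in members if m.role == "apo"]
        m = apo_members[decoy.member % len(apo_members)]
        res = m.residue_by_key(("A", anchor_seq, ""))
        pos, u = _anchor(res)
        if decoy.placement == "near_site":
            xyz = pos + decoy.distance * u
        else:
            xyz = pos + 30.0 * u
        m.hets.append(HetRecord(decoy.code, "X", 801 + d_idx, "",
                                [Atom("C1", "C", xyz)], decoy.mol_weight))
        decoy_truth.setdefault(m.pdb_id, []).append(
            {"code": decoy.code, "mol_weight": decoy.mol_weight,
             "placement": decoy.placement})

    # freeze coordinates to PDB file precision (3 decimals) so the written
    # bundle reproduces the fixture exactly, then measure all ground truth
    # on the frozen coordinates
    for m in members:
        for res in m.residues():
            for a in res.atoms:
                a.position = np.round(a.position, 3)
        for h in m.hets:
            for a in h.atoms:
                a.position = np.round(a.position, 3)
    contact_truth = {}
    for m in members:
        if m.role != "holo":
            continue
        lig_xyz = np.array(
            [a.position for h in m.hets if h.component_code == spec.ligand_code
             for a in h.atoms])
        contact_truth[m.pdb_id] = _contact_set(m, lig_xyz)

    # per-member renumbering offsets (exercises reference-numbering recovery)
    offsets = spec.numbering_offsets or [0] * len(members)
    for m, off in zip(members, offsets):
        if off:
            for res in m.residues():
                res.auth_seq += off

    manifest = _build_manifest(spec, members, achieved_rmsd, contact_truth,
                               decoy_truth, offsets, member_index)
    return FamilyFixture(spec, members, ligand_specs, manifest)


def _build_manifest(spec, members, achieved_rmsd, contact_truth, decoy_truth,
                    offsets, member_index):
    # the pipeline's reference member (best resolution, then smallest id)
    # determines the numbering frame the manifest reports in
    ref_pos = min(range(len(members)),
                  key=lambda i: (members[i].resolution, members[i].pdb_id))
    ref_offset = offsets[ref_pos]
    member_offset = {m.pdb_id: off for m, off in zip(members, offsets)}

    # contact sets were measured in base numbering (before offsets)
    unified = sorted({seq + ref_offset
                      for s in contact_truth.values() for seq in s}) \
        if contact_truth else []

    # pairwise Calpha RMSD ground truth on the frozen coordinates
    pair_rmsd = {}
    ca = {m.pdb_id: np.array([r.atom("CA").position for r in m.chains["A"]])
          for m in members}
    ids = sorted(ca)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            _, _, r = geometry.kabsch(ca[a], ca[b])
            pair_rmsd[f"{a}|{b}"] = float(r)

    # chi1 range ground truth per planted residue, per set: angles measured
    # from the frozen structures with an independent torsion formula, ranges
    # from the brute-force minimal-arc oracle
    chi1_truth = {}
    for auth_seq in sorted(spec.chi1_settings):
        per_set = {}
        for set_label, role_filter in (("apo", {"apo"}), ("holo", {"holo"}),
                                       ("apo_holo", {"apo", "holo"})):
            angles = []
            for m in members:
                if m.role not in role_filter:
                    continue
                res = m.residue_by_key(
                    ("A", auth_seq + member_offset[m.pdb_id], ""))
                angles.append(_measure_chi1(res))
            per_set[set_label] = _minimal_arc(angles)
        chi1_truth[str(auth_seq + ref_offset)] = per_set

    expected_decisions = {}
    for m in members:
        reasons = []
        if m.resolution > 2.5:
            reasons.append("RESOLUTION")
        for d in decoy_truth.get(m.pdb_id, []):
            if d["placement"] == "near_site":
                reasons.append("SITE_CONTAMINATION")
            elif d["mol_weight"] > 100.0:
                reasons.append("HET_DISALLOWED")
        expected_decisions[m.pdb_id] = {
            "accepted": not reasons,
            "reasons": sorted(set(reasons)),
        }

    return {
        "family_id": spec.family_id,
        "sequence": spec.sequence,
        "n_apo": spec.n_apo,
        "n_holo": spec.n_holo,
        "unified_site": unified,
        "achieved_rmsd": achieved_rmsd,
        "pair_rmsd": pair_rmsd,
        "chi1_ranges": chi1_truth,
        "contact_sets": {k: sorted(seq + ref_offset for seq in v)
                         for k, v in contact_truth.items()},
        "expected_decisions": expected_decisions,
        "numbering_offsets": offsets,
        "seed": spec.seed,
    }


# ---------------------------------------------------------------------------
# cohorts

def make_cohort(
    n_families: int = 10,
    seed: int = 0,
    induced_shift: float = 100.0,
    inherent_jitter: float = 8.0,
    backbone_rmsd: float = 0.3,
) -> list[FamilyFixture]:
    """A cohort with equal apo/holo inherent flexibility plus induced shifts.

    Within each family, apo and holo chi1 angles for the planted site
    residues jitter identically (+- ``inherent_jitter`` degrees around the
    -60 rotamer), while a random subset of residues is additionally rotated
    by ``induced_shift`` in the holo set only — the binding-induced
    displacement signature: per-set ranges stay small and similar, combined
    apo+holo ranges grow.
    """
    rng = np.random.default_rng(seed)
    fixtures = []
    alphabet = "ACDEFHIKLMNQRSTVWY"  # tail letters giving unique sequences
    for f in range(n_families):
        template = FamilyFixtureSpec().sequence
        tail = alphabet[f % len(alphabet)] + alphabet[(f // len(alphabet)) % len(alphabet)]
        spec = FamilyFixtureSpec(
            family_id=f"F{f + 1:04d}",
            sequence=template + tail,  # family-specific termini: one family each
            seed=int(rng.integers(1, 2**20)),
            backbone_rmsd=backbone_rmsd,
            # resolutions and ligand mass vary as in real cohorts
            # (~1.8 A average resolution, ligand mass a few hundred g/mol)
            resolutions=np.round(rng.uniform(1.4, 2.3, 6), 2).tolist(),
            ligand_mw=float(np.round(rng.uniform(120.0, 650.0), 1)),
        )
        chi1 = {}
        candidates = [a for a in spec.ligand_contacts]
        # extra site-adjacent residues with chi1 so families have several streams
        candidates += [7, 10, 12]
        for auth_seq in candidates:
            name = ONE_TO_THREE[spec.sequence[auth_seq - 1]]
            if name in ("GLY", "PRO", "ALA"):
                continue
            apo = (-60.0 + rng.normal(0, inherent_jitter, spec.n_apo)).tolist()
            holo = (-60.0 + rng.normal(0, inherent_jitter, spec.n_holo)).tolist()
            if rng.random() < 0.5:
                holo = [h + induced_shift for h in holo]
            chi1[auth_seq] = {"apo": apo, "holo": holo}
        spec.chi1_settings = chi1
        fixtures.append(make_family(spec))
    return fixtures


# ---------------------------------------------------------------------------
# bundle I/O

def write_bundle(fixtures: list[FamilyFixture], outdir: str | Path,
                 allowlist: set[str] | None = None) -> Path:
    """Write the input-bundle layout the pipeline consumes.

    Layout: ``pdb/<id>.pdb``, ``index.csv`` (family_id,pdb_id,role,resolution),
    ``ligands.csv``, ``allowlist.csv`` and ``manifest.json``.
    """
    out = Path(outdir)
    (out / "pdb").mkdir(parents=True, exist_ok=True)
    index_rows = ["family_id,pdb_id,role,resolution"]
    lig_rows = ["pdb_id,instance_id,component_code,chain_id,auth_seq,mol_weight"]
    het_weights: dict[str, float] = {}
    manifest = {}
    for fx in fixtures:
        manifest[fx.spec.family_id] = fx.manifest
        for d in fx.spec.decoy_hets:
            het_weights[d.code] = d.mol_weight
        for m in fx.structures:
            (out / "pdb" / f"{m.pdb_id}.pdb").write_text(write_pdb(m))
            index_rows.append(
                f"{fx.spec.family_id},{m.pdb_id},{m.role},{m.resolution:.2f}")
            for ls in fx.ligand_specs.get(m.pdb_id, []):
                for code, ch, seq in ls.components:
                    lig_rows.append(
                        f"{m.pdb_id},{ls.instance_id},{code},{ch},{seq},"
                        f"{ls.mol_weight if ls.mol_weight is not None else ''}")
    (out / "index.csv").write_text("\n".join(index_rows) + "\n")
    (out / "ligands.csv").write_text("\n".join(lig_rows) + "\n")
    (out / "het_weights.csv").write_text(
        "component_code,mol_weight\n" +
        "".join(f"{c},{w}\n" for c, w in sorted(het_weights.items())))
    allow = sorted(allowlist or {"GOL", "EDO", "PEG", "SO4", "PO4", "ACT"})
    (out / "allowlist.csv").write_text(
        "component_code\n" + "\n".join(allow) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
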