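"""Family construction and apo/holo validity filtering.

Structures are clustered into *families* of 100 % sequence identity (both
directions: identical sets of chain sequences), every member is renumbered
onto a shared reference numbering by global alignment, and the validity
rules are applied:

* holo — resolution within the cutoff, exactly one valid ligand, no foreign
  molecules in the binding site;
* apo — resolution within the cutoff, every non-water HET either light
  (MW <= 100 Da) or on the permissible-HET allow-list, and no non-water HET
  heavy atom within the contact cutoff of any unified-binding-site residue.

A family survives only with at least two accepted apo and two accepted holo
members.  The filter order is fixed and reproducible: holo filtering, then
unified site, then apo filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .binding_site import UnifiedSite, site_residues, unify_sites
from .config import RunConfig
from .structure import StructureRecord

__all__ = [
    "Family",
    "CurationDecision",
    "cluster_families",
    "build_reference_numbering",
    "validate_holo",
    "validate_apo",
    "curate_cohort",
]

# rule codes
RESOLUTION = "RESOLUTION"
MULTI_LIGAND = "MULTI_LIGAND"
SITE_CONTAMINATION = "SITE_CONTAMINATION"
HET_DISALLOWED = "HET_DISALLOWED"
NO_FAMILY = "NO_FAMILY"
RENUMBER_FAIL = "RENUMBER_FAIL"


@dataclass
class CurationDecision:
    pdb_id: str
    role: str
    family_id: str
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        assert self.accepted == (not self.reasons)


@dataclass
class Family:
    family_id: str
    members: list[StructureRecord] = field(default_factory=list)
    reference_id: str | None = None
    reference_sequences: dict[str, str] = field(default_factory=dict)
    unified_site: UnifiedSite | None = None
    decisions: list[CurationDecision] = field(default_factory=list)

    def members_by_role(self, role: str) -> list[StructureRecord]:
        return sorted((m for m in self.members if m.role == role),
                      key=lambda s: s.pdb_id)

    @property
    def n_apo(self) -> int:
        return len(self.members_by_role("apo"))

    @property
    def n_holo(self) -> int:
        return len(self.members_by_role("holo"))


# ---------------------------------------------------------------------------
# clustering

def _sequence_key(s: StructureRecord) -> tuple[str, ...]:
    return tuple(sorted(s.chain_sequences().values()))


def _is_terminal_extension(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    """True when each short sequence occurs inside the corresponding long one
    (i.e. the long family only adds residues at the termini)."""
    if len(short) != len(long):
        return False
    return all(a in b for a, b in zip(short, long))


def cluster_families(
    structures: list[StructureRecord],
    merge_terminal_extensions: bool = False,
) -> list[Family]:
    """Group structures sharing identical chain-sequence sets.

    With ``merge_terminal_extensions``, a family whose sequences equal another
    family's extended only at the termini is merged into it (approximating the
    95 %-identity merge pass that catches N/C-terminal tag additions).
    """
    groups: dict[tuple[str, ...], list[StructureRecord]] = {}
    for s in structures:
        groups.setdefault(_sequence_key(s), []).append(s)

    keys = sorted(groups, key=lambda k: (-max(len(x) for x in k), k))
    if merge_terminal_extensions:
        merged: list[tuple[str, ...]] = []
        for k in keys:  # longest first: extensions absorb their cores
            host = next((m for m in merged if _is_terminal_extension(k, m)), None)
            if host is not None:
                groups[host].extend(groups.pop(k))
            else:
                merged.append(k)
        keys = merged

    families = []
    for i, k in enumerate(sorted(keys, key=lambda k: sorted(groups[k],
                                                            key=lambda s: s.pdb_id)[0].pdb_id)):
        members = sorted(groups[k], key=lambda s: s.pdb_id)
        families.append(Family(family_id=f"F{i + 1:04d}", members=members))
    return families


# ---------------------------------------------------------------------------
# reference numbering

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _align_map(ref_seq: str, mem_seq: str, aligner) -> tuple[float, list[tuple[int, int]], int]:
    """Best global alignment: (score, [(ref_pos, mem_pos)], n_mismatches)."""
    aln = aligner.align(ref_seq, mem_seq)[0]
    pairs: list[tuple[int, int]] = []
    mismatches = 0
    for (rs, re), (ms, me) in zip(*aln.aligned):
        for k in range(re - rs):
            i, j = rs + k, ms + k
            if ref_seq[i] != mem_seq[j]:
                mismatches += 1
            pairs.append((i, j))
    return float(aln.score), pairs, mismatches


def build_reference_numbering(family: Family) -> None:
    """Assign a shared reference numbering to every member (in place).

    The reference is the best-resolved member (ties: lexicographically
    smallest pdb id).  Each member chain is globally aligned to each reference
    chain and assigned to the best-scoring one (ties broken by reference chain
    id order).  A member is rejected with RENUMBER_FAIL when any aligned
    residue name mismatches the reference, or two of its chains map onto the
    same reference chain with overlapping reference ranges.
    """
    if not family.members:
        return
    ref = min(family.members, key=lambda s: (s.resolution, s.pdb_id))
    family.reference_id = ref.pdb_id
    family.reference_sequences = ref.chain_sequences()
    aligner = _make_aligner()
    ref_residues = {c: list(ref.chains[c]) for c in ref.chains}

    kept = []
    for m in family.members:
        try:
            _number_member(m, ref, ref_residues, aligner)
            kept.append(m)
        except _RenumberError as exc:
            family.decisions.append(CurationDecision(
                m.pdb_id, m.role, family.family_id, False,
                [f"{RENUMBER_FAIL}:{exc}"]))
    family.members = kept


class _RenumberError(Exception):
    pass


def _number_member(m, ref, ref_residues, aligner) -> None:
    assigned_ranges: dict[str, list[tuple[int, int]]] = {}
    plan = []  # (member_chain, ref_chain, pairs)
    for mc in sorted(m.chains):
        mseq = m.chain_sequence(mc)
        best = None
        for rc in sorted(ref.chains):
            score, pairs, mism = _align_map(ref.chain_sequence(rc), mseq, aligner)
            cand = (-score, rc)
            if best is None or cand < best[0]:
                best = (cand, rc, pairs, mism)
        _, rc, pairs, mism = best
        if mism > 0:
            raise _RenumberError(f"chain {mc}: {mism} aligned residue mismatches")
        if not pairs:
            raise _RenumberError(f"chain {mc}: empty alignment")
        lo = min(p[0] for p in pairs)
        hi = max(p[0] for p in pairs)
        for (plo, phi) in assigned_ranges.get(rc, []):
            if lo <= phi and plo <= hi:
                raise _RenumberError(
                    f"chains map onto reference chain {rc} with overlapping ranges")
        assigned_ranges.setdefault(rc, []).append((lo, hi))
        plan.append((mc, rc, pairs))

    for mc, rc, pairs in plan:
        mem_res = m.chains[mc]
        rres = ref_residues[rc]
        for ref_pos, mem_pos in pairs:
            res = mem_res[mem_pos]
            if res.one_letter != rres[ref_pos].one_letter:
                raise _RenumberError(
                    f"chain {mc}: residue name mismatch at reference "
                    f"{rc}{rres[ref_pos].auth_seq}")
            res.ref_chain = rc
            res.ref_index = rres[ref_pos].auth_seq


# ---------------------------------------------------------------------------
# validity filters

def validate_holo(s: StructureRecord, config: RunConfig | None = None) -> CurationDecision:
    """Apply the holo validity rules; the structure must carry its ligand
    spec(s) and have been stripped (ligands assembled)."""
    cfg = config or RunConfig()
    if s.role != "holo":
        raise ValueError(f"{s.pdb_id}: validate_holo on a {s.role} structure")
    if not s.ligand_specs:
        raise ValueError(f"{s.pdb_id}: holo structure without a ligand spec")
    reasons = []
    if s.resolution > cfg.resolution_cutoff:
        reasons.append(RESOLUTION)
    if len(s.ligands) > 1:
        reasons.append(MULTI_LIGAND)
    elif s.ligand is not None:
        # foreign molecules in the binding site: non-water HETs near the
        # structure's own contact residues
        contact_keys = site_residues(s, s.ligand, cfg.distance_cutoff)
        site_xyz = []
        for key in contact_keys:
            res = s.residue_by_key(key)
            site_xyz.extend(a.position for a in res.heavy_atoms())
        if site_xyz:
            tree = cKDTree(np.asarray(site_xyz))
            for het in s.hets:
                if het.is_water:
                    continue
                pos = [a.position for a in het.heavy_atoms()]
                if pos and float(np.min(tree.query(np.asarray(pos), k=1)[0])) <= cfg.distance_cutoff:
                    reasons.append(SITE_CONTAMINATION)
                    break
    return CurationDecision(s.pdb_id, "holo", "", not reasons, reasons)


def validate_apo(
    s: StructureRecord,
    site: UnifiedSite | None,
    allowlist: set[str],
    config: RunConfig | None = None,
) -> CurationDecision:
    """Apply the apo validity rules against the family's unified site."""
    cfg = config or RunConfig()
    if site is None:
        raise ValueError(
            f"{s.pdb_id}: unified site must be computed (from accepted holo "
            "members) before apo validation")
    reasons = []
    if s.resolution > cfg.resolution_cutoff:
        reasons.append(RESOLUTION)
    non_water = [h for h in s.hets if not h.is_water]
    for het in non_water:
        if het.weight > cfg.het_mw_cutoff and het.component_code not in allowlist:
            reasons.append(HET_DISALLOWED)
            break
    # site contamination: any non-water HET heavy atom within the cutoff of
    # any unified-site residue heavy atom (site mapped via reference numbering)
    site_xyz = []
    for res in s.residues():
        if res.ref_index is not None and (res.ref_chain, res.ref_index) in site.residue_ids:
            site_xyz.extend(a.position for a in res.heavy_atoms())
    if site_xyz and non_water:
        tree = cKDTree(np.asarray(site_xyz))
        for het in non_water:
            pos = [a.position for a in het.heavy_atoms()]
            if pos and float(np.min(tree.query(np.asarray(pos), k=1)[0])) <= cfg.distance_cutoff:
                reasons.append(SITE_CONTAMINATION)
                break
    return CurationDecision(s.pdb_id, "apo", "", not reasons, sorted(set(reasons)))


# ---------------------------------------------------------------------------
# cohort driver

def curate_cohort(
    structures: list[StructureRecord],
    allowlist: set[str],
    config: RunConfig | None = None,
) -> tuple[list[Family], list[CurationDecision]]:
    """Cluster, renumber and filter a cohort.

    Returns the surviving families (each with >= 2 accepted apo and >= 2
    accepted holo members and a unified site) plus the full decision log.
    """
    cfg = config or RunConfig()
    families = cluster_families(structures, cfg.merge_terminal_extensions)
    decisions: list[CurationDecision] = []
    surviving: list[Family] = []
    for fam in families:
        build_reference_numbering(fam)
        for d in fam.decisions:
            d.family_id = fam.family_id
        decisions.extend(fam.decisions)
        fam.decisions = []

        accepted: list[StructureRecord] = []
        holo_ok: list[StructureRecord] = []
        for m in fam.members_by_role("holo"):
            d = validate_holo(m, cfg)
            d.family_id = fam.family_id
            decisions.append(d)
            if d.accepted:
                holo_ok.append(m)

        apo_ok: list[StructureRecord] = []
        if holo_ok:
            fam.unified_site = unify_sites(holo_ok, fam.members, cfg.distance_cutoff)
            for m in fam.members_by_role("apo"):
                d = validate_apo(m, fam.unified_site, allowlist, cfg)
                d.family_id = fam.family_id
                decisions.append(d)
                if d.accepted:
                    apo_ok.append(m)
        else:
            for m in fam.members_by_role("apo"):
                decisions.append(CurationDecision(m.pdb_id, "apo", fam.family_id,
                                                  False, [NO_FAMILY]))

        accepted = holo_ok + apo_ok
        if len(apo_ok) >= 2 and len(holo_ok) >= 2:
            fam.members = sorted(accepted, key=lambda s: s.pdb_id)
            # presence map restricted to surviving members
            fam.unified_site = unify_sites(holo_ok, fam.members, cfg.distance_cutoff)
            surviving.append(fam)
        else:
            for m in accepted:
                # structure itself was fine; its family fell below 2+2
                for d in decisions:
                    if d.pdb_id == m.pdb_id and d.family_id == fam.family_id and d.accepted:
                        d.accepted = False
                        d.reasons = [NO_FAMILY]
    return surviving, decisions
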