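"""Binding-site residue identification and the family-level unified site.

A structure's binding site is every protein residue with a heavy atom within
the distance cutoff (default 4.5 A, inclusive) of any ligand heavy atom;
hydrogens are never considered.  A family's *unified* binding site is the
union of the per-structure contact sets over all of its holo members, in the
family reference numbering — the totality of the pocket across every observed
ligand pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import LigandInstance, StructureRecord

__all__ = ["UnifiedSite", "site_residues", "unify_sites"]

DEFAULT_CUTOFF = 4.5


@dataclass
class UnifiedSite:
    residue_ids: set[tuple[str, int]]  # (ref_chain, ref_index)
    # subset of residue_ids resolvable in each member structure
    per_structure_presence: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    residue_names: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.residue_ids)

    def sorted_ids(self) -> list[tuple[str, int]]:
        return sorted(self.residue_ids)


def site_residues(
    s: StructureRecord,
    lig: LigandInstance,
    cutoff: float = DEFAULT_CUTOFF,
) -> set[tuple[str, int, str]]:
    """Residue keys with any heavy atom within ``cutoff`` of a ligand heavy atom.

    The cutoff is inclusive (d <= cutoff counts).  The structure should be
    stripped and altloc-resolved; hydrogens are skipped defensively anyway.
    """
    if lig is None or not lig.heavy_atoms:
        raise ValueError(f"{s.pdb_id}: empty ligand in site_residues")
    lig_xyz = np.array([a.position for a in lig.heavy_atoms
                        if not a.is_hydrogen])
    if lig_xyz.size == 0:
        raise ValueError(f"{s.pdb_id}: ligand has no heavy atoms")
    tree = cKDTree(lig_xyz)
    out: set[tuple[str, int, str]] = set()
    for res in s.residues():
        pos = [a.position for a in res.atoms if not a.is_hydrogen]
        if not pos:
            continue
        d, _ = tree.query(np.asarray(pos), k=1)
        if float(np.min(d)) <= cutoff:
            out.add(res.key)
    return out


def _site_residues_bruteforce(s, lig, cutoff=DEFAULT_CUTOFF):
    """All-pairs double loop; reference implementation for equivalence tests."""
    out = set()
    lig_atoms = [a for a in lig.heavy_atoms if not a.is_hydrogen]
    for res in s.residues():
        hit = False
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            for b in lig_atoms:
                if float(np.linalg.norm(a.position - b.position)) <= cutoff:
                    hit = True
                    break
            if hit:
                break
        if hit:
            out.add(res.key)
    return out


def unify_sites(
    holo_members: list[StructureRecord],
    all_members: list[StructureRecord] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> UnifiedSite:
    """Union of per-structure contact sets over all holo members, mapped into
    the family reference numbering.

    ``all_members`` (defaulting to the holo members) determines the
    per-structure presence map: which unified-site residues each structure
    actually resolves.
    """
    if not holo_members:
        raise ValueError("unify_sites needs at least one holo member")
    ids: set[tuple[str, int]] = set()
    names: dict[tuple[str, int], str] = {}
    for m in sorted(holo_members, key=lambda s: s.pdb_id):
        if m.ligand is None:
            raise ValueError(f"{m.pdb_id}: holo member has no assembled ligand")
        contact_keys = site_residues(m, m.ligand, cutoff)
        for key in contact_keys:
            res = m.residue_by_key(key)
            if res is None or res.ref_index is None:
                continue  # contact residue outside the reference mapping
            rid = (res.ref_chain, res.ref_index)
            ids.add(rid)
            names.setdefault(rid, res.name)
    site = UnifiedSite(residue_ids=ids, residue_names=names)
    for m in sorted(all_members or holo_members, key=lambda s: s.pdb_id):
        present = set()
        for res in m.residues():
            if res.ref_index is not None and (res.ref_chain, res.ref_index) in ids:
                present.add((res.ref_chain, res.ref_index))
        site.per_structure_presence[m.pdb_id] = present
    return site
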