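"""Domain types and PDB-format I/O for apo/holo structure analysis.

A :class:`StructureRecord` is the in-memory form of one crystal structure:
protein chains of residues of atoms, plus the non-protein HET inventory and
(for holo structures) the assembled biologically relevant ligand.  Parsing is
delegated to :mod:`gemmi`; the curation policies layered on top — alternate
location resolution by occupancy, hydrogen/water stripping, ligand extraction —
are implemented here because they carry the analysis conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "HetRecord",
    "LigandInstance",
    "LigandSpec",
    "StructureRecord",
    "PdbError",
    "parse_structure",
    "resolve_altlocs",
    "strip_for_analysis",
    "write_pdb",
]

# 20 standard amino acids, three-letter -> one-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
# Modified amino acids kept in the protein chain (backbone analysis only;
# excluded from chi1 work).  MSE = selenomethionine.
MODIFIED_AA = {"MSE": "M"}
WATER_CODES = {"HOH", "DOD", "WAT"}
HYDROGEN_ELEMENTS = {"H", "D"}

# Standard atomic weights (g/mol) for HET molecular-weight fallback.
ATOMIC_WEIGHTS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "FE": 55.845, "ZN": 65.38, "CU": 63.546,
    "CO": 58.933, "NI": 58.693, "CD": 112.414, "HG": 200.592, "B": 10.81,
}


class PdbError(ValueError):
    """Raised for malformed coordinate files or violated input contracts."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    serial: int = 0

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    chain_id: str
    auth_seq: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    # Family reference numbering, assigned during curation.
    ref_chain: str | None = None
    ref_index: int | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        """Residue identity: (chain, author seq number, insertion code)."""
        return (self.chain_id, self.auth_seq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name) or MODIFIED_AA.get(self.name, "X")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class HetRecord:
    component_code: str
    chain_id: str
    auth_seq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    mol_weight: float | None = None

    @property
    def is_water(self) -> bool:
        return self.component_code in WATER_CODES

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def computed_weight(self) -> float:
        """Molecular weight from atomic composition (heavy atoms as stored)."""
        w = 0.0
        for a in self.atoms:
            try:
                w += ATOMIC_WEIGHTS[a.element.upper()]
            except KeyError:
                raise PdbError(
                    f"no atomic weight for element {a.element!r} "
                    f"in HET {self.component_code}"
                ) from None
        return w

    @property
    def weight(self) -> float:
        return self.mol_weight if self.mol_weight is not None else self.computed_weight()


@dataclass
class LigandSpec:
    """Selector for one biologically relevant ligand instance.

    ``components`` lists (component_code, chain_id, auth_seq) triples; a
    multi-HET ligand (e.g. the four-part peptidic inhibitor 34H+DIL+XPR+AG2)
    is one instance with several components.
    """

    instance_id: str
    components: list[tuple[str, str, int]]
    mol_weight: float | None = None


@dataclass
class LigandInstance:
    component_codes: list[str]
    heavy_atoms: list[Atom]
    mol_weight: float

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_atoms)


@dataclass
class StructureRecord:
    pdb_id: str
    resolution: float
    role: str  # "apo" | "holo"
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    hets: list[HetRecord] = field(default_factory=list)
    ligand_specs: list[LigandSpec] = field(default_factory=list)
    ligands: list[LigandInstance] = field(default_factory=list)

    @property
    def ligand(self) -> LigandInstance | None:
        """The single validated ligand of a holo structure, if exactly one."""
        return self.ligands[0] if len(self.ligands) == 1 else None

    def residues(self):
        for chain_id in sorted(self.chains):
            yield from self.chains[chain_id]

    def residue_by_key(self, key: tuple[str, int, str]) -> Residue | None:
        for r in self.chains.get(key[0], []):
            if r.key == key:
                return r
        return None

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])

    def chain_sequences(self) -> dict[str, str]:
        return {c: self.chain_sequence(c) for c in sorted(self.chains)}

    def n_atoms(self) -> int:
        n = sum(len(r.atoms) for r in self.residues())
        n += sum(len(h.atoms) for h in self.hets)
        n += sum(len(l.heavy_atoms) for l in self.ligands)
        return n


def _is_protein_residue(name: str, has_ca: bool) -> bool:
    return (name in THREE_TO_ONE or name in MODIFIED_AA) and has_ca


def _validate_coordinate_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PdbError(f"line {lineno}: coordinate record too short")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PdbError(
                    f"line {lineno}: malformed coordinate fields"
                ) from None


def parse_structure(
    pdb_text: str,
    role: str,
    pdb_id: str | None = None,
    resolution: float | None = None,
    ligand_specs: list[LigandSpec] | None = None,
) -> StructureRecord:
    """Parse PDB-format text into a :class:`StructureRecord`.

    ``resolution`` overrides the header value (REMARK 2); it must be available
    from one of the two because resolution is a curation criterion.  Residues
    are grouped by (chain, auth_seq, icode); HETATM groups that are not
    recognisable amino acids become :class:`HetRecord` entries.  For files with
    multiple MODELs the first model containing all declared ligand components
    is used (MODEL 1 when no ligand is declared).
    """
    if role not in ("apo", "holo"):
        raise ValueError(f"role must be 'apo' or 'holo', got {role!r}")
    _validate_coordinate_lines(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PdbError(f"PDB parse failed: {exc}") from exc
    if len(st) == 0:
        raise PdbError("no ATOM/HETATM records found")

    specs = ligand_specs or []
    model = _select_model(st, specs)

    rec = StructureRecord(
        pdb_id=(pdb_id or st.name or "XXXX").lower(),
        resolution=0.0,
        role=role,
        ligand_specs=list(specs),
    )
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper(),
                    position=np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float),
                    occupancy=a.occ,
                    altloc=a.altloc if a.altloc != "\0" else "",
                    b_factor=a.b_iso,
                    serial=a.serial,
                )
                for a in res
            ]
            has_ca = any(a.name == "CA" for a in atoms)
            if _is_protein_residue(res.name, has_ca):
                rec.chains.setdefault(chain.name, []).append(
                    Residue(chain.name, res.seqid.num, icode, res.name, atoms)
                )
            else:
                rec.hets.append(
                    HetRecord(res.name, chain.name, res.seqid.num, icode, atoms)
                )

    res_val = resolution if resolution is not None else (st.resolution or None)
    if res_val is None or res_val <= 0:
        raise PdbError(
            f"{rec.pdb_id}: resolution unavailable (header REMARK 2 or "
            "sidecar metadata required)"
        )
    rec.resolution = float(res_val)
    return rec


def _select_model(st: gemmi.Structure, specs: list[LigandSpec]):
    if len(st) == 1 or not specs:
        return st[0]
    wanted = {(code, ch, seq) for s in specs for (code, ch, seq) in s.components}
    for model in st:
        present = set()
        for chain in model:
            for res in chain:
                present.add((res.name, chain.name, res.seqid.num))
        if wanted <= present:
            return model
    return st[0]


def _pick_altloc(atoms: list[Atom]) -> list[Atom]:
    """One atom per name: highest occupancy, ties broken by file order."""
    out: list[Atom] = []
    seen: dict[str, int] = {}
    for a in atoms:
        if a.name not in seen:
            seen[a.name] = len(out)
            out.append(a)
        else:
            i = seen[a.name]
            if a.occupancy > out[i].occupancy:
                out[i] = a
    for a in out:
        a.altloc = ""
    return out


def resolve_altlocs(s: StructureRecord) -> StructureRecord:
    """Collapse alternate locations: keep the highest-occupancy copy of each
    atom name, first-listed on ties.  Idempotent."""
    for res in s.residues():
        res.atoms = _pick_altloc(res.atoms)
    for het in s.hets:
        het.atoms = _pick_altloc(het.atoms)
    return s


def strip_for_analysis(s: StructureRecord) -> StructureRecord:
    """Prepare a structure for measurement.

    Removes all hydrogens/deuteriums and all waters, and moves the declared
    ligand components of a holo structure out of the HET inventory into
    assembled :class:`LigandInstance` objects.  Coordinates of retained atoms
    are untouched.
    """
    for res in s.residues():
        res.atoms = [a for a in res.atoms if not a.is_hydrogen]
    s.hets = [h for h in s.hets if not h.is_water]
    for h in s.hets:
        h.atoms = [a for a in h.atoms if not a.is_hydrogen]

    if s.ligand_specs:
        remaining = list(s.hets)
        s.ligands = []
        for spec in s.ligand_specs:
            atoms: list[Atom] = []
            codes: list[str] = []
            matched_any = False
            for code, chain_id, auth_seq in spec.components:
                hit = None
                for h in remaining:
                    if (h.component_code == code and h.chain_id == chain_id
                            and h.auth_seq == auth_seq):
                        hit = h
                        break
                if hit is None:
                    continue
                matched_any = True
                remaining.remove(hit)
                codes.append(code)
                atoms.extend(hit.heavy_atoms())
            if not matched_any:
                raise PdbError(
                    f"{s.pdb_id}: ligand spec {spec.instance_id!r} matches no "
                    "HET group"
                )
            if spec.mol_weight is not None:
                mw = spec.mol_weight
            else:
                mw = sum(ATOMIC_WEIGHTS.get(a.element.upper(), 0.0) for a in atoms)
            s.ligands.append(LigandInstance(codes, atoms, mw))
        s.hets = remaining
    return s


def _fmt_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-2 char elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(s: StructureRecord) -> str:
    """Serialize to fixed-column PDB format (round-trips with parse_structure)."""
    lines = [
        f"HEADER    PROTEIN                                 01-JAN-00   {s.pdb_id.upper()[:4]:<4s}",
        f"REMARK   2 RESOLUTION.    {s.resolution:.2f} ANGSTROMS.",
    ]
    serial = 0

    def coord_line(record: str, a: Atom, resname: str, chain: str,
                   seq: int, icode: str) -> str:
        nonlocal serial
        serial += 1
        name = _fmt_atom_name(a.name, a.element)
        alt = a.altloc or " "
        ic = icode or " "
        x, y, z = a.position
        el = f"{a.element.upper():>2s}"
        return (f"{record:<6s}{serial:5d} {name}{alt}{resname:>3s} {chain:1s}"
                f"{seq:4d}{ic}   {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
                f"{a.b_factor:6.2f}          {el}")

    for chain_id in sorted(s.chains):
        for res in s.chains[chain_id]:
            for a in res.atoms:
                lines.append(coord_line("ATOM", a, res.name, chain_id,
                                        res.auth_seq, res.icode))
        lines.append("TER")
    for h in s.hets:
        for a in h.atoms:
            lines.append(coord_line("HETATM", a, h.component_code, h.chain_id,
                                    h.auth_seq, h.icode))
    for i, lig in enumerate(s.ligands):
        # extracted ligands are written back under their first component code;
        # files meant to round-trip are written before strip_for_analysis
        code = lig.component_codes[0] if lig.component_codes else "LIG"
        for a in lig.heavy_atoms:
            lines.append(coord_line("HETATM", a, code, "L", 900 + i, ""))
    lines.append("END")
    return "\n".join(lines) + "\n"
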