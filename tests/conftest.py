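"""Shared fixtures: tiny handwritten PDB snippets and synthetic families."""

import numpy as np
import pytest

from apoholo.config import RunConfig
from apoholo.structure import parse_structure, resolve_altlocs, strip_for_analysis
from apoholo.synthetic import FamilyFixtureSpec, make_family


def pdb_line(record, serial, name, resname, chain, seq, x, y, z,
             occ=1.0, b=0.0, element=None, altloc=" ", icode=" "):
    element = element or name[0]
    aname = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:5d} {aname}{altloc}{resname:>3s} {chain}"
            f"{seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


def minimal_pdb(extra_lines=(), resolution=1.8):
    """Three-residue single-chain fragment with plausible geometry."""
    lines = [f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS."]
    coords = [
        ("N", "ALA", 1, 0.0, 0.0, 0.0), ("CA", "ALA", 1, 1.46, 0.0, 0.0),
        ("C", "ALA", 1, 2.0, 1.4, 0.0), ("O", "ALA", 1, 1.3, 2.4, 0.0),
        ("CB", "ALA", 1, 2.0, -0.8, -1.2),
        ("N", "GLY", 2, 3.3, 1.5, 0.0), ("CA", "GLY", 2, 4.0, 2.8, 0.0),
        ("C", "GLY", 2, 5.5, 2.7, 0.0), ("O", "GLY", 2, 6.1, 1.6, 0.0),
        ("N", "SER", 3, 6.1, 3.9, 0.0), ("CA", "SER", 3, 7.5, 4.0, 0.0),
        ("C", "SER", 3, 8.2, 5.3, 0.0), ("O", "SER", 3, 7.5, 6.4, 0.0),
        ("CB", "SER", 3, 8.3, 3.5, 1.2), ("OG", "SER", 3, 9.6, 4.0, 1.3),
    ]
    for i, (name, res, seq, x, y, z) in enumerate(coords, start=1):
        lines.append(pdb_line("ATOM", i, name, res, "A", seq, x, y, z))
    lines.extend(extra_lines)
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_residue_pdb():
    return minimal_pdb()


@pytest.fixture
def default_config():
    return RunConfig()


@pytest.fixture
def plain_family():
    """One synthetic family, no decoys, modest backbone variation."""
    return make_family(FamilyFixtureSpec(seed=11))


@pytest.fixture
def shifted_family():
    """Family with a planted apo/holo chi1 displacement on residue 9 (Ile)."""
    spec = FamilyFixtureSpec(
        seed=5,
        chi1_settings={9: {"apo": -60.0, "holo": 180.0}},
    )
    return make_family(spec)


def load_fixture_structures(fixture):
    """Round-trip fixture members through PDB text, as the pipeline would."""
    from apoholo.structure import write_pdb
    out = []
    for m in fixture.structures:
        text = write_pdb(m)
        s = parse_structure(text, m.role, pdb_id=m.pdb_id,
                            resolution=m.resolution,
                            ligand_specs=fixture.ligand_specs.get(m.pdb_id, []))
        resolve_altlocs(s)
        strip_for_analysis(s)
        out.append(s)
    return out
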