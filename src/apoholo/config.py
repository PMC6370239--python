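"""Run configuration: every tunable cutoff of the analysis in one place.

Defaults mirror the study conventions: 4.5 A inclusive contact cutoff, 2.5 A
resolution ceiling, 100 Da HET molecular-weight threshold, 1.4 A probe.
The config is serialized into every output bundle so a run is reproducible
from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    distance_cutoff: float = 4.5      # A, ligand-contact / contamination rule (inclusive)
    resolution_cutoff: float = 2.5    # A, maximum accepted resolution
    het_mw_cutoff: float = 100.0      # Da, HET allowed in apo without allow-list entry
    probe_radius: float = 1.4         # A, SASA probe
    sasa_points: int = 960            # test points per atom
    site_rmsd_fit: str = "local"      # "local" | "global" superposition frame
    merge_valine_chi1: bool = False   # merge Val's two chi1 streams
    merge_terminal_extensions: bool = False  # family merge for termini-extended seqs
    bin_width: float = 10.0           # deg, chi1 occupancy histograms
    jackknife_resamples: int = 1000
    jackknife_fraction: float = 0.9
    flex_threshold: float = 40.0      # deg, amino-acid class threshold
    seed: int = 0

    def __post_init__(self):
        for name in ("distance_cutoff", "resolution_cutoff", "het_mw_cutoff",
                     "probe_radius", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.site_rmsd_fit not in ("local", "global"):
            raise ValueError("site_rmsd_fit must be 'local' or 'global'")
        if not 0 < self.jackknife_fraction <= 1:
            raise ValueError("jackknife_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
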