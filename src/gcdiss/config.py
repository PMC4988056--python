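"""Run configuration: every pipeline constant in one serialisable place.

Defaults are the calibrated/ conventional values: hit filters e-value
1e-5 and identity 30 %, genome QC at 1000 mapped genes, delineation
cutoffs 0.2 (species) and 0.4 (family), ANIb fragmentation at 1020 nt
with 30 % identity / 70 % coverage retention, 999 MRPP permutations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    evalue_max: float = 1e-5
    identity_min: float = 30.0
    min_mapped: int = 1000
    species_cutoff: float = 0.2
    family_cutoff: float = 0.4
    ani_identity_min: float = 30.0
    ani_coverage_min: float = 0.7
    fragment_len: int = 1020
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_max < 0:
            raise ValueError("evalue_max must be non-negative")
        for name in ("identity_min", "ani_identity_min"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if not 0 < self.species_cutoff < self.family_cutoff < 1:
            raise ValueError("require 0 < species_cutoff < family_cutoff < 1")
        if not 0 < self.ani_coverage_min <= 1:
            raise ValueError("ani_coverage_min must be in (0, 1]")
        if self.fragment_len < 1 or self.min_mapped < 0 or self.n_perm < 1:
            raise ValueError("fragment_len/min_mapped/n_perm out of range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        """New config with non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)
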