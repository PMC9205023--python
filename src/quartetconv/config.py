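"""Pipeline configuration: one dataclass holding every tunable, plus YAML IO.

Defaults follow the operational criteria of the underlying study where one
is stated (max gap 50 genes, blocks of >= 4 anchors, gene families capped at
50 members, KDE bandwidth 0.05, curve-fit R^2 >= 0.95, conversion tracts
>= 10 nt, 1000 bootstrap replicates, alpha 0.05, twofold expression cutoff).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    max_gap: int = 50
    min_block_len: int = 4
    family_size_cutoff: int = 50
    kde_bandwidth: float = 0.05
    r2_threshold: float = 0.95
    min_tract_len: int = 10
    bootstrap_B: int = 1000
    alpha: float = 0.05
    fold_cutoff: float = 2.0
    tpm_pseudocount: float = 0.1
    rng_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
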