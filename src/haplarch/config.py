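"""Run configuration: one dataclass holding every tunable, YAML-loadable.

Defaults are the method's standard operating point: 80-SNP windows
overlapping by 5, groups of 4 windows, 100 downsampling replicates at
20% missing for annotation, 10 EM iterations from τ₀ = 0.01, and 100
sampled paths for credible intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    window_size: int = 80
    window_overlap: int = 5
    group_size: int = 4
    target_groups: int | None = None
    merge_horizon: int = 3
    merge_tolerance: float = 0.15
    edge_floor: float | None = None
    downsample_reps: int = 100
    missing_rate: float = 0.2
    em_iterations: int = 10
    init_tau: float = 0.01
    pi_floor: float = 1e-6
    n_path_samples: int = 100
    ci_level: float = 0.95
    seed: int | None = None
    threads: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
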