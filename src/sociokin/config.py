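"""Pipeline configuration.

The defaults reproduce the analysis conditions of the field study the
package models: a 350 m distance / 1 h simultaneity association rule on
daily sampling periods, a 250 m fixed kernel bandwidth on a 200x200 grid,
1000 data-stream permutations for the preferred-companion test, 10000
permutations for matrix tests, and 10-day jackknife blocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    association_distance_m: float = 350.0
    simultaneity_window_h: float = 1.0
    sampling_period_days: int = 1
    kernel_bandwidth_m: float = 250.0
    kernel_grid_cells: int = 200
    n_permutations_association: int = 1000
    n_permutations_matrix: int = 10000
    jackknife_block_days: int = 10
    missing_genotype_token: str = "0"
    mark_rate: float = 1.0
    random_seed: int = 0

    _POSITIVE = (
        "association_distance_m",
        "simultaneity_window_h",
        "sampling_period_days",
        "kernel_bandwidth_m",
        "kernel_grid_cells",
        "n_permutations_association",
        "n_permutations_matrix",
        "jackknife_block_days",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not (0 < self.mark_rate <= 1):
            raise ConfigError("mark_rate must be in (0, 1]")
        if self.random_seed is None:
            raise ConfigError("random_seed is required for reproducibility")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known - {"inputs", "output"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
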