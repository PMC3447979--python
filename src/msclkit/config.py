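"""Run configuration shared by the CLI subcommands.

Precedence is flags > config file > defaults, and every run persists its
resolved configuration next to its outputs so results can be reproduced from
the output directory alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .restraints import DEFAULT_DR, DEFAULT_EPR_BOUND, DEFAULT_K, DEFAULT_R_MAX
from .structure import DomainMap


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    domain_map_overrides: dict[str, tuple[int, int]] = field(default_factory=dict)
    k: float = DEFAULT_K
    epr_bound: float = DEFAULT_EPR_BOUND
    epsilon_alpha: float = 0.5
    epsilon_clip: tuple[float, float] = (0.5, 2.0)
    table_dr: float = DEFAULT_DR
    table_r_max: float = DEFAULT_R_MAX
    table_dialect: str = "plain"
    kink_angle_threshold: float = 20.0
    kink_displacement_threshold: float = 0.15
    n_lambda_windows: int = 5
    seed: int = 0

    _FIELDS = (
        "domain_map_overrides k epr_bound epsilon_alpha epsilon_clip table_dr "
        "table_r_max table_dialect kink_angle_threshold kink_displacement_threshold "
        "n_lambda_windows seed"
    ).split()

    def __post_init__(self) -> None:
        if self.k < 0 or self.epr_bound <= 0 or self.table_dr <= 0:
            raise ConfigError("k must be >= 0, epr_bound and table_dr > 0")
        if self.table_dialect not in ("plain", "extended"):
            raise ConfigError(f"unknown table dialect {self.table_dialect!r}")
        if self.n_lambda_windows < 2:
            raise ConfigError("n_lambda_windows must be >= 2")

    @classmethod
    def load(cls, path: str | Path | None, **overrides: Any) -> "RunConfig":
        """Build from defaults <- YAML file <- keyword overrides (None skipped)."""
        data: dict[str, Any] = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            unknown = set(raw) - set(cls._FIELDS)
            if unknown:
                raise ConfigError(f"unknown config keys: {sorted(unknown)}")
            data.update(raw)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "epsilon_clip" in data:
            data["epsilon_clip"] = tuple(data["epsilon_clip"])
        if "domain_map_overrides" in data:
            data["domain_map_overrides"] = {
                k: tuple(v) for k, v in data["domain_map_overrides"].items()
            }
        return cls(**data)

    def domain_map(self) -> DomainMap:
        return DomainMap.default().merged(self.domain_map_overrides)

    def dump(self, path: str | Path) -> None:
        d = asdict(self)
        d["epsilon_clip"] = list(self.epsilon_clip)
        d["domain_map_overrides"] = {
            k: list(v) for k, v in self.domain_map_overrides.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
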