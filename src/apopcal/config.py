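"""YAML run configuration.

A config file captures everything a sweep+calibration run needs: grid preset
or explicit levels, cycle lengths, model selection, protocol settings, range
preset, output paths and worker count.  A ``toy_model:`` block overrides the
phenomenological cell's constants.  The pipeline is deterministic; ``seed``
is carried for forward compatibility with stochastic models.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .core import ModelInputError
from .sweep import GridSpec
from .synthetic_cell import ToyModelConstants

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    grid: str | dict[str, list[float]] = "default"
    cls: list[int] = field(default_factory=lambda: [400, 600, 1000])
    model: str = "toy"
    dt: float = 1.0
    max_time: float = 1_000_000.0
    steady_tol: float = 0.05
    ranges: str = "table1"
    out: str = "sweep.h5"
    workers: int = 1
    store_traces: bool = False
    seed: int = 0
    toy_model: dict[str, float] = field(default_factory=dict)

    def grid_spec(self) -> GridSpec:
        if isinstance(self.grid, str):
            return GridSpec.from_preset(self.grid)
        return GridSpec.from_dict(self.grid)

    def toy_constants(self) -> ToyModelConstants:
        return ToyModelConstants().with_overrides(self.toy_model)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ModelInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
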