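"""Run configuration shared by the CLI and the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

from leafmorph.errors import ConfigurationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    dpi: float = 1200.0
    harmonics: int = 50
    contour_samples: int = 1000
    bin_width: float = 10.0
    grid_resolution: int = 2048
    alpha: float = 0.05
    seed: int = 0
    min_component_px: int = 100
    distance_pairing: str = "nearest"  # or "indexed"
    force_test: str | None = None  # None | "t" | "mw"

    def __post_init__(self) -> None:
        if self.distance_pairing not in ("nearest", "indexed"):
            raise ConfigurationError(f"unknown distance_pairing {self.distance_pairing!r}")
        if self.force_test not in (None, "t", "mw"):
            raise ConfigurationError(f"unknown force_test {self.force_test!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
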