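"""Run configuration: physical parameters, output precision, logging."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .constants import Constants
from .thermochem import QuasiRRHOParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable knobs for one analysis run.

    Physical parameters must be positive; ``output_precision`` is the number
    of significant figures used only in human-facing report cells —
    machine-readable outputs always carry full precision.
    """

    temperature: float = 298.15
    pressure: float = 1.0
    conversion_constant: float = 627.5095
    nu0: float = 100.0
    alpha: float = 4.0
    b_av: float = 1e-44
    output_precision: int = 3
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "conversion_constant", "nu0", "alpha", "b_av"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.output_precision < 1:
            raise ValueError("output_precision must be ≥ 1")

    @property
    def constants(self) -> Constants:
        return Constants(hartree_to_kcal=self.conversion_constant)

    @property
    def qrrho(self) -> QuasiRRHOParams:
        return QuasiRRHOParams(nu0=self.nu0, alpha=self.alpha, b_av=self.b_av)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Read YAML (JSON is a YAML subset, so both parse)."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")

    def override(self, **changes) -> "RunConfig":
        """CLI flags take precedence over file values."""
        provided = {k: v for k, v in changes.items() if v is not None}
        return replace(self, **provided) if provided else self
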