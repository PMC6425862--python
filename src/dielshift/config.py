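"""Run configuration for the end-to-end pipeline (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .io_formats import canonicalize_hour
from .window_enrichment import TimeWindow

__all__ = ["ConfigError", "SpeciesConfig", "RunConfig"]


class ConfigError(ValueError):
    """The run configuration is invalid."""


@dataclass(frozen=True)
class SpeciesConfig:
    """One species: its role in the contrast, data path, and diel windows."""

    id: str
    role: str  # "cam" | "c3"
    expression: Path
    dusk_hours: tuple[float, ...]
    dawn_hours: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.role not in ("cam", "c3"):
            raise ConfigError(f"species {self.id!r}: role must be 'cam' or 'c3', got {self.role!r}")
        object.__setattr__(self, "expression", Path(self.expression))
        object.__setattr__(
            self, "dusk_hours", tuple(canonicalize_hour(h) for h in self.dusk_hours)
        )
        object.__setattr__(
            self, "dawn_hours", tuple(canonicalize_hour(h) for h in self.dawn_hours)
        )
        if set(self.dusk_hours) & set(self.dawn_hours):
            raise ConfigError(f"species {self.id!r}: dusk and dawn windows overlap")

    @property
    def dusk(self) -> TimeWindow:
        return TimeWindow("dusk", frozenset(self.dusk_hours))

    @property
    def dawn(self) -> TimeWindow:
        return TimeWindow("dawn", frozenset(self.dawn_hours))


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; exactly one CAM and two C3 species."""

    species: tuple[SpeciesConfig, ...]
    ortholog_groups: Path
    output_dir: Path
    alpha: float = 0.05
    rho_neg: float = -0.6
    rho_pos: float = 0.6
    min_mean_fpkm: float = 0.01
    max_zero_fraction: float = 0.5
    normalization_scale: int = 1000
    rho_on: str = "raw"  # "raw" | "normalized"
    target_hours: tuple[float, ...] = tuple(float(h) for h in range(0, 24, 2))

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "ortholog_groups", Path(self.ortholog_groups))
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        object.__setattr__(
            self, "target_hours", tuple(sorted(canonicalize_hour(h) for h in self.target_hours))
        )
        cam = [s for s in self.species if s.role == "cam"]
        c3 = [s for s in self.species if s.role == "c3"]
        if len(cam) != 1:
            raise ConfigError(f"exactly one CAM species required, found {len(cam)}")
        if len(c3) != 2:
            raise ConfigError(f"exactly two C3 species required, found {len(c3)}")
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate species IDs: {ids}")
        grid = set(self.target_hours)
        for s in self.species:
            off = sorted((set(s.dusk_hours) | set(s.dawn_hours)) - grid)
            if off:
                raise ConfigError(
                    f"species {s.id!r}: window hour(s) {off} not on the "
                    f"post-interpolation grid {sorted(grid)}"
                )
        if self.rho_on not in ("raw", "normalized"):
            raise ConfigError(f"rho_on must be 'raw' or 'normalized', got {self.rho_on!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (-1 <= self.rho_neg <= 1 and -1 <= self.rho_pos <= 1):
            raise ConfigError("rho thresholds must lie in [-1, 1]")

    @property
    def cam(self) -> SpeciesConfig:
        return next(s for s in self.species if s.role == "cam")

    @property
    def c3(self) -> tuple[SpeciesConfig, SpeciesConfig]:
        a, b = (s for s in self.species if s.role == "c3")
        return (a, b)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run config; relative paths resolve against the YAML's directory."""
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        base = path.parent
        try:
            species = tuple(
                SpeciesConfig(
                    id=s["id"],
                    role=s["role"],
                    expression=base / s["expression"],
                    dusk_hours=tuple(s["windows"]["dusk"]),
                    dawn_hours=tuple(s["windows"]["dawn"]),
                )
                for s in data["species"]
            )
            kwargs = {
                k: data[k]
                for k in (
                    "alpha", "rho_neg", "rho_pos", "min_mean_fpkm",
                    "max_zero_fraction", "normalization_scale", "rho_on",
                )
                if k in data
            }
            if "target_hours" in data:
                kwargs["target_hours"] = tuple(data["target_hours"])
            return cls(
                species=species,
                ortholog_groups=base / data["ortholog_groups"],
                output_dir=base / data.get("output_dir", "results"),
                **kwargs,
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing required key {exc}") from None

    def describe(self) -> dict:
        """JSON-serializable dump used for the manifest's config hash."""
        d = asdict(self)
        d["species"] = [
            {
                "id": s.id,
                "role": s.role,
                "expression": str(s.expression),
                "dusk_hours": list(s.dusk_hours),
                "dawn_hours": list(s.dawn_hours),
            }
            for s in self.species
        ]
        d["ortholog_groups"] = str(self.ortholog_groups)
        d["output_dir"] = str(self.output_dir)
        d["target_hours"] = list(self.target_hours)
        return d
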