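"""Synthetic multi-species diel expression studies with known ground truth.

The generator emulates the processed form of the real datasets the pipeline
consumes: non-negative FPKM profiles over one 24-h cycle, sampled every 2 h
for two species and every 4 h for the third, with gene-specific peak phase,
amplitude, and multiplicative (log-normal) noise:

    x_t = baseline * (1 + amplitude_ratio * (1 + cos(2*pi*(t - peak)/24)) / 2)
          * exp(eps_t),        eps_t ~ Normal(0, noise_sigma^2)

Each ortholog group gets one gene per species.  "Rescheduled" groups plant
the CAM gene's peak 12 h opposite the shared C3 peak; "conserved" groups give
all three species the C3 peak.  Additional background genes (not in any
group) draw their peak uniformly on [0, 24) so the transcriptome-wide
dusk/dawn balance against which single genes are tested is realistic and the
"neither" phase path is exercised.  A truth table records each group's
planted label, so end-to-end sensitivity/specificity are measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import DielMatrix, OrthologGroup, write_expression, write_ortholog_groups

__all__ = ["SyntheticSpec", "generate_profile", "generate_study", "write_study"]

GRID_2H = tuple(float(h) for h in range(0, 24, 2))
GRID_4H = tuple(float(h) for h in range(0, 24, 4))

#: Windows matching each default species' light regime: a 12-h photoperiod
#: for the CAM species and the interpolated C3 species (dusk 10/12/14), a
#: 10-h photoperiod for the 2-h C3 species (dusk 8/10/12); dawn is 22/0/2
#: everywhere (hour 24 == hour 0).
DEFAULT_WINDOWS: dict[str, dict[str, tuple[float, ...]]] = {
    "cam_kalanchoe": {"dusk": (10.0, 12.0, 14.0), "dawn": (22.0, 0.0, 2.0)},
    "c3_tomato": {"dusk": (8.0, 10.0, 12.0), "dawn": (22.0, 0.0, 2.0)},
    "c3_arabidopsis": {"dusk": (10.0, 12.0, 14.0), "dawn": (22.0, 0.0, 2.0)},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study; identical specs generate identical data.

    Defaults describe a study with 200 ortholog groups of which 20 are planted
    anti-phase (CAM peak at dusk, hour 12; C3 peak at dawn, hour 0), cosine
    amplitude 3× baseline, 20% multiplicative noise, and 300 uniform-phase
    background genes per species.
    """

    n_ogs: int = 200
    n_rescheduled: int = 20
    baseline: float = 10.0
    amplitude_ratio: float = 3.0
    noise_sigma: float = 0.2
    cam_species: str = "cam_kalanchoe"
    c3_species: tuple[str, str] = ("c3_tomato", "c3_arabidopsis")
    grids: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "cam_kalanchoe": GRID_2H,
            "c3_tomato": GRID_2H,
            "c3_arabidopsis": GRID_4H,
        }
    )
    cam_peak_hour: float = 12.0
    c3_peak_hour: float = 0.0
    n_background: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "c3_species", tuple(self.c3_species))
        object.__setattr__(
            self, "grids", {s: tuple(float(t) for t in g) for s, g in self.grids.items()}
        )
        if self.n_ogs <= 0:
            raise ValueError("n_ogs must be positive")
        if not 0 <= self.n_rescheduled <= self.n_ogs:
            raise ValueError(
                f"n_rescheduled={self.n_rescheduled} outside [0, n_ogs={self.n_ogs}]"
            )
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.amplitude_ratio < 0 or self.noise_sigma < 0:
            raise ValueError("amplitude_ratio and noise_sigma must be non-negative")
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        if len(self.c3_species) != 2:
            raise ValueError("exactly two C3 species are required")
        for sp in self.species:
            if sp not in self.grids:
                raise ValueError(f"no sampling grid for species {sp!r}")
        if self.n_rescheduled > 0:
            gap = (self.cam_peak_hour - self.c3_peak_hour) % 24.0
            if gap != 12.0:
                raise ValueError(
                    "planted rescheduled groups require CAM and C3 peaks 12 h apart "
                    f"(mod 24); got {gap} h"
                )

    @property
    def species(self) -> tuple[str, ...]:
        return (self.cam_species, *self.c3_species)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "c3_species" in data:
            data["c3_species"] = tuple(data["c3_species"])
        if "grids" in data:
            data["grids"] = {s: tuple(g) for s, g in data["grids"].items()}
        return cls(**data)


def generate_profile(
    peak_hour: float,
    baseline: float,
    amplitude_ratio: float,
    noise_sigma: float,
    grid: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gene's expression series on ``grid``: cosine shape × log-normal noise."""
    if len(grid) == 0:
        raise ValueError("empty sampling grid")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t = np.asarray(grid, dtype=float)
    # evaluate the cosine through the circular distance to the peak so that
    # hours equidistant from the peak give bit-identical values (exact ties);
    # mathematically identical to cos(2*pi*(t - peak)/24)
    dist = np.minimum((t - peak_hour) % 24.0, (peak_hour - t) % 24.0)
    shape = 1.0 + amplitude_ratio * (1.0 + np.cos(2.0 * np.pi * dist / 24.0)) / 2.0
    noise = np.exp(rng.normal(0.0, noise_sigma, size=t.shape)) if noise_sigma > 0 else 1.0
    return baseline * shape * noise


def generate_study(
    spec: SyntheticSpec,
) -> tuple[dict[str, DielMatrix], list[OrthologGroup], pd.DataFrame]:
    """Generate per-species matrices, ortholog groups, and the planted truth.

    Group ``i`` holds gene ``{species}_g{i:04d}`` in each species; the first
    ``n_rescheduled`` groups are planted anti-phase, the rest conserved.
    Background genes ``{species}_bg{j:04d}`` appear in no group.  Output is a
    deterministic function of ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    matrices: dict[str, DielMatrix] = {}
    for sp in spec.species:
        grid = spec.grids[sp]
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for i in range(spec.n_ogs):
            planted = i < spec.n_rescheduled
            peak = spec.cam_peak_hour if (planted and sp == spec.cam_species) else spec.c3_peak_hour
            gene_ids.append(f"{sp}_g{i:04d}")
            rows.append(
                generate_profile(
                    peak, spec.baseline, spec.amplitude_ratio, spec.noise_sigma, grid, rng
                )
            )
        for j in range(spec.n_background):
            peak = rng.uniform(0.0, 24.0)
            gene_ids.append(f"{sp}_bg{j:04d}")
            rows.append(
                generate_profile(
                    peak, spec.baseline, spec.amplitude_ratio, spec.noise_sigma, grid, rng
                )
            )
        matrices[sp] = DielMatrix(sp, grid, tuple(gene_ids), np.vstack(rows))

    groups = [
        OrthologGroup(
            f"OG{i:04d}", {sp: (f"{sp}_g{i:04d}",) for sp in spec.species}
        )
        for i in range(spec.n_ogs)
    ]
    truth = pd.DataFrame(
        {
            "og_id": [g.og_id for g in groups],
            "label": [
                "rescheduled" if i < spec.n_rescheduled else "conserved"
                for i in range(spec.n_ogs)
            ],
        }
    )
    return matrices, groups, truth


def write_study(
    spec: SyntheticSpec,
    outdir: str | Path,
    windows: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
) -> dict[str, Path]:
    """Write a study to disk plus a ready-to-run pipeline config.

    Produces ``<species>.expression.tsv`` per species, ``ortholog_groups.tsv``,
    ``truth.tsv`` and ``run.yaml`` (pointing at those files, with per-species
    dawn/dusk windows).  Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if windows is None:
        windows = {
            sp: DEFAULT_WINDOWS.get(sp, DEFAULT_WINDOWS["cam_kalanchoe"])
            for sp in spec.species
        }
    matrices, groups, truth = generate_study(spec)

    paths: dict[str, Path] = {}
    species_cfg = []
    for sp in spec.species:
        p = outdir / f"{sp}.expression.tsv"
        write_expression(matrices[sp], p)
        paths[f"expression:{sp}"] = p
        species_cfg.append(
            {
                "id": sp,
                "role": "cam" if sp == spec.cam_species else "c3",
                "expression": p.name,
                "windows": {
                    "dusk": [float(h) for h in windows[sp]["dusk"]],
                    "dawn": [float(h) for h in windows[sp]["dawn"]],
                },
            }
        )
    paths["ortholog_groups"] = outdir / "ortholog_groups.tsv"
    write_ortholog_groups(groups, paths["ortholog_groups"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)

    config = {
        "species": species_cfg,
        "ortholog_groups": "ortholog_groups.tsv",
        "output_dir": "results",
        "alpha": 0.05,
        "rho_neg": -0.6,
        "rho_pos": 0.6,
        "min_mean_fpkm": 0.01,
        "max_zero_fraction": 0.5,
        "normalization_scale": 1000,
        "rho_on": "raw",
        "target_hours": [float(h) for h in GRID_2H],
    }
    paths["config"] = outdir / "run.yaml"
    with paths["config"].open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
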