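"""Cross-species rescheduling verdicts for ortholog groups.

An ortholog group links one gene (or several) in the CAM species to genes in
each of two C3 species.  A gene trio (one gene per species) is called
*rescheduled* when

1. the CAM gene is significantly enriched in one window (dawn or dusk) while
   both C3 orthologs are enriched in the opposite window, and
2. the CAM gene's diel profile has Spearman rank correlation below ``rho_neg``
   (default −0.6) with both C3 profiles, while the two C3 profiles correlate
   above ``rho_pos`` (default 0.6) with each other.

"Opposite window" is resolved by label (dawn vs dusk), not by clock-hour
arithmetic, because the species' light regimes (and hence their window hours)
differ.  Groups with several genes per species are evaluated over every
(cam, c3_a, c3_b) combination; the group counts as rescheduled when at least
one combination passes, and every combination's evidence is emitted so
stricter rules can be applied downstream.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import DielMatrix, OrthologGroup
from .window_enrichment import EnrichmentCall

__all__ = [
    "ConstantSeriesError",
    "ReschedulingCall",
    "spearman_rho",
    "call_rescheduled",
    "OPPOSITE_WINDOW",
]

logger = logging.getLogger(__name__)

OPPOSITE_WINDOW = {"dawn": "dusk", "dusk": "dawn"}


class ConstantSeriesError(ValueError):
    """Spearman correlation is undefined when a series is constant."""


@dataclass(frozen=True)
class ReschedulingCall:
    """Verdict for one (CAM gene, C3 gene, C3 gene) combination of a group."""

    og_id: str
    cam_species: str
    cam_gene: str
    c3_genes: Mapping[str, str]
    cam_phase: str
    c3_phases: Mapping[str, str]
    rho_cam_c3: Mapping[str, float]
    rho_c3_c3: float
    criterion1_pass: bool
    criterion2_pass: bool
    rescheduled: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "c3_genes", dict(self.c3_genes))
        object.__setattr__(self, "c3_phases", dict(self.c3_phases))
        object.__setattr__(
            self, "rho_cam_c3", {s: float(r) for s, r in self.rho_cam_c3.items()}
        )
        if set(self.c3_genes) != set(self.c3_phases) or set(self.c3_genes) != set(self.rho_cam_c3):
            raise ValueError(f"{self.og_id}: inconsistent C3 species keys")
        if len(self.c3_genes) != 2:
            raise ValueError(f"{self.og_id}: expected exactly two C3 species")
        if self.rescheduled != (self.criterion1_pass and self.criterion2_pass):
            raise ValueError(
                f"{self.og_id}: rescheduled flag must equal criterion1 AND criterion2"
            )
        for r in (*self.rho_cam_c3.values(), self.rho_c3_c3):
            if not (-1.0 <= r <= 1.0):
                raise ValueError(f"{self.og_id}: correlation {r} outside [-1, 1]")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average (mid-) ranks for ties.

    The Pearson correlation of the two rank vectors, computed with exact
    integer arithmetic on doubled mid-ranks (mid-ranks are half-integers),
    so a perfect monotone relationship returns exactly ±1.  Raises
    :class:`ConstantSeriesError` for a constant input, where the statistic
    is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    n = int(x.size)
    rx = [int(r) for r in np.rint(2 * stats.rankdata(x))]
    ry = [int(r) for r in np.rint(2 * stats.rankdata(y))]
    num = n * sum(a * b for a, b in zip(rx, ry)) - sum(rx) * sum(ry)
    dx = n * sum(a * a for a in rx) - sum(rx) ** 2
    dy = n * sum(b * b for b in ry) - sum(ry) ** 2
    if num * num == dx * dy:
        return 1.0 if num > 0 else -1.0
    return float(np.clip(num / np.sqrt(dx) / np.sqrt(dy), -1.0, 1.0))


def call_rescheduled(
    og: OrthologGroup,
    calls: Mapping[str, Mapping[str, EnrichmentCall]],
    matrices: Mapping[str, DielMatrix],
    cam_species: str,
    c3_species: Sequence[str],
    rho_neg: float = -0.6,
    rho_pos: float = 0.6,
) -> list[ReschedulingCall]:
    """Evaluate every gene trio of one ortholog group.

    ``calls`` maps species -> gene -> :class:`EnrichmentCall`; ``matrices``
    holds the profiles used for the Spearman correlations (same sampling grid
    for all species).  A group missing any of the three species (or whose
    genes were all filtered out upstream) is skipped with a logged reason and
    yields no calls; a trio containing a constant profile is likewise skipped,
    since its correlation criterion is not evaluable.  Thresholds are strict
    inequalities: rho == rho_neg or rho == rho_pos fails.
    """
    c3_species = list(c3_species)
    if len(c3_species) != 2:
        raise ValueError(f"expected exactly two C3 species, got {c3_species}")
    grids = {matrices[s].timepoints for s in (cam_species, *c3_species) if s in matrices}
    if len(grids) > 1:
        raise ValueError("species matrices must share a common sampling grid")

    usable: dict[str, list[str]] = {}
    for sp in (cam_species, *c3_species):
        members = og.members.get(sp, ())
        present = [
            g for g in members
            if sp in matrices and g in matrices[sp] and g in calls.get(sp, {})
        ]
        if not present:
            reason = "species absent from group" if not members else "no member with expression data"
            logger.info("%s: skipped (%s: %s)", og.og_id, sp, reason)
            return []
        usable[sp] = present

    sp_a, sp_b = c3_species
    out: list[ReschedulingCall] = []
    for cam_gene, gene_a, gene_b in itertools.product(
        usable[cam_species], usable[sp_a], usable[sp_b]
    ):
        cam_phase = calls[cam_species][cam_gene].phase
        phase_a = calls[sp_a][gene_a].phase
        phase_b = calls[sp_b][gene_b].phase
        criterion1 = (
            cam_phase in OPPOSITE_WINDOW
            and phase_a == phase_b == OPPOSITE_WINDOW[cam_phase]
        )
        try:
            rho_a = spearman_rho(matrices[cam_species].row(cam_gene), matrices[sp_a].row(gene_a))
            rho_b = spearman_rho(matrices[cam_species].row(cam_gene), matrices[sp_b].row(gene_b))
            rho_ab = spearman_rho(matrices[sp_a].row(gene_a), matrices[sp_b].row(gene_b))
        except ConstantSeriesError:
            logger.info(
                "%s: combination (%s, %s, %s) skipped — constant profile, "
                "correlation criterion not evaluable", og.og_id, cam_gene, gene_a, gene_b,
            )
            continue
        criterion2 = rho_a < rho_neg and rho_b < rho_neg and rho_ab > rho_pos
        out.append(
            ReschedulingCall(
                og_id=og.og_id,
                cam_species=cam_species,
                cam_gene=cam_gene,
                c3_genes={sp_a: gene_a, sp_b: gene_b},
                cam_phase=cam_phase,
                c3_phases={sp_a: phase_a, sp_b: phase_b},
                rho_cam_c3={sp_a: rho_a, sp_b: rho_b},
                rho_c3_c3=rho_ab,
                criterion1_pass=criterion1,
                criterion2_pass=criterion2,
                rescheduled=criterion1 and criterion2,
            )
        )
    return out
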