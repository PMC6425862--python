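"""Expression-profile preprocessing ahead of the dawn/dusk enrichment test.

Stages, in pipeline order:

1. :func:`interpolate_timepoints` — bring a coarser sampling grid (the 4-h
   dataset) onto the common 2-h grid with a not-a-knot cubic spline.
2. :func:`remove_negative` — drop genes with any negative expression value.
3. :func:`filter_low_expression` — drop genes with mean FPKM below 0.01 or
   with at least half of their sampling points at zero.
4. :func:`normalize_diel` — convert each retained profile to integer
   pseudo-counts totalling a fixed scale (default 1000) via largest-remainder
   rounding, so the downstream exact test sees integer counts and only the
   within-gene shape of the profile matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .io_formats import DielMatrix, canonicalize_hour

__all__ = [
    "NormalizedProfile",
    "filter_low_expression",
    "remove_negative",
    "interpolate_timepoints",
    "normalize_diel",
    "rotate_profiles",
]

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class NormalizedProfile:
    """One gene's diel profile as integer pseudo-counts summing to ``scale``."""

    gene_id: str
    timepoints: tuple[float, ...]
    counts: np.ndarray
    scale: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if self.counts.shape != (len(self.timepoints),):
            raise ValueError("counts length must match timepoints")
        if (self.counts < 0).any():
            raise ValueError(f"{self.gene_id}: negative pseudo-count")
        if int(self.counts.sum()) != int(self.scale):
            raise ValueError(
                f"{self.gene_id}: counts sum {int(self.counts.sum())} != scale {self.scale}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NormalizedProfile):
            return NotImplemented
        return (
            self.gene_id == other.gene_id
            and self.timepoints == other.timepoints
            and self.scale == other.scale
            and np.array_equal(self.counts, other.counts)
        )


def filter_low_expression(
    m: DielMatrix, min_mean: float = 0.01, max_zero_fraction: float = 0.5
) -> DielMatrix:
    """Drop weakly/sporadically expressed genes.

    Retains exactly the genes with mean expression >= ``min_mean`` AND a
    fraction of zero-valued sampling points strictly below
    ``max_zero_fraction``; gene order is preserved.
    """
    if not (min_mean >= 0):
        raise ValueError(f"min_mean must be >= 0, got {min_mean}")
    if not (0 <= max_zero_fraction <= 1):
        raise ValueError(f"max_zero_fraction must be in [0, 1], got {max_zero_fraction}")
    if len(m.timepoints) == 0:
        raise ValueError("matrix has zero timepoints")
    means = m.values.mean(axis=1)
    zero_frac = (m.values == 0).mean(axis=1)
    keep = (means >= min_mean) & (zero_frac < max_zero_fraction)
    removed = int((~keep).sum())
    if removed:
        logger.info("%s: low-expression filter removed %d/%d genes",
                    m.species_id, removed, m.n_genes)
    return DielMatrix(
        m.species_id,
        m.timepoints,
        tuple(g for g, k in zip(m.gene_ids, keep) if k),
        m.values[keep],
    )


def remove_negative(m: DielMatrix) -> DielMatrix:
    """Drop genes having any negative expression value."""
    keep = (m.values >= 0).all(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("%s: removed %d genes with negative values", m.species_id, removed)
    return DielMatrix(
        m.species_id,
        m.timepoints,
        tuple(g for g, k in zip(m.gene_ids, keep) if k),
        m.values[keep],
    )


def interpolate_timepoints(
    m: DielMatrix,
    target_hours,
    return_clamp_count: bool = False,
):
    """Resample every gene onto ``target_hours`` with a not-a-knot cubic spline.

    ``target_hours`` must contain every original sampling hour; original hours
    keep their values bit-for-bit.  Inserted hours are spline interpolants
    (the not-a-knot boundary reproduces cubic polynomials exactly); inserted
    hours outside the sampled span are the natural polynomial extension of
    the boundary piece.  Negative interpolants at inserted hours are clamped
    to 0 so interpolation can never remove a gene downstream; the number of
    clamped cells is logged (and returned when ``return_clamp_count``).
    """
    if len(m.timepoints) < 4:
        raise ValueError("cubic interpolation needs at least 4 timepoints")
    target = tuple(canonicalize_hour(t) for t in target_hours)
    if len(set(target)) != len(target):
        raise ValueError("duplicate target hours")
    target = tuple(sorted(target))
    missing = sorted(set(m.timepoints) - set(target))
    if missing:
        raise ValueError(f"target grid missing original hour(s) {missing}")

    x = np.asarray(m.timepoints, dtype=float)
    spline = CubicSpline(x, m.values, axis=1, bc_type="not-a-knot", extrapolate=True)
    out = spline(np.asarray(target, dtype=float))

    source_pos = {t: i for i, t in enumerate(m.timepoints)}
    inserted = np.ones(len(target), dtype=bool)
    for j, t in enumerate(target):
        if t in source_pos:
            out[:, j] = m.values[:, source_pos[t]]  # preserve knots exactly
            inserted[j] = False

    neg = out[:, inserted] < 0
    clamped = int(neg.sum())
    if clamped:
        logger.info("%s: clamped %d negative interpolants to 0", m.species_id, clamped)
        block = out[:, inserted]
        block[neg] = 0.0
        out[:, inserted] = block

    result = DielMatrix(m.species_id, target, m.gene_ids, out)
    if return_clamp_count:
        return result, clamped
    return result


def normalize_diel(m: DielMatrix, scale: int = 1000) -> list[NormalizedProfile]:
    """Turn each gene's profile into integer pseudo-counts totalling ``scale``.

    counts_t = largest-remainder rounding of ``scale * x_t / sum(x)``, so the
    counts sum to ``scale`` exactly and depend only on the profile's shape
    (invariant under positive rescaling).  Remainder units go to the cells
    with the largest fractional parts, earlier timepoints first on exact ties.
    """
    scale = int(scale)
    if scale <= 0:
        raise ValueError(f"scale must be a positive integer, got {scale}")
    if (m.values < 0).any():
        bad = m.gene_ids[int(np.argmax((m.values < 0).any(axis=1)))]
        raise ValueError(f"negative expression for gene {bad!r}; run remove_negative first")
    totals = m.values.sum(axis=1)
    if (totals == 0).any():
        bad = m.gene_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"all-zero profile for gene {bad!r}; filter before normalizing")

    profiles = []
    n = len(m.timepoints)
    for gene, row, total in zip(m.gene_ids, m.values, totals):
        raw = scale * row / total
        base = np.floor(raw).astype(int)
        frac = raw - base
        remainder = scale - int(base.sum())
        # sort by fractional part descending, then timepoint index ascending
        order = np.lexsort((np.arange(n), -frac))
        base[order[:remainder]] += 1
        profiles.append(NormalizedProfile(gene, m.timepoints, base, scale))
    return profiles


def rotate_profiles(m: DielMatrix, shift_hours: float) -> DielMatrix:
    """Rotate every profile around the diel cycle by ``shift_hours``.

    The shifted grid must map onto itself modulo 24 (true for any uniform
    grid and a shift that is a multiple of its spacing).  Mainly used to
    exercise the dawn/dusk window symmetry.
    """
    shifted = [canonicalize_hour((t + shift_hours) % 24) for t in m.timepoints]
    order = np.argsort(shifted, kind="stable")
    return DielMatrix(
        m.species_id,
        tuple(shifted[i] for i in order),
        m.gene_ids,
        m.values[:, order],
    )
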