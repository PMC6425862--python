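"""Post-processing of literature-homology hits.

Hits come from a sequence-homology search whose results link each homologous
protein to text snippets from the publications mentioning it.  This module
reproduces the downstream filtering: keep hits that pass an E-value threshold
and whose snippets mention a stomata-related keyword; summarize kept hits per
species; and partition a well-annotated species' genes into annotated /
known / literature-mined categories to expose the "underexplored" set — genes
tied to stomatal biology only through the literature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import HitRecord

__all__ = [
    "DEFAULT_KEYWORDS",
    "DEFAULT_MAX_EVALUE",
    "CategoryPartition",
    "filter_hits",
    "summarize_by_species",
    "partition_categories",
]

DEFAULT_KEYWORDS = ("stomata", "guard cell")
DEFAULT_MAX_EVALUE = 1e-3


@dataclass(frozen=True)
class CategoryPartition:
    """Three-way overlap of gene categories, with the underexplored remainder.

    ``underexplored`` is the literature-mined set minus genes that are either
    functionally annotated (``go_set``) or already known key genes
    (``known_set``).
    """

    go_set: frozenset
    known_set: frozenset
    litmined_set: frozenset
    underexplored: frozenset = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "go_set", frozenset(self.go_set))
        object.__setattr__(self, "known_set", frozenset(self.known_set))
        object.__setattr__(self, "litmined_set", frozenset(self.litmined_set))
        object.__setattr__(
            self,
            "underexplored",
            self.litmined_set - (self.go_set | self.known_set),
        )

    def venn_sizes(self) -> dict[str, int]:
        """Sizes of all seven regions of the three-set Venn diagram."""
        g, k, l = self.go_set, self.known_set, self.litmined_set
        return {
            "go_only": len(g - k - l),
            "known_only": len(k - g - l),
            "litmined_only": len(l - g - k),
            "go_and_known": len((g & k) - l),
            "go_and_litmined": len((g & l) - k),
            "known_and_litmined": len((k & l) - g),
            "all_three": len(g & k & l),
        }


def _matches(snippets: Sequence[str], keywords: Sequence[str], regex: bool) -> bool:
    if regex:
        patterns = [re.compile(k, re.IGNORECASE) for k in keywords]
        return any(p.search(s) for s in snippets for p in patterns)
    lowered = [k.lower() for k in keywords]
    return any(k in s.lower() for s in snippets for k in lowered)


def filter_hits(
    records: Iterable[HitRecord],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    regex: bool = False,
) -> list[HitRecord]:
    """Keep hits passing the E-value cut whose snippets mention a keyword.

    Keyword matching is case-insensitive plain substring by default (so
    "stomata" also matches "stomatal"); with ``regex=True`` each keyword is
    treated as a case-insensitive regular expression.  Record order is
    preserved and records are never modified.
    """
    keywords = list(keywords)
    if not keywords:
        raise ValueError("at least one keyword is required")
    if not (max_evalue >= 0):
        raise ValueError(f"max_evalue must be non-negative, got {max_evalue}")
    return [
        r
        for r in records
        if r.evalue <= max_evalue and _matches(r.snippets, keywords, regex)
    ]


def summarize_by_species(
    records: Iterable[HitRecord], species_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-species hit totals: record multiplicity and distinct subjects.

    Returns a DataFrame with columns ``species``, ``total_hits`` (records,
    counting multiplicity) and ``unique_subjects`` (distinct subject IDs),
    sorted by species.  Every subject must be mapped or a ValueError lists
    the unmapped IDs.
    """
    records = list(records)
    unmapped = sorted({r.subject_id for r in records if r.subject_id not in species_of})
    if unmapped:
        raise ValueError(f"subject ID(s) not mapped to a species: {unmapped}")
    rows: dict[str, dict[str, set | int]] = {}
    for r in records:
        sp = species_of[r.subject_id]
        entry = rows.setdefault(sp, {"total": 0, "subjects": set()})
        entry["total"] += 1
        entry["subjects"].add(r.subject_id)
    return pd.DataFrame(
        [
            {
                "species": sp,
                "total_hits": entry["total"],
                "unique_subjects": len(entry["subjects"]),
            }
            for sp, entry in sorted(rows.items())
        ],
        columns=["species", "total_hits", "unique_subjects"],
    )


def partition_categories(
    go_set: Iterable[str], known_set: Iterable[str], litmined_set: Iterable[str]
) -> CategoryPartition:
    """Partition genes into annotated / known / literature-mined categories."""
    return CategoryPartition(frozenset(go_set), frozenset(known_set), frozenset(litmined_set))
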