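"""Readers and writers for every on-disk artifact the pipeline touches.

Formats (all UTF-8, plain text):

* Expression matrices: TSV, header ``gene_id<TAB>h0<TAB>h2...``, one row per
  gene.  Hours are "hours after the start of the light period"; hour 24 is
  canonicalized to hour 0 at parse time, and columns are stored in increasing
  hour order.
* Ortholog groups: long-format TSV with columns ``og_id``, ``species_id``,
  ``gene_id`` (one row per member gene).
* Homology hit records: JSON lines, one object per hit with keys
  ``query_id``, ``subject_id``, ``evalue``, ``snippets``, ``publication_ids``.
* Gene lists: one ID per line.
* Result tables (enrichment / rescheduling calls): TSV with a fixed column
  order; floating-point statistics are rendered at 6 significant digits.

Readers validate aggressively and never silently drop rows: any file that
violates a stated invariant raises :class:`FormatError` (malformed structure)
or :class:`ValueError` (bad cell value).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DielMatrix",
    "OrthologGroup",
    "HitRecord",
    "canonicalize_hour",
    "read_expression",
    "write_expression",
    "read_ortholog_groups",
    "write_ortholog_groups",
    "read_hits",
    "write_hits",
    "read_gene_list",
    "write_gene_list",
    "write_results",
    "read_enrichment_calls",
    "read_rescheduling_calls",
]


class FormatError(ValueError):
    """A file's structure violates the documented dialect."""


def canonicalize_hour(hour: float) -> float:
    """Map an hour label onto the canonical [0, 24) diel axis.

    Hour 24 denotes the same clock time as hour 0 (one full cycle later) and
    is stored as 0, so the dawn window {22, 24, 2} becomes {22, 0, 2}.
    """
    h = float(hour)
    if not math.isfinite(h):
        raise FormatError(f"hour {hour!r} is not finite")
    if h == 24.0:
        h = 0.0
    if not 0.0 <= h < 24.0:
        raise FormatError(f"hour {hour!r} outside [0, 24]")
    return h


def _format_float(v: float) -> str:
    return format(float(v), ".6g")


@dataclass(eq=False)
class DielMatrix:
    """One species' genes × ordered diel time points of expression values.

    ``timepoints`` are hours after the start of the light period, unique and
    strictly increasing (hour 24 canonicalized to 0 before construction).
    ``values`` is a ``(n_genes, n_timepoints)`` float array; negative entries
    are permitted here (some upstream sources contain them) and are handled
    by :func:`dielshift.preprocess.remove_negative`.
    """

    species_id: str
    timepoints: tuple[float, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = tuple(canonicalize_hour(t) for t in self.timepoints)
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D gene × timepoint grid")
        if self.values.shape != (len(self.gene_ids), len(self.timepoints)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.timepoints)} timepoints"
            )
        if len(set(self.timepoints)) != len(self.timepoints):
            raise FormatError("duplicate timepoints after canonicalization")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise FormatError("timepoints must be strictly increasing")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise FormatError(f"duplicate gene IDs: {dupes}")
        if any(not g for g in self.gene_ids):
            raise FormatError("empty gene ID")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def subset(self, gene_ids: Sequence[str]) -> "DielMatrix":
        idx = [self._index[g] for g in gene_ids]
        return DielMatrix(
            self.species_id, self.timepoints, tuple(gene_ids), self.values[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.timepoints)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DielMatrix):
            return NotImplemented
        return (
            self.species_id == other.species_id
            and self.timepoints == other.timepoints
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class OrthologGroup:
    """Mapping from one ortholog-group ID to per-species gene-ID lists."""

    og_id: str
    members: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        members = {str(s): tuple(str(g) for g in genes) for s, genes in self.members.items()}
        for species, genes in members.items():
            if not genes:
                raise FormatError(f"{self.og_id}: species {species!r} has no genes")
            if any(not g for g in genes):
                raise FormatError(f"{self.og_id}: empty gene ID for species {species!r}")
        object.__setattr__(self, "members", members)


@dataclass(frozen=True)
class HitRecord:
    """One literature-homology hit: an E-value plus free-text evidence."""

    query_id: str
    subject_id: str
    evalue: float
    snippets: tuple[str, ...] = ()
    publication_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "evalue", float(self.evalue))
        object.__setattr__(self, "snippets", tuple(str(s) for s in self.snippets))
        object.__setattr__(
            self, "publication_ids", tuple(str(p) for p in self.publication_ids)
        )
        if not (self.evalue >= 0):
            raise ValueError(f"negative E-value {self.evalue} for {self.query_id}")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _parse_hour_header(label: str) -> float:
    text = label.strip()
    if text[:1] in ("h", "H"):
        text = text[1:]
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"header column {label!r} does not parse as an hour") from None


def read_expression(path: str | Path, species_id: str | None = None) -> DielMatrix:
    """Read a genes × timepoints expression TSV into a :class:`DielMatrix`.

    The first header cell must be ``gene_id``; remaining header cells are
    hours, optionally prefixed with ``h``.  ``species_id`` defaults to the
    file's stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene_id column plus hour columns")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first header cell is {df.columns[0]!r}, not 'gene_id'")
    hours = [_parse_hour_header(c) for c in df.columns[1:]]
    gene_ids = df.iloc[:, 0].tolist()
    dupes = sorted(set(g for g in gene_ids if gene_ids.count(g) > 1)) if len(set(gene_ids)) != len(gene_ids) else []
    if dupes:
        raise FormatError(f"{path}: duplicate gene IDs: {dupes}")

    values = np.empty((len(gene_ids), len(hours)), dtype=float)
    for j, col in enumerate(df.columns[1:]):
        # float() round-trips repr() output exactly, unlike pandas' fast parser
        for i, cell in enumerate(df[col]):
            try:
                v = float(cell)
                if not math.isfinite(v):
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"{path}: cell at row {i + 2} (gene {gene_ids[i]!r}), "
                    f"column {col!r} is not a finite number: {cell!r}"
                ) from None
            values[i, j] = v

    canon = [canonicalize_hour(h) for h in hours]
    order = np.argsort(canon, kind="stable")
    return DielMatrix(
        species_id=species_id if species_id is not None else path.stem,
        timepoints=tuple(canon[i] for i in order),
        gene_ids=tuple(gene_ids),
        values=values[:, order],
    )


def _hour_label(h: float) -> str:
    return f"h{int(h)}" if float(h).is_integer() else f"h{h:g}"


def write_expression(m: DielMatrix, path: str | Path) -> None:
    """Write a :class:`DielMatrix` in the dialect :func:`read_expression` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(_hour_label(t) for t in m.timepoints) + "\n")
        for gene, row in zip(m.gene_ids, m.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# ortholog groups
# ---------------------------------------------------------------------------

_OG_COLUMNS = ("og_id", "species_id", "gene_id")


def read_ortholog_groups(path: str | Path) -> list[OrthologGroup]:
    """Read long-format ortholog groups; member lists preserve file order."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    missing = [c for c in _OG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    grouped: dict[str, dict[str, list[str]]] = {}
    for i, (og, sp, gene) in enumerate(zip(df["og_id"], df["species_id"], df["gene_id"])):
        if not gene:
            raise ValueError(f"{path}: empty gene_id cell at row {i + 2}")
        if not og or not sp:
            raise ValueError(f"{path}: empty og_id/species_id cell at row {i + 2}")
        grouped.setdefault(og, {}).setdefault(sp, []).append(gene)
    return [
        OrthologGroup(og, {s: tuple(g) for s, g in species.items()})
        for og, species in grouped.items()
    ]


def write_ortholog_groups(groups: Iterable[OrthologGroup], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_OG_COLUMNS) + "\n")
        for og in groups:
            for species, genes in og.members.items():
                for gene in genes:
                    fh.write(f"{og.og_id}\t{species}\t{gene}\n")


# ---------------------------------------------------------------------------
# homology hit records (JSON lines)
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> list[HitRecord]:
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: line {lineno} is not valid JSON: {exc}") from None
            try:
                records.append(
                    HitRecord(
                        query_id=obj["query_id"],
                        subject_id=obj["subject_id"],
                        evalue=obj["evalue"],
                        snippets=tuple(obj.get("snippets", ())),
                        publication_ids=tuple(obj.get("publication_ids", ())),
                    )
                )
            except KeyError as exc:
                raise FormatError(f"{path}: line {lineno} missing key {exc}") from None
    return records


def write_hits(records: Iterable[HitRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "query_id": r.query_id,
                        "subject_id": r.subject_id,
                        "evalue": r.evalue,
                        "snippets": list(r.snippets),
                        "publication_ids": list(r.publication_ids),
                    }
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    with Path(path).open("r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_ENRICHMENT_COLUMNS = (
    "gene_id", "dusk_sum", "dawn_sum",
    "p_dusk", "p_dawn", "q_dusk", "q_dawn", "phase",
)
_RESCHEDULING_COLUMNS = (
    "og_id", "cam_species", "cam_gene",
    "c3_species_a", "c3_gene_a", "c3_species_b", "c3_gene_b",
    "cam_phase", "c3_phase_a", "c3_phase_b",
    "rho_cam_a", "rho_cam_b", "rho_c3_c3",
    "criterion1", "criterion2", "rescheduled",
)


def _kind_of(call: object) -> str:
    # local imports avoid a circular dependency on the analysis modules
    from .window_enrichment import EnrichmentCall
    from .rescheduling import ReschedulingCall

    if isinstance(call, EnrichmentCall):
        return "enrichment"
    if isinstance(call, ReschedulingCall):
        return "rescheduling"
    raise TypeError(f"unsupported record type {type(call).__name__}")


def write_results(calls: Sequence[object], path: str | Path, kind: str | None = None) -> None:
    """Write a homogeneous list of enrichment or rescheduling calls as TSV.

    ``kind`` ("enrichment" | "rescheduling") is required for an empty list,
    which otherwise carries no type information; a non-empty list must be
    homogeneous or a :class:`TypeError` is raised.
    """
    calls = list(calls)
    if calls:
        kinds = {_kind_of(c) for c in calls}
        if len(kinds) > 1:
            raise TypeError(f"mixed record kinds in one table: {sorted(kinds)}")
        inferred = kinds.pop()
        if kind is not None and kind != inferred:
            raise TypeError(f"kind={kind!r} does not match records of kind {inferred!r}")
        kind = inferred
    if kind not in ("enrichment", "rescheduling"):
        raise TypeError("kind must be 'enrichment' or 'rescheduling' for an empty list")

    with Path(path).open("w", encoding="utf-8") as fh:
        if kind == "enrichment":
            fh.write("\t".join(_ENRICHMENT_COLUMNS) + "\n")
            for c in calls:
                fh.write(
                    "\t".join(
                        [
                            c.gene_id,
                            str(int(c.dusk_sum)),
                            str(int(c.dawn_sum)),
                            _format_float(c.p_dusk),
                            _format_float(c.p_dawn),
                            _format_float(c.q_dusk),
                            _format_float(c.q_dawn),
                            c.phase,
                        ]
                    )
                    + "\n"
                )
        else:
            fh.write("\t".join(_RESCHEDULING_COLUMNS) + "\n")
            for c in calls:
                sp_a, sp_b = sorted(c.c3_genes)
                fh.write(
                    "\t".join(
                        [
                            c.og_id,
                            c.cam_species,
                            c.cam_gene,
                            sp_a,
                            c.c3_genes[sp_a],
                            sp_b,
                            c.c3_genes[sp_b],
                            c.cam_phase,
                            c.c3_phases[sp_a],
                            c.c3_phases[sp_b],
                            _format_float(c.rho_cam_c3[sp_a]),
                            _format_float(c.rho_cam_c3[sp_b]),
                            _format_float(c.rho_c3_c3),
                            str(bool(c.criterion1_pass)).lower(),
                            str(bool(c.criterion2_pass)).lower(),
                            str(bool(c.rescheduled)).lower(),
                        ]
                    )
                    + "\n"
                )


def _read_result_frame(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", header=0, dtype=str, keep_default_na=False)
    if tuple(df.columns) != columns:
        raise FormatError(f"{path}: header {tuple(df.columns)} != expected {columns}")
    return df


def read_enrichment_calls(path: str | Path) -> list:
    from .window_enrichment import EnrichmentCall

    df = _read_result_frame(path, _ENRICHMENT_COLUMNS)
    return [
        EnrichmentCall(
            gene_id=r.gene_id,
            dusk_sum=int(r.dusk_sum),
            dawn_sum=int(r.dawn_sum),
            p_dusk=float(r.p_dusk),
            p_dawn=float(r.p_dawn),
            q_dusk=float(r.q_dusk),
            q_dawn=float(r.q_dawn),
            phase=r.phase,
        )
        for r in df.itertuples(index=False)
    ]


def read_rescheduling_calls(path: str | Path) -> list:
    from .rescheduling import ReschedulingCall

    df = _read_result_frame(path, _RESCHEDULING_COLUMNS)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            ReschedulingCall(
                og_id=r.og_id,
                cam_species=r.cam_species,
                cam_gene=r.cam_gene,
                c3_genes={r.c3_species_a: r.c3_gene_a, r.c3_species_b: r.c3_gene_b},
                cam_phase=r.cam_phase,
                c3_phases={r.c3_species_a: r.c3_phase_a, r.c3_species_b: r.c3_phase_b},
                rho_cam_c3={
                    r.c3_species_a: float(r.rho_cam_a),
                    r.c3_species_b: float(r.rho_cam_b),
                },
                rho_c3_c3=float(r.rho_c3_c3),
                criterion1_pass=r.criterion1 == "true",
                criterion2_pass=r.criterion2 == "true",
                rescheduled=r.rescheduled == "true",
            )
        )
    return out
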