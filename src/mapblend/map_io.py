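"""Reading and writing genetic maps and physical annotations.

The native exchange format is header-bearing delimited text (TSV by default;
the delimiter is sniffed, so CSV works too):

* genetic map:          ``marker_id  linkage_group  position_cM``
* physical annotations: ``marker_id  chromosome  position_bp`` (1-based)
* chromosome lengths:   ``chromosome  length_bp``

All structural invariants (unique marker ids, nonnegative finite positions,
sorted linkage groups) are enforced on read, so downstream code can assume
valid containers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

MAP_COLUMNS = ("marker_id", "linkage_group", "position_cM")
PHYS_COLUMNS = ("marker_id", "chromosome", "position_bp")
LENGTH_COLUMNS = ("chromosome", "length_bp")


class MapFormatError(ValueError):
    """A file violates the genetic-map / annotation format contract."""


@dataclass(frozen=True)
class MarkerRecord:
    """One marker on one linkage group at a genetic position in centimorgans."""

    marker_id: str
    linkage_group: str
    position_cM: float

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise MapFormatError("empty marker_id")
        if not (math.isfinite(self.position_cM) and self.position_cM >= 0):
            raise MapFormatError(
                f"marker {self.marker_id!r}: position_cM must be finite and >= 0, "
                f"got {self.position_cM!r}"
            )


@dataclass
class LinkageGroupMap:
    """All markers of one linkage group, sorted by genetic position."""

    label: str
    records: list[MarkerRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.linkage_group != self.label:
                raise MapFormatError(
                    f"record {r.marker_id!r} carries group {r.linkage_group!r}, "
                    f"expected {self.label!r}"
                )
        seen: set[str] = set()
        for r in self.records:
            if r.marker_id in seen:
                raise MapFormatError(f"duplicate marker_id {r.marker_id!r}")
            seen.add(r.marker_id)
        # stable sort keeps input order within co-segregating bins
        self.records.sort(key=lambda r: r.position_cM)

    @property
    def n_markers(self) -> int:
        return len(self.records)

    def positions(self) -> list[float]:
        return [r.position_cM for r in self.records]

    def marker_ids(self) -> list[str]:
        return [r.marker_id for r in self.records]

    def position_of(self, marker_id: str) -> float:
        for r in self.records:
            if r.marker_id == marker_id:
                return r.position_cM
        raise KeyError(marker_id)


@dataclass
class GeneticMap:
    """A named genetic map: an ordered collection of linkage groups."""

    name: str
    groups: dict[str, LinkageGroupMap] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, lg in self.groups.items():
            if label != lg.label:
                raise MapFormatError(f"group keyed {label!r} labelled {lg.label!r}")
            for r in lg.records:
                if r.marker_id in seen:
                    raise MapFormatError(
                        f"duplicate marker_id {r.marker_id!r} across groups"
                    )
                seen.add(r.marker_id)

    def __len__(self) -> int:
        return sum(lg.n_markers for lg in self.groups.values())

    def __iter__(self) -> Iterator[MarkerRecord]:
        for lg in self.groups.values():
            yield from lg.records

    def marker_ids(self) -> set[str]:
        return {r.marker_id for r in self}

    def group_of(self, marker_id: str) -> str:
        for label, lg in self.groups.items():
            if any(r.marker_id == marker_id for r in lg.records):
                return label
        raise KeyError(marker_id)


@dataclass
class PhysicalAnnotationSet:
    """marker_id -> (chromosome, 1-based bp position) on the reference genome."""

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker, (chrom, bp) in self.entries.items():
            if bp < 1:
                raise MapFormatError(
                    f"marker {marker!r}: position_bp must be >= 1 (1-based), got {bp}"
                )
            if not chrom:
                raise MapFormatError(f"marker {marker!r}: empty chromosome label")

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def chromosome_of(self, marker_id: str) -> str:
        return self.entries[marker_id][0]

    def bp_of(self, marker_id: str) -> int:
        return self.entries[marker_id][1]


def _read_table(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        raise MapFormatError(f"{path}: empty file") from None
    except csv.Error:
        # the sniffer cannot find a delimiter in header-only/one-column files
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            raise MapFormatError(f"{path}: empty file") from None
    if df.empty:
        raise MapFormatError(f"{path}: no data rows")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MapFormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df[list(columns)]


def read_genetic_map(path: str | Path, name: str | None = None) -> GeneticMap:
    """Read a delimited genetic-map table into a validated :class:`GeneticMap`.

    Raises :class:`MapFormatError` on duplicate markers (naming the marker),
    on negative or non-numeric cM values (naming the data line), and on empty
    files.
    """
    path = Path(path)
    df = _read_table(path, MAP_COLUMNS)
    if name is None:
        name = path.stem
    records: list[MarkerRecord] = []
    seen: dict[str, int] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        marker = str(row.marker_id)
        if marker in seen:
            raise MapFormatError(
                f"{path}: duplicate marker_id {marker!r} (lines {seen[marker]} and {idx})"
            )
        seen[marker] = idx
        try:
            pos = float(row.position_cM)
        except (TypeError, ValueError):
            raise MapFormatError(
                f"{path} line {idx}: non-numeric position_cM {row.position_cM!r}"
            ) from None
        if not (math.isfinite(pos) and pos >= 0):
            raise MapFormatError(
                f"{path} line {idx}: position_cM must be finite and >= 0, got {pos}"
            )
        records.append(MarkerRecord(marker, str(row.linkage_group), pos))
    groups: dict[str, list[MarkerRecord]] = {}
    for r in records:
        groups.setdefault(r.linkage_group, []).append(r)
    return GeneticMap(
        name=name,
        groups={label: LinkageGroupMap(label, recs) for label, recs in groups.items()},
    )


def read_physical_annotations(path: str | Path) -> PhysicalAnnotationSet:
    """Read marker physical annotations (chromosome, 1-based bp)."""
    path = Path(path)
    df = _read_table(path, PHYS_COLUMNS)
    entries: dict[str, tuple[str, int]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        marker = str(row.marker_id)
        if marker in entries:
            raise MapFormatError(f"{path}: duplicate marker_id {marker!r}")
        try:
            bp = int(row.position_bp)
        except (TypeError, ValueError):
            raise MapFormatError(
                f"{path} line {idx}: non-integer position_bp {row.position_bp!r}"
            ) from None
        if bp < 1:
            raise MapFormatError(
                f"{path} line {idx}: position_bp must be >= 1 (1-based), got {bp}"
            )
        entries[marker] = (str(row.chromosome), bp)
    return PhysicalAnnotationSet(entries)


def read_chromosome_lengths(path: str | Path) -> dict[str, int]:
    """Read chromosome lengths (bp) as a plain mapping."""
    df = _read_table(path, LENGTH_COLUMNS)
    lengths: dict[str, int] = {}
    for row in df.itertuples(index=False):
        length = int(row.length_bp)
        if length < 1:
            raise MapFormatError(f"chromosome {row.chromosome!r}: length_bp must be >= 1")
        lengths[str(row.chromosome)] = length
    return lengths


def write_map_table(gmap: GeneticMap, path: str | Path, decimals: int = 6) -> None:
    """Write a genetic map as TSV; round-trips through :func:`read_genetic_map`.

    Empty linkage groups are omitted with a logged warning. Positions are
    formatted with ``decimals`` digits (default 6, matching the 1e-6 cM
    round-trip tolerance).
    """
    path = Path(path)
    rows = []
    for label, lg in gmap.groups.items():
        if not lg.records:
            logger.warning("map %s: omitting empty linkage group %s", gmap.name, label)
            continue
        for r in lg.records:
            rows.append((r.marker_id, label, f"{r.position_cM:.{decimals}f}"))
    with open(path, "w") as fh:
        fh.write("\t".join(MAP_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_physical_annotations(ann: PhysicalAnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PHYS_COLUMNS) + "\n")
        for marker, (chrom, bp) in ann.entries.items():
            fh.write(f"{marker}\t{chrom}\t{bp}\n")


def write_chromosome_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LENGTH_COLUMNS) + "\n")
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_genetic_map_xlsx(
    path: str | Path,
    name: str | None = None,
    *,
    sheet: int | str = 0,
    column_map: Mapping[str, str] | None = None,
) -> GeneticMap:
    """Read a genetic map from a spreadsheet (optional ``xlsx`` extra).

    ``column_map`` maps the spreadsheet's column headers onto the native
    ``marker_id`` / ``linkage_group`` / ``position_cM`` names, since published
    supplementary tables rarely use a fixed layout.
    """
    try:
        import openpyxl  # noqa: F401
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading .xlsx maps requires the 'xlsx' extra (openpyxl)") from exc
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise MapFormatError(f"{path}: missing column(s) {missing} after renaming")
    if name is None:
        name = Path(path).stem
    records: dict[str, list[MarkerRecord]] = {}
    seen: set[str] = set()
    for row in df[list(MAP_COLUMNS)].itertuples(index=False):
        marker = str(row.marker_id)
        if marker in seen:
            raise MapFormatError(f"{path}: duplicate marker_id {marker!r}")
        seen.add(marker)
        rec = MarkerRecord(marker, str(row.linkage_group), float(row.position_cM))
        records.setdefault(rec.linkage_group, []).append(rec)
    return GeneticMap(
        name=name,
        groups={label: LinkageGroupMap(label, recs) for label, recs in records.items()},
    )


def maps_equal(a: GeneticMap, b: GeneticMap, tol_cM: float = 1e-6) -> bool:
    """Structural equality up to a cM tolerance (used by round-trip tests)."""
    if set(a.groups) != set(b.groups):
        return False
    for label, lga in a.groups.items():
        lgb = b.groups[label]
        if lga.marker_ids() != lgb.marker_ids():
            return False
        for ra, rb in zip(lga.records, lgb.records):
            if abs(ra.position_cM - rb.position_cM) > tol_cM:
                return False
    return True
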