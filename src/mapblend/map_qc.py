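"""Per-map QC: marker binning, collinearity filtering, and map statistics.

Co-segregating markers (identical genetic position) are grouped into bins.
Markers whose genetic order disagrees with their physical (bp) order on the
assigned chromosome are removed at bin granularity: the filter keeps a
longest strictly-increasing-in-bp subsequence of bins taken in cM order and
removes the complement, which is a minimum-size removal set. Map statistics
follow the usual linkage-map summaries: genetic length, unique positions
(bins), largest gap, marker density (cM per unique position), physical span,
coverage and the cM/Mb recombination-rate ratio.
"""

from __future__ import annotations

import statistics
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .map_io import GeneticMap, LinkageGroupMap, PhysicalAnnotationSet

BIN_TOL_CM = 1e-6  # exact-equality intent; guards float round-trips


@dataclass
class MarkerBin:
    """Markers sharing one genetic position (within 1e-6 cM)."""

    position_cM: float
    member_ids: list[str]


@dataclass
class CollinearityReport:
    """Outcome of filtering one linkage group against physical order."""

    group: str
    lg_chromosome: str
    removed_ids: set[str] = field(default_factory=set)
    kept_count: int = 0


def bin_markers(lg: LinkageGroupMap, tol_cM: float = BIN_TOL_CM) -> list[MarkerBin]:
    """Group co-segregating markers into position bins, sorted by position."""
    bins: list[MarkerBin] = []
    for rec in lg.records:
        if bins and abs(rec.position_cM - bins[-1].position_cM) <= tol_cM:
            bins[-1].member_ids.append(rec.marker_id)
        else:
            bins.append(MarkerBin(rec.position_cM, [rec.marker_id]))
    return bins


def assign_chromosome(lg: LinkageGroupMap, annotations: PhysicalAnnotationSet) -> str:
    """Chromosome carrying a strict majority of the group's annotated markers."""
    counts = Counter(
        annotations.chromosome_of(r.marker_id)
        for r in lg.records
        if r.marker_id in annotations
    )
    if not counts:
        raise ValueError(f"group {lg.label}: no marker has a physical annotation")
    total = sum(counts.values())
    chrom, top = counts.most_common(1)[0]
    if 2 * top <= total:
        raise ValueError(
            f"group {lg.label}: no strict majority chromosome among {dict(counts)}"
        )
    return chrom


def longest_increasing_indices(values: list[float]) -> list[int]:
    """Indices of a longest strictly increasing subsequence.

    Patience sorting with smallest-tail reconstruction: deterministic among
    the (generally non-unique) maximal subsequences.
    """
    tails: list[float] = []  # smallest tail value of each pile
    tail_idx: list[int] = []  # index of the element currently topping each pile
    pred = [-1] * len(values)
    for i, v in enumerate(values):
        pile = bisect_left(tails, v)
        if pile == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[pile] = v
            tail_idx[pile] = i
        pred[i] = tail_idx[pile - 1] if pile > 0 else -1
    out: list[int] = []
    i = tail_idx[-1] if tail_idx else -1
    while i != -1:
        out.append(i)
        i = pred[i]
    return out[::-1]


def _bin_bp(
    b: MarkerBin, annotations: PhysicalAnnotationSet, chromosome: str
) -> float | None:
    """Median bp of a bin's members annotated on the assigned chromosome."""
    bps = [
        annotations.bp_of(m)
        for m in b.member_ids
        if m in annotations and annotations.chromosome_of(m) == chromosome
    ]
    return statistics.median(bps) if bps else None


def filter_noncollinear(
    lg: LinkageGroupMap,
    annotations: PhysicalAnnotationSet,
    chromosome: str | None = None,
) -> tuple[LinkageGroupMap, CollinearityReport]:
    """Remove bins whose physical order disagrees with the genetic order.

    Operates at bin granularity (bin bp = median of members' bp): in cM
    order, a longest strictly-increasing-in-bp subsequence of annotated bins
    is kept and the complement removed, whole bins at a time - a minimum-size
    removal. Bins with no member annotated on the group's chromosome pass
    through untested (SSR / morphological markers are never removed).
    """
    if chromosome is None:
        chromosome = assign_chromosome(lg, annotations)
    bins = bin_markers(lg)
    annotated = [(k, bp) for k, b in enumerate(bins)
                 if (bp := _bin_bp(b, annotations, chromosome)) is not None]
    keep_rel = set(longest_increasing_indices([bp for _, bp in annotated]))
    removed_bins = {annotated[r][0] for r in range(len(annotated)) if r not in keep_rel}
    removed_ids = {m for k in removed_bins for m in bins[k].member_ids}
    kept_records = [r for r in lg.records if r.marker_id not in removed_ids]
    report = CollinearityReport(
        group=lg.label,
        lg_chromosome=chromosome,
        removed_ids=removed_ids,
        kept_count=len(kept_records),
    )
    return LinkageGroupMap(lg.label, kept_records), report


def filter_map(
    gmap: GeneticMap, annotations: PhysicalAnnotationSet
) -> tuple[GeneticMap, dict[str, CollinearityReport]]:
    """Apply :func:`filter_noncollinear` to every linkage group of a map."""
    groups: dict[str, LinkageGroupMap] = {}
    reports: dict[str, CollinearityReport] = {}
    for label, lg in gmap.groups.items():
        filtered, rep = filter_noncollinear(lg, annotations)
        groups[label] = filtered
        reports[label] = rep
    return GeneticMap(gmap.name, groups), reports


def marker_density(length_cM: float, n_positions: int) -> float:
    """Average distance in cM between unique map positions."""
    if n_positions <= 0:
        return 0.0
    return length_cM / n_positions


def recombination_ratio(length_cM: float, span_Mb: float) -> float:
    """cM/Mb ratio: genetic length over the physical span covered by markers."""
    return length_cM / span_Mb


def compute_stats(
    gmap: GeneticMap,
    annotations: PhysicalAnnotationSet | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-group and total map statistics as a DataFrame (index = group, 'total').

    Columns: n_markers, n_bins, length_cM, largest_gap_cM, density_cM,
    physical_span_Mb, coverage_pct, ratio_cM_per_Mb. Physical columns are NaN
    for groups without annotations (or when ``annotations`` is None);
    coverage additionally needs ``chrom_lengths``.
    """
    if not gmap.groups or all(not lg.records for lg in gmap.groups.values()):
        raise ValueError(f"map {gmap.name}: empty map")
    rows = {}
    for label, lg in gmap.groups.items():
        if not lg.records:
            continue
        bins = bin_markers(lg)
        positions = [b.position_cM for b in bins]
        length = positions[-1] - positions[0]
        gap = max(np.diff(positions)) if len(positions) > 1 else 0.0
        row = {
            "n_markers": lg.n_markers,
            "n_bins": len(bins),
            "length_cM": length,
            "largest_gap_cM": float(gap),
            "density_cM": marker_density(length, len(bins)),
            "physical_span_Mb": np.nan,
            "coverage_pct": np.nan,
            "ratio_cM_per_Mb": np.nan,
        }
        if annotations is not None:
            try:
                chrom = assign_chromosome(lg, annotations)
            except ValueError:
                chrom = None
            if chrom is not None:
                bps = [
                    annotations.bp_of(r.marker_id)
                    for r in lg.records
                    if r.marker_id in annotations
                    and annotations.chromosome_of(r.marker_id) == chrom
                ]
                span_bp = max(bps) - min(bps)
                row["physical_span_Mb"] = span_bp / 1e6
                if span_bp > 0:
                    row["ratio_cM_per_Mb"] = recombination_ratio(length, span_bp / 1e6)
                if chrom_lengths and chrom in chrom_lengths:
                    row["coverage_pct"] = 100.0 * span_bp / chrom_lengths[chrom]
                row["_chrom"] = chrom
                row["_span_bp"] = span_bp
        rows[label] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    total = {
        "n_markers": int(df["n_markers"].sum()),
        "n_bins": int(df["n_bins"].sum()),
        "length_cM": float(df["length_cM"].sum()),
        "largest_gap_cM": float(df["largest_gap_cM"].max()),
        "density_cM": marker_density(float(df["length_cM"].sum()), int(df["n_bins"].sum())),
        "physical_span_Mb": float(df["physical_span_Mb"].sum(skipna=True))
        if df["physical_span_Mb"].notna().any()
        else np.nan,
        "coverage_pct": np.nan,
        "ratio_cM_per_Mb": np.nan,
    }
    if "_span_bp" in df.columns and chrom_lengths:
        covered = df.dropna(subset=["_span_bp"])
        tot_len = sum(
            chrom_lengths[c] for c in covered["_chrom"] if c in chrom_lengths
        )
        if tot_len > 0:
            total["coverage_pct"] = 100.0 * covered["_span_bp"].sum() / tot_len
    if np.isfinite(total["physical_span_Mb"]) and total["physical_span_Mb"] > 0:
        total["ratio_cM_per_Mb"] = recombination_ratio(
            total["length_cM"], total["physical_span_Mb"]
        )
    df = df.drop(columns=[c for c in ("_chrom", "_span_bp") if c in df.columns])
    df.loc["total"] = pd.Series(total)
    df.index.name = "group"
    return df
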