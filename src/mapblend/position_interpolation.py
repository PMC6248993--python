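"""Estimate genetic positions (cM) for unmapped markers from physical position.

For a marker at ``snp_bp`` between two mapped markers of a consensus linkage
group, the estimate is the linear interpolation

    delta_bp    = snp2_bp - snp1_bp
    delta_cM    = snp2_cM - snp1_cM
    cM_estimate = snp1_cM + delta_cM * (snp_bp - snp1_bp) / delta_bp

Beyond the last mapped marker, delta_cM is taken from the last two mapped
markers and snp2_bp becomes the chromosome (scaffold) end. Before the first
mapped marker the rule is mirrored with the first two markers and
snp1_bp = 1, clamping estimates at 0 cM. A query landing exactly on a mapped
marker returns that marker's consensus position directly.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass

import pandas as pd

from .map_io import GeneticMap, LinkageGroupMap, PhysicalAnnotationSet
from .map_qc import assign_chromosome

logger = logging.getLogger(__name__)

INTERPOLATED = "interpolated"
EXTRAPOLATED_END = "extrapolated_end"
EXTRAPOLATED_START = "extrapolated_start"
MAPPED = "mapped"
UNPLACED = "unplaced"


@dataclass(frozen=True)
class FlankingPair:
    """The two reference points used for one estimate."""

    snp1_bp: int
    snp1_cM: float
    snp2_bp: int
    snp2_cM: float

    @property
    def delta_bp(self) -> int:
        return self.snp2_bp - self.snp1_bp

    @property
    def delta_cM(self) -> float:
        return self.snp2_cM - self.snp1_cM


@dataclass(frozen=True)
class InterpolationResult:
    marker_id: str
    chromosome: str
    snp_bp: int
    cM_estimate: float | None
    method: str


def mapped_reference(
    lg: LinkageGroupMap, annotations: PhysicalAnnotationSet, chromosome: str
) -> list[tuple[int, float]]:
    """(bp, cM) of the group's annotated markers, sorted by bp, unique bp."""
    pts: dict[int, float] = {}
    for r in lg.records:
        if r.marker_id in annotations and annotations.chromosome_of(r.marker_id) == chromosome:
            pts.setdefault(annotations.bp_of(r.marker_id), r.position_cM)
    return sorted(pts.items())


def find_flanking(
    reference: list[tuple[int, float]], snp_bp: int, chrom_length: int
) -> tuple[FlankingPair | None, str, float | None]:
    """Locate the flanking pair for a query bp.

    Returns ``(pair, method, exact_cM)``; for a query that coincides with a
    mapped marker, ``pair`` is None and ``exact_cM`` carries the answer.
    """
    if len(reference) < 2:
        raise ValueError("need at least 2 mapped, annotated markers on the group")
    if not 1 <= snp_bp <= chrom_length:
        raise ValueError(f"snp_bp {snp_bp} outside [1, {chrom_length}]")
    bps = [bp for bp, _ in reference]
    k = bisect_left(bps, snp_bp)
    if k < len(bps) and bps[k] == snp_bp:
        return None, MAPPED, reference[k][1]
    if k == 0:  # before the first mapped marker: mirrored end rule
        (bp1, cm1), (bp2, cm2) = reference[0], reference[1]
        delta = cm2 - cm1
        return FlankingPair(1, cm1 - delta, bp1, cm1), EXTRAPOLATED_START, None
    if k == len(bps):  # beyond the last mapped marker: scaffold-end rule
        (bpm1, cmm1), (bpl, cml) = reference[-2], reference[-1]
        delta = cml - cmm1
        return FlankingPair(bpl, cml, chrom_length, cml + delta), EXTRAPOLATED_END, None
    (bp1, cm1), (bp2, cm2) = reference[k - 1], reference[k]
    return FlankingPair(bp1, cm1, bp2, cm2), INTERPOLATED, None


def estimate_position(snp_bp: int, pair: FlankingPair) -> float:
    """Apply the interpolation formula; estimates are clamped at 0 cM."""
    if pair.delta_bp <= 0:
        raise ValueError(f"flanking pair has delta_bp {pair.delta_bp} <= 0")
    if not pair.snp1_bp <= snp_bp <= pair.snp2_bp:
        raise ValueError(
            f"snp_bp {snp_bp} outside flank interval [{pair.snp1_bp}, {pair.snp2_bp}]"
        )
    est = pair.snp1_cM + pair.delta_cM * (snp_bp - pair.snp1_bp) / pair.delta_bp
    return max(est, 0.0)


def estimate_one(
    reference: list[tuple[int, float]], snp_bp: int, chrom_length: int
) -> tuple[float, str]:
    pair, method, exact = find_flanking(reference, snp_bp, chrom_length)
    if method == MAPPED:
        return float(exact), method
    return estimate_position(snp_bp, pair), method


def estimate_all_unmapped(
    unmapped: pd.DataFrame,
    consensus: GeneticMap,
    annotations: PhysicalAnnotationSet,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Estimate positions for a table of (marker_id, chromosome, position_bp).

    Returns one row per marker sorted by chromosome then bp, with columns
    ``linkage_group``, ``cM_estimate`` and ``method``; markers on a
    chromosome without a consensus group get an empty estimate and a logged
    warning.
    """
    chrom_to_group: dict[str, tuple[str, list[tuple[int, float]]]] = {}
    for label, lg in consensus.groups.items():
        try:
            chrom = assign_chromosome(lg, annotations)
        except ValueError:
            continue
        chrom_to_group[chrom] = (label, mapped_reference(lg, annotations, chrom))
    rows = []
    for row in unmapped.itertuples(index=False):
        chrom = str(row.chromosome)
        bp = int(row.position_bp)
        if chrom not in chrom_to_group:
            logger.warning(
                "marker %s: chromosome %s has no consensus group", row.marker_id, chrom
            )
            rows.append((row.marker_id, chrom, bp, None, None, UNPLACED))
            continue
        label, reference = chrom_to_group[chrom]
        length = chrom_lengths.get(chrom, max(bp, reference[-1][0]))
        est, method = estimate_one(reference, bp, length)
        rows.append((row.marker_id, chrom, bp, label, est, method))
    out = pd.DataFrame(
        rows,
        columns=["marker_id", "chromosome", "position_bp", "linkage_group",
                 "cM_estimate", "method"],
    )
    return out.sort_values(["chromosome", "position_bp"], kind="stable").reset_index(
        drop=True
    )
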