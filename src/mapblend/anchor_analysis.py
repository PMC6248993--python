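"""Marker sharing between maps: anchor points and common-marker counts.

An *anchor point* is one marker shared by one pair of maps on the same
linkage group: a marker present in k maps contributes k(k-1)/2 anchor points
but counts once as a common marker. This is the only definition under which
the total number of anchor points exceeds the number of common markers, as
observed in multi-population map studies. Markers shared under conflicting
group labels are excluded from all counts and reported separately.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import pandas as pd

from .map_io import GeneticMap

logger = logging.getLogger(__name__)


@dataclass
class AnchorMatrix:
    """Pairwise anchor-point counts and per-group common-marker totals."""

    map_names: list[str]
    group_labels: list[str]
    # (map_i, map_j, group) -> count, with map_i before map_j in input order
    pair_lg_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    pair_totals: dict[tuple[str, str], int] = field(default_factory=dict)
    lg_anchor_totals: dict[str, int] = field(default_factory=dict)
    lg_common_markers: dict[str, int] = field(default_factory=dict)
    total_common_markers: int = 0
    total_anchor_points: int = 0
    # markers excluded because their group label differs between maps:
    # marker -> {map_name: group}
    conflicts: dict[str, dict[str, str]] = field(default_factory=dict)

    def pair_count(self, a: str, b: str, group: str | None = None) -> int:
        """Symmetric accessor for a pair's anchor count (one group or total)."""
        i, j = sorted((a, b), key=self.map_names.index)
        if group is None:
            return self.pair_totals.get((i, j), 0)
        return self.pair_lg_counts.get((i, j, group), 0)

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped report: one row per map pair, one column per group."""
        rows = []
        for (i, j), total in self.pair_totals.items():
            row = {"pair": f"{i} vs. {j}"}
            for g in self.group_labels:
                row[g] = self.pair_lg_counts.get((i, j, g), 0)
            row["anchors_per_pair"] = total
            rows.append(row)
        df = pd.DataFrame(rows)
        anchors = {"pair": "anchors_per_group"}
        common = {"pair": "common_markers"}
        for g in self.group_labels:
            anchors[g] = self.lg_anchor_totals.get(g, 0)
            common[g] = self.lg_common_markers.get(g, 0)
        anchors["anchors_per_pair"] = self.total_anchor_points
        common["anchors_per_pair"] = self.total_common_markers
        return pd.concat(
            [df, pd.DataFrame([anchors, common])], ignore_index=True
        )


def count_anchors(maps: Sequence[GeneticMap]) -> AnchorMatrix:
    """Count anchor points and common markers across >= 2 maps."""
    if len(maps) < 2:
        raise ValueError("anchor analysis requires at least 2 maps")
    names = [m.name for m in maps]
    if len(set(names)) != len(names):
        raise ValueError(f"map names must be unique, got {names}")

    marker_locs: dict[str, dict[str, str]] = defaultdict(dict)  # marker -> map -> group
    group_labels: list[str] = []
    for m in maps:
        for label, lg in m.groups.items():
            if label not in group_labels:
                group_labels.append(label)
            for r in lg.records:
                marker_locs[r.marker_id][m.name] = label

    out = AnchorMatrix(map_names=names, group_labels=group_labels)
    for marker, locs in marker_locs.items():
        if len(locs) < 2:
            continue
        if len(set(locs.values())) > 1:
            out.conflicts[marker] = dict(locs)
            logger.warning(
                "marker %s excluded: conflicting linkage groups %s", marker, locs
            )
            continue
        group = next(iter(locs.values()))
        out.total_common_markers += 1
        out.lg_common_markers[group] = out.lg_common_markers.get(group, 0) + 1
        for a, b in combinations(sorted(locs, key=names.index), 2):
            out.pair_lg_counts[(a, b, group)] = out.pair_lg_counts.get((a, b, group), 0) + 1
            out.pair_totals[(a, b)] = out.pair_totals.get((a, b), 0) + 1
            out.lg_anchor_totals[group] = out.lg_anchor_totals.get(group, 0) + 1
            out.total_anchor_points += 1
    # make every pair present, even when it shares nothing
    for a, b in combinations(names, 2):
        out.pair_totals.setdefault((a, b), 0)
    return out
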