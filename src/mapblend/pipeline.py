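"""End-to-end orchestration: QC -> anchors -> merge -> interpolation.

``run_pipeline`` reads the input maps, filters non-collinear markers, counts
anchors, builds the consensus for every K in the grid, selects the lowest-RMSE
candidate and (optionally) interpolates unmapped markers, writing one TSV
report per stage plus a run manifest. Reports are byte-identical across runs
with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .anchor_analysis import count_anchors
from .consensus_merge import MergeConfig, select_consensus
from .map_io import (
    GeneticMap,
    LinkageGroupMap,
    read_chromosome_lengths,
    read_genetic_map,
    read_physical_annotations,
    write_map_table,
)
from .map_qc import compute_stats, filter_map
from .position_interpolation import estimate_all_unmapped

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    map_paths: list[str]
    phys_path: str
    out_dir: str
    map_names: list[str] | None = None
    chrom_lengths_path: str | None = None
    unmapped_path: str | None = None
    K_grid: tuple[int, ...] = (1, 2, 3, 4)
    weights: dict[str, float] | None = None
    report_decimals: int = 2
    position_decimals: int = 4
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if len(self.map_paths) < 2:
            raise ValueError("pipeline needs at least 2 maps to merge")
        if self.map_names is not None and len(self.map_names) != len(self.map_paths):
            raise ValueError("map_names must match map_paths")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "K_grid" in data:
            data["K_grid"] = tuple(int(k) for k in data["K_grid"])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    consensus: GeneticMap
    stats_per_map: pd.DataFrame
    consensus_stats: pd.DataFrame
    anchors: pd.DataFrame
    rmse: pd.DataFrame
    selected_K: int
    removed: pd.DataFrame
    conflicts: dict[str, dict[str, str]]
    estimates: pd.DataFrame | None = None
    out_dir: Path | None = None


def _drop_conflicted(maps: list[GeneticMap], conflicts: set[str]) -> list[GeneticMap]:
    if not conflicts:
        return maps
    out = []
    for gm in maps:
        groups = {
            label: LinkageGroupMap(
                label, [r for r in lg.records if r.marker_id not in conflicts]
            )
            for label, lg in gm.groups.items()
        }
        out.append(GeneticMap(gm.name, groups))
    return out


def _round_frame(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    return df.round(decimals)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    names = config.map_names or [Path(p).stem for p in config.map_paths]
    maps = [read_genetic_map(p, n) for p, n in zip(config.map_paths, names)]
    annotations = read_physical_annotations(config.phys_path)
    chrom_lengths = (
        read_chromosome_lengths(config.chrom_lengths_path)
        if config.chrom_lengths_path
        else None
    )

    # stage 1: per-map stats and collinearity filtering
    stats_frames, filtered, removed_rows = [], [], []
    for gm in maps:
        stats = compute_stats(gm, annotations, chrom_lengths)
        stats.insert(0, "map", gm.name)
        stats_frames.append(stats.reset_index())
        fmap, reports = filter_map(gm, annotations)
        filtered.append(fmap)
        for label, rep in reports.items():
            for marker in sorted(rep.removed_ids):
                removed_rows.append((gm.name, label, marker))
            logger.info(
                "map %s %s: removed %d non-collinear marker(s), kept %d",
                gm.name, label, len(rep.removed_ids), rep.kept_count,
            )
    stats_per_map = pd.concat(stats_frames, ignore_index=True)
    removed = pd.DataFrame(removed_rows, columns=["map", "linkage_group", "marker_id"])

    # stage 2: anchor analysis on the filtered maps
    anchors = count_anchors(filtered)
    mergeable = _drop_conflicted(filtered, set(anchors.conflicts))

    # stage 3: consensus merge with K selection
    merge_cfg = MergeConfig(K_grid=config.K_grid, weights=config.weights)
    consensus, rmse_report = select_consensus(mergeable, annotations, merge_cfg)
    rmse = rmse_report.selected_frame.copy()
    rmse["mean"] = rmse_report.per_map_mean()
    consensus_stats = compute_stats(consensus, annotations, chrom_lengths)

    # stage 4: interpolation of unmapped markers
    estimates = None
    if config.unmapped_path:
        unmapped = pd.read_csv(config.unmapped_path, sep=None, engine="python")
        estimates = estimate_all_unmapped(
            unmapped, consensus, annotations, chrom_lengths or {}
        )

    # reports
    dec = config.report_decimals
    _round_frame(stats_per_map, dec).to_csv(out_dir / "map_stats.tsv", sep="\t", index=False)
    removed.to_csv(out_dir / "removed_markers.tsv", sep="\t", index=False)
    anchors.to_frame().to_csv(out_dir / "anchors.tsv", sep="\t", index=False)
    per_k = pd.DataFrame(
        sorted(rmse_report.overall_mean_by_K.items()), columns=["K", "mean_rmse_cM"]
    )
    per_k["selected"] = per_k["K"] == rmse_report.selected_K
    per_k.round(4).to_csv(out_dir / "rmse_by_K.tsv", sep="\t", index=False)
    _round_frame(rmse, 4).to_csv(out_dir / "rmse.tsv", sep="\t")
    write_map_table(consensus, out_dir / "consensus.tsv", decimals=config.position_decimals)
    _round_frame(consensus_stats, dec).to_csv(out_dir / "consensus_stats.tsv", sep="\t")
    if estimates is not None:
        est = estimates.copy()
        est["cM_estimate"] = est["cM_estimate"].map(
            lambda v: "" if pd.isna(v) else f"{v:.{config.position_decimals}f}"
        )
        est.to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    if anchors.conflicts:
        with open(out_dir / "group_conflicts.tsv", "w") as fh:
            fh.write("marker_id\tassignments\n")
            for marker, locs in sorted(anchors.conflicts.items()):
                fh.write(f"{marker}\t{json.dumps(locs, sort_keys=True)}\n")
    manifest = {
        "mapblend_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "selected_K": rmse_report.selected_K,
        "maps": names,
        "n_markers_consensus": len(consensus),
        "n_removed_noncollinear": int(len(removed)),
        "n_group_conflicts": len(anchors.conflicts),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        consensus=consensus,
        stats_per_map=stats_per_map,
        consensus_stats=consensus_stats,
        anchors=anchors.to_frame(),
        rmse=rmse,
        selected_K=rmse_report.selected_K,
        removed=removed,
        conflicts=anchors.conflicts,
        estimates=estimates,
        out_dir=out_dir,
    )
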