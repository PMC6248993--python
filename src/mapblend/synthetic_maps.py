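"""Truth-known simulation of multi-population linkage-map datasets.

The generator emulates the statistical structure of a multi-population SNP
linkage-map study in a diploid plant: eight linkage groups matching the
chromosomes of the reference genome, a piecewise-constant recombination
landscape in the 1.6-6.6 cM/Mb band, co-segregating marker bins produced by
the finite resolution of an F2 mapping population, five component maps that
each retain a random subset of the markers with positional jitter, and
occasional local order inversions that make a handful of markers
non-collinear with the physical map.

Because the true genetic position of every marker (mapped or unmapped) is
known, every downstream stage - collinearity filtering, consensus merging,
interpolation - can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .map_io import (
    GeneticMap,
    LinkageGroupMap,
    MarkerRecord,
    PhysicalAnnotationSet,
)

# Physical chromosome sizes (bp) of the eight peach pseudomolecules as covered
# by a dense consensus map; used so synthetic summary tables look like real ones.
DEFAULT_CHROM_LENGTHS_BP: tuple[int, ...] = (
    47_440_000,
    30_130_000,
    27_250_000,
    25_150_000,
    16_520_000,
    30_100_000,
    22_190_000,
    21_910_000,
)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic dataset.

    Defaults describe the study conditions the package targets: 8 linkage
    groups on peach-sized chromosomes, 200 SNPs per group, a 5-segment
    recombination landscape drawn from 1.6-6.6 cM/Mb, five component maps
    each retaining 60% of markers, 0.5 cM positional jitter, and a 0.5 cM
    co-segregation grid (the resolution of an F2 population of ~90
    individuals, where one recombinant shifts a position by ~0.56 cM).
    """

    n_groups: int = 8
    chrom_length_bp: tuple[int, ...] = DEFAULT_CHROM_LENGTHS_BP
    n_markers: int = 200
    n_rate_segments: int = 5
    rate_range_cM_per_Mb: tuple[float, float] = (1.6, 6.6)
    n_component_maps: int = 5
    retain_prob: float = 0.6
    jitter_sd_cM: float = 0.5
    inversion_prob: float = 0.25
    inversion_window: int = 4
    resolution_cM: float = 0.5
    n_unmapped: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.retain_prob <= 1.0:
            raise ValueError("retain_prob must be in (0, 1]")
        if not 0.0 <= self.inversion_prob <= 1.0:
            raise ValueError("inversion_prob must be in [0, 1]")
        lo, hi = self.rate_range_cM_per_Mb
        if lo > hi or lo <= 0:
            raise ValueError("rate_range_cM_per_Mb must satisfy 0 < low <= high")
        if self.resolution_cM < 0 or self.jitter_sd_cM < 0:
            raise ValueError("resolution_cM and jitter_sd_cM must be >= 0")
        if self.n_groups < 1 or self.n_markers < 2:
            raise ValueError("need >= 1 group and >= 2 markers per group")
        if len(self.lengths()) != self.n_groups:
            raise ValueError("chrom_length_bp must have one entry per group")

    def lengths(self) -> tuple[int, ...]:
        if isinstance(self.chrom_length_bp, int):
            return (self.chrom_length_bp,) * self.n_groups
        return tuple(self.chrom_length_bp)[: self.n_groups]

    def group_labels(self) -> list[str]:
        return [f"LG{i + 1}" for i in range(self.n_groups)]

    def chrom_labels(self) -> list[str]:
        return [f"Pp{i + 1:02d}" for i in range(self.n_groups)]


@dataclass
class RateFunction:
    """Piecewise-constant recombination rate r(bp) in cM/Mb on [1, length]."""

    breaks_bp: np.ndarray  # segment boundaries, len S+1, breaks[0]=1
    rates: np.ndarray  # len S

    def cumulative_cM(self, bp: np.ndarray | float) -> np.ndarray | float:
        """Integral of r from bp=1 to bp, in cM (bp in base pairs)."""
        seg_cM = np.diff(self.breaks_bp) * self.rates / 1e6
        cum = np.concatenate([[0.0], np.cumsum(seg_cM)])
        return np.interp(bp, self.breaks_bp, cum)


@dataclass
class TruthSet:
    """A synthetic study: truth map, component maps, and unmapped markers."""

    true_map: GeneticMap
    annotations: PhysicalAnnotationSet
    chrom_lengths: dict[str, int]
    component_maps: list[GeneticMap] = field(default_factory=list)
    unmapped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["marker_id", "chromosome", "position_bp", "true_cM"]
        )
    )
    rate_functions: dict[str, RateFunction] = field(default_factory=dict)
    # (map_name, group) -> marker ids whose order was locally reversed
    inversions: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    params: SimulationParams | None = None

    def group_chromosome(self, group: str) -> str:
        first = self.true_map.groups[group].records[0]
        return self.annotations.chromosome_of(first.marker_id)


def _rng(params: SimulationParams, stage: int) -> np.random.Generator:
    # independent streams per stage so component maps / unmapped markers are
    # reproducible regardless of which stages the caller runs
    return np.random.default_rng([params.seed, stage])


def generate_truth(params: SimulationParams) -> TruthSet:
    """Draw the true map: marker bp positions and their true genetic positions.

    Marker bp are drawn uniformly without replacement on [1, chrom_length].
    True cM is the cumulative integral of a piecewise-constant rate function
    from the group's first marker, optionally snapped *down* to multiples of
    ``resolution_cM`` (which creates co-segregating bins).
    """
    rng = _rng(params, 0)
    groups: dict[str, LinkageGroupMap] = {}
    entries: dict[str, tuple[str, int]] = {}
    chrom_lengths: dict[str, int] = {}
    rate_functions: dict[str, RateFunction] = {}
    lo, hi = params.rate_range_cM_per_Mb
    for g, (label, chrom, length) in enumerate(
        zip(params.group_labels(), params.chrom_labels(), params.lengths())
    ):
        if params.n_markers > length:
            raise ValueError(f"{label}: n_markers={params.n_markers} exceeds {length} bp")
        chrom_lengths[chrom] = length
        bps = np.sort(rng.choice(length, size=params.n_markers, replace=False) + 1)
        breaks = np.linspace(1, length, params.n_rate_segments + 1)
        rates = rng.uniform(lo, hi, size=params.n_rate_segments)
        rf = RateFunction(breaks_bp=breaks, rates=rates)
        rate_functions[label] = rf
        cm = np.asarray(rf.cumulative_cM(bps), dtype=float)
        cm -= cm[0]
        if params.resolution_cM > 0:
            cm = np.floor(cm / params.resolution_cM + 1e-12) * params.resolution_cM
        records = [
            MarkerRecord(f"SNP_{label}_{i:04d}", label, float(cm[i]))
            for i in range(params.n_markers)
        ]
        for rec, bp in zip(records, bps):
            entries[rec.marker_id] = (chrom, int(bp))
        groups[label] = LinkageGroupMap(label, records)
    return TruthSet(
        true_map=GeneticMap("truth", groups),
        annotations=PhysicalAnnotationSet(entries),
        chrom_lengths=chrom_lengths,
        rate_functions=rate_functions,
        params=params,
    )


def derive_component_maps(truth: TruthSet, params: SimulationParams) -> list[GeneticMap]:
    """Derive population maps: subset, jitter (isotonic-projected), invert.

    Each marker is retained independently with ``retain_prob`` (at least two
    per group are forced so every group stays a map). Retained positions get
    additive Gaussian jitter and are projected to the nearest monotone
    nondecreasing sequence, so each component is internally a valid map at
    any noise level. With probability ``inversion_prob`` per group, the cM
    values of one window of ``inversion_window`` consecutive interior markers
    are reversed; the members are logged in ``truth.inversions`` so the
    collinearity filter can be scored.
    """
    if params.retain_prob <= 0:
        raise ValueError("retain_prob must be > 0: components would be empty")
    rng = _rng(params, 1)
    maps: list[GeneticMap] = []
    truth.inversions.clear()
    for m in range(params.n_component_maps):
        name = f"pop{m + 1}"
        groups: dict[str, LinkageGroupMap] = {}
        for label, lg in truth.true_map.groups.items():
            n = lg.n_markers
            keep = rng.random(n) < params.retain_prob
            if keep.sum() < 2:
                forced = rng.choice(n, size=2, replace=False)
                keep[forced] = True
            # physical (bp) order == truth cM order here
            ids = [r.marker_id for r, k in zip(lg.records, keep) if k]
            cm = np.array([r.position_cM for r, k in zip(lg.records, keep) if k])
            if params.jitter_sd_cM > 0:
                cm = cm + rng.normal(0.0, params.jitter_sd_cM, size=cm.size)
                cm = isotonic_regression(cm).x
                cm = cm - cm.min()
            if (
                params.inversion_prob > 0
                and rng.random() < params.inversion_prob
                and cm.size >= params.inversion_window + 2
            ):
                w = params.inversion_window
                start = int(rng.integers(1, cm.size - w))  # interior window
                cm[start : start + w] = cm[start : start + w][::-1]
                truth.inversions[(name, label)] = set(ids[start : start + w])
            records = [
                MarkerRecord(mid, label, float(pos)) for mid, pos in zip(ids, cm)
            ]
            groups[label] = LinkageGroupMap(label, records)
        maps.append(GeneticMap(name, groups))
    truth.component_maps = maps
    return maps


def generate_unmapped(truth: TruthSet, params: SimulationParams) -> pd.DataFrame:
    """Extra markers with known physical position and true cM but no map.

    Positions are sampled between each group's first mapped marker and the
    chromosome end, avoiding collisions with mapped markers; at least one
    position per group lies beyond the last mapped marker so the
    scaffold-end extrapolation rule is exercised. True cM comes from the
    same rate function as the mapped markers (unsnapped).
    """
    rng = _rng(params, 2)
    rows: list[tuple[str, str, int, float]] = []
    if params.n_unmapped > 0:
        for label, lg in truth.true_map.groups.items():
            chrom = truth.group_chromosome(label)
            length = truth.chrom_lengths[chrom]
            rf = truth.rate_functions[label]
            mapped_bp = {truth.annotations.bp_of(r.marker_id) for r in lg.records}
            first_bp = min(mapped_bp)
            last_bp = max(mapped_bp)
            chosen: list[int] = []
            taken = set(mapped_bp)
            while len(chosen) < params.n_unmapped:
                bp = int(rng.integers(first_bp, length + 1))
                if bp not in taken:
                    taken.add(bp)
                    chosen.append(bp)
            if not any(bp > last_bp for bp in chosen) and last_bp < length:
                bp = int(rng.integers(last_bp + 1, length + 1))
                while bp in taken:  # pragma: no cover - sparse collisions
                    bp = int(rng.integers(last_bp + 1, length + 1))
                chosen[-1] = bp
            base = float(rf.cumulative_cM(first_bp))
            for i, bp in enumerate(sorted(chosen)):
                true_cm = float(rf.cumulative_cM(bp)) - base
                rows.append((f"UNM_{label}_{i:04d}", chrom, bp, true_cm))
    out = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "true_cM"])
    truth.unmapped = out
    return out


def simulate(params: SimulationParams | None = None, **overrides) -> TruthSet:
    """Convenience wrapper: truth + component maps + unmapped markers."""
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    truth = generate_truth(params)
    derive_component_maps(truth, params)
    generate_unmapped(truth, params)
    return truth
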