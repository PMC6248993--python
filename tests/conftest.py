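import pytest

from mapblend.map_io import (
    GeneticMap,
    LinkageGroupMap,
    MarkerRecord,
    PhysicalAnnotationSet,
)
from mapblend.synthetic_maps import SimulationParams, simulate


def make_lg(label, markers):
    """markers: iterable of (marker_id, position_cM)."""
    return LinkageGroupMap(label, [MarkerRecord(m, label, p) for m, p in markers])


def make_map(name, groups):
    """groups: {label: [(marker_id, position_cM), ...]}."""
    return GeneticMap(name, {lab: make_lg(lab, ms) for lab, ms in groups.items()})


@pytest.fixture
def small_truth():
    """Tiny noise-free truth-known dataset shared by cross-module tests."""
    params = SimulationParams(
        n_groups=2,
        chrom_length_bp=(20_000_000, 15_000_000),
        n_markers=40,
        n_component_maps=3,
        retain_prob=0.7,
        jitter_sd_cM=0.0,
        inversion_prob=0.0,
        resolution_cM=0.5,
        n_unmapped=10,
        seed=7,
    )
    return simulate(params)


@pytest.fixture
def annotations():
    return PhysicalAnnotationSet(
        {
            "m1": ("Pp01", 100),
            "m2": ("Pp01", 2_000_000),
            "m3": ("Pp01", 4_000_000),
            "m4": ("Pp01", 6_000_000),
            "m5": ("Pp01", 8_000_000),
        }
    )
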