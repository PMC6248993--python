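import numpy as np
import pytest

from mapblend.consensus_merge import (
    BackboneGroup,
    IntervalConstraint,
    MergeConfig,
    as_consensus_lg,
    build_backbone,
    compute_rmse,
    extract_interval_constraints,
    merge_linkage_group,
    select_consensus,
)
from mapblend.map_io import PhysicalAnnotationSet
from mapblend.map_qc import filter_map
from mapblend.synthetic_maps import SimulationParams, simulate

from conftest import make_lg, make_map


def C(i, j, d, w=1.0, src="m"):
    return IntervalConstraint(i, j, d, w, src)


class TestBuildBackbone:
    def test_all_annotated_is_bp_order(self, annotations):
        a = make_map("A", {"LG1": [("m2", 0.0), ("m1", 1.0), ("m3", 2.0)]})
        b = make_map("B", {"LG1": [("m1", 0.0), ("m3", 1.0)]})
        bb = build_backbone([a, b], annotations)
        assert bb.groups["LG1"].order == ["m1", "m2", "m3"]
        assert all(v == "physical" for v in bb.groups["LG1"].method.values())

    def test_unannotated_inserted_between_flanks(self, annotations):
        a = make_map("A", {"LG1": [("m1", 0.0), ("ssr", 1.0), ("m2", 2.0)]})
        b = make_map("B", {"LG1": [("m1", 0.0), ("m2", 1.0), ("m3", 2.0)]})
        bb = build_backbone([a, b], annotations)
        assert bb.groups["LG1"].order == ["m1", "ssr", "m2", "m3"]
        assert bb.groups["LG1"].method["ssr"] == "inferred"

    def test_ambiguous_placement_uses_mean_rank(self, annotations):
        # map A puts ssr between m1,m2 (key 0.5); map B between m2,m3 (key 1.5)
        a = make_map("A", {"LG1": [("m1", 0.0), ("ssr", 1.0), ("m2", 2.0)]})
        b = make_map("B", {"LG1": [("m2", 0.0), ("ssr", 1.0), ("m3", 2.0)]})
        bb = build_backbone([a, b], annotations)
        order = bb.groups["LG1"].order
        # mean key 1.0 ties with m2's rank; inferred sorts after physical
        assert order.index("ssr") == order.index("m2") + 1

    def test_unplaceable_marker_is_error(self):
        ann = PhysicalAnnotationSet({"m1": ("Pp01", 100)})
        a = make_map("A", {"LG1": [("m1", 0.0)]})
        b = make_map("B", {"LG1": [("ssr", 0.0)]})
        with pytest.raises(ValueError, match="ssr"):
            build_backbone([a, b], ann)


class TestExtractConstraints:
    def test_k1_adjacent_only(self):
        lg = make_lg("A", [("m1", 0.0), ("m2", 4.0), ("m3", 10.0)])
        rank = {"m1": 0, "m2": 1, "m3": 2}
        cs = extract_interval_constraints(lg, rank, K=1)
        assert {(c.i, c.j, c.d) for c in cs} == {("m1", "m2", 4.0), ("m2", "m3", 6.0)}

    def test_k2_adds_skip_pair(self):
        lg = make_lg("A", [("m1", 0.0), ("m2", 4.0), ("m3", 10.0)])
        rank = {"m1": 0, "m2": 1, "m3": 2}
        cs = extract_interval_constraints(lg, rank, K=2)
        assert ("m1", "m3", 10.0) in {(c.i, c.j, c.d) for c in cs}

    def test_single_marker_empty(self):
        assert extract_interval_constraints(make_lg("A", [("m1", 0.0)]), {"m1": 0}, 3) == []

    def test_bins_tied_to_representative(self):
        lg = make_lg("A", [("a", 0.0), ("b", 0.0), ("c", 2.0)])
        rank = {"a": 0, "b": 1, "c": 2}
        cs = extract_interval_constraints(lg, rank, K=1)
        assert ("a", "b", 0.0) in {(c.i, c.j, c.d) for c in cs}
        assert ("a", "c", 2.0) in {(c.i, c.j, c.d) for c in cs}

    def test_orientation_follows_backbone(self):
        lg = make_lg("A", [("m1", 0.0), ("m2", 4.0)])
        cs = extract_interval_constraints(lg, {"m2": 0, "m1": 1}, K=1)
        assert (cs[0].i, cs[0].j, cs[0].d) == ("m2", "m1", 4.0)


class TestMergeLinkageGroup:
    def test_identical_components_recovered_exactly(self):
        bg = BackboneGroup("LG1", ["m1", "m2", "m3"], {})
        cs = [C("m1", "m2", 4, src="A"), C("m2", "m3", 6, src="A"),
              C("m1", "m2", 4, src="B"), C("m2", "m3", 6, src="B")]
        res = merge_linkage_group(cs, bg)
        assert res.objective_cM == pytest.approx(0.0, abs=1e-9)
        assert [res.positions[m] for m in bg.order] == pytest.approx([0.0, 4.0, 10.0])

    def test_chained_consistent_intervals(self):
        # A: m1@0,m2@10; B: m2@0,m3@5 -> 0, 10, 15
        bg = BackboneGroup("LG1", ["m1", "m2", "m3"], {})
        res = merge_linkage_group([C("m1", "m2", 10, src="A"), C("m2", "m3", 5, src="B")], bg)
        assert [res.positions[m] for m in bg.order] == pytest.approx([0.0, 10.0, 15.0])

    def test_tie_break_is_weighted_mean(self):
        # optimal face [6, 10]; squared-residual tie-break lands on 8
        bg = BackboneGroup("LG1", ["m1", "m2"], {})
        res = merge_linkage_group([C("m1", "m2", 10, src="A"), C("m1", "m2", 6, src="B")], bg)
        assert res.positions["m2"] == pytest.approx(8.0, abs=1e-4)
        assert res.objective_cM == pytest.approx(4.0, abs=1e-6)

    def test_unequal_weights_shift_tie_break(self):
        bg = BackboneGroup("LG1", ["m1", "m2"], {})
        res = merge_linkage_group(
            [C("m1", "m2", 10, w=3.0, src="A"), C("m1", "m2", 6, w=1.0, src="B")], bg
        )
        # L1 optimum is now the heavier map's distance
        assert res.positions["m2"] == pytest.approx(10.0, abs=1e-4)

    def test_monotone_and_anchored(self):
        rng = np.random.default_rng(2)
        n = 20
        order = [f"m{i}" for i in range(n)]
        bg = BackboneGroup("LG1", order, {})
        cs = []
        for src in "AB":
            pos = np.cumsum(rng.uniform(0, 3, size=n))
            for i in range(n - 1):
                cs.append(C(order[i], order[i + 1], pos[i + 1] - pos[i], src=src))
        res = merge_linkage_group(cs, bg)
        x = [res.positions[m] for m in order]
        assert x[0] == 0.0
        assert all(b >= a - 1e-9 for a, b in zip(x, x[1:]))

    def test_weight_invariance(self):
        bg = BackboneGroup("LG1", ["m1", "m2", "m3"], {})
        cs1 = [C("m1", "m2", 3, w=1, src="A"), C("m2", "m3", 5, w=1, src="A"),
               C("m1", "m2", 4, w=1, src="B")]
        cs2 = [IntervalConstraint(c.i, c.j, c.d, c.weight * 7.5, c.source) for c in cs1]
        r1 = merge_linkage_group(cs1, bg)
        r2 = merge_linkage_group(cs2, bg)
        for m in bg.order:
            assert r1.positions[m] == pytest.approx(r2.positions[m], abs=1e-6)

    def test_empty_constraints_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            merge_linkage_group([], BackboneGroup("LG1", ["m1", "m2"], {}))


class TestComputeRmse:
    def test_identical_zero(self):
        lg = make_lg("LG1", [("m1", 0.0), ("m2", 8.0)])
        assert compute_rmse(as_consensus_lg(lg), lg) == 0.0

    def test_hand_computed(self):
        cons = as_consensus_lg(make_lg("LG1", [("m1", 0.0), ("m2", 8.0)]))
        comp = make_lg("LG1", [("m1", 0.0), ("m2", 10.0)])
        assert compute_rmse(cons, comp) == pytest.approx(np.sqrt(2.0), abs=1e-6)

    def test_anchoring_invariance(self):
        cons = as_consensus_lg(make_lg("LG1", [("m1", 0.0), ("m2", 8.0)]))
        comp = make_lg("LG1", [("m1", 5.0), ("m2", 15.0)])
        assert compute_rmse(cons, comp) == pytest.approx(np.sqrt(2.0), abs=1e-6)

    def test_no_shared_markers_is_error(self):
        cons = as_consensus_lg(make_lg("LG1", [("m1", 0.0)]))
        with pytest.raises(ValueError, match="no marker shared"):
            compute_rmse(cons, make_lg("LG1", [("zz", 0.0)]))


class TestSelectConsensus:
    def test_noise_free_recovery_and_smallest_K(self, small_truth):
        consensus, report = select_consensus(
            small_truth.component_maps, small_truth.annotations, MergeConfig()
        )
        assert report.selected_K == 1  # all K give RMSE 0; tie -> smallest
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in report.overall_mean_by_K.values())
        for label, lg in consensus.groups.items():
            tpos = {r.marker_id: r.position_cM for r in
                    small_truth.true_map.groups[label].records}
            offset = min(tpos[r.marker_id] for r in lg.records)
            for r in lg.records:
                assert r.position_cM == pytest.approx(tpos[r.marker_id] - offset, abs=1e-6)

    def test_selected_K_is_argmin(self):
        params = SimulationParams(
            n_groups=2, chrom_length_bp=(15_000_000, 12_000_000), n_markers=40,
            n_component_maps=3, jitter_sd_cM=1.0, inversion_prob=0.0, seed=21,
        )
        truth = simulate(params)
        filtered = [filter_map(m, truth.annotations)[0] for m in truth.component_maps]
        _, report = select_consensus(filtered, truth.annotations, MergeConfig())
        best = report.overall_mean_by_K[report.selected_K]
        assert all(best <= v + 1e-12 for v in report.overall_mean_by_K.values())

    def test_report_shape(self, small_truth):
        _, report = select_consensus(
            small_truth.component_maps, small_truth.annotations, MergeConfig(K_grid=(1, 2))
        )
        frame = report.selected_frame
        assert list(frame.index) == [m.name for m in small_truth.component_maps]
        assert set(frame.columns) == set(small_truth.true_map.groups)
        assert (frame.to_numpy() >= 0).all()

    def test_two_maps_minimum(self, small_truth):
        with pytest.raises(ValueError):
            select_consensus(small_truth.component_maps[:1], small_truth.annotations)


class TestMergeProperties:
    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_consensus_length_within_component_range(self, K):
        """Two components over the same markers (no ties): every consensus
        position is the mean of the two, so the consensus group length lies
        within the component length range."""
        rng = np.random.default_rng(17)
        n = 12
        order = [f"m{i}" for i in range(n)]
        ann = PhysicalAnnotationSet(
            {m: ("Pp01", 1_000_000 * (i + 1)) for i, m in enumerate(order)}
        )
        maps = []
        gaps_a = rng.uniform(0.5, 3.0, size=n - 1)
        for name, gaps in [("A", gaps_a), ("B", gaps_a + rng.uniform(-0.4, 0.4, n - 1))]:
            pos = np.concatenate([[0.0], np.cumsum(gaps)])
            maps.append(make_map(name, {"LG1": list(zip(order, pos))}))
        consensus, _ = select_consensus(maps, ann, MergeConfig(K_grid=(K,)))
        lengths = [max(m.groups["LG1"].positions()) for m in maps]
        clen = max(consensus.groups["LG1"].positions())
        assert min(lengths) - 1e-6 <= clen <= max(lengths) + 1e-6

    def test_rmse_nondecreasing_with_jitter(self):
        """Mean consensus-vs-truth RMSE trends upward with jitter sd."""
        from scipy.stats import spearmanr

        sds = [0.0, 0.5, 1.0, 2.0]
        means = []
        for sd in sds:
            vals = []
            for seed in range(5):
                params = SimulationParams(
                    n_groups=2, chrom_length_bp=(15_000_000, 12_000_000),
                    n_markers=40, n_component_maps=3, jitter_sd_cM=sd,
                    inversion_prob=0.0, resolution_cM=0.0, seed=seed,
                )
                truth = simulate(params)
                consensus, _ = select_consensus(
                    truth.component_maps, truth.annotations, MergeConfig(K_grid=(1,))
                )
                for label, lg in consensus.groups.items():
                    vals.append(compute_rmse(as_consensus_lg(lg),
                                             truth.true_map.groups[label]))
            means.append(np.mean(vals))
        rho, _ = spearmanr(sds, means)
        assert rho > 0
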