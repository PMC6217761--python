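import numpy as np
import pytest

from helpers import graph_partition
from slicelink import (
    LinkParams,
    ScenarioConfig,
    SliceStack,
    assign_categories,
    coarse_matrices,
    forward_label,
    generate,
    refine_matrix,
    run_pipeline,
    skip_connect,
)
from slicelink.components import extract_segments
from slicelink.linker import Category, ConnectionMatrix


def binary_matrix(entries, shape, slice_index=0):
    return ConnectionMatrix(
        slice_index=slice_index,
        gap=1,
        shape=shape,
        entries={k: 1.0 for k in entries},
    )


def stack_of(*masks, voxel_size=(1.0, 1.0, 1.0)):
    return SliceStack(masks=np.stack([np.asarray(m) for m in masks]), voxel_size=voxel_size)


class TestCategories:
    def test_worked_five_case_matrix(self):
        # Rows: one-to-one chain, chain end, split parent, two merge
        # parents; columns: split children, chain start, merge child.
        b = binary_matrix([(0, 0), (2, 1), (2, 2), (3, 4), (4, 4)], (5, 5))
        assert (b.row_sums() == [1, 0, 2, 1, 1]).all()
        assert (b.col_sums() == [1, 1, 1, 0, 2]).all()
        cats = assign_categories([b], [5, 5])
        row_cats = [cats[(0, p)] - {Category.S} for p in range(5)]
        col_cats = [cats[(1, q)] - {Category.E} for q in range(5)]
        assert row_cats == [{"O"}, {"E"}, {"S1"}, {"M1"}, {"M1"}]
        assert col_cats == [set(), {"S2"}, {"S2"}, {"S"}, {"M2"}]

    def test_all_zero_matrix_means_all_end_then_all_start(self):
        b = binary_matrix([], (3, 4))
        cats = assign_categories([b], [3, 4])
        assert all(Category.E in cats[(0, p)] for p in range(3))
        assert all(Category.S in cats[(1, q)] for q in range(4))

    def test_identity_matrix_is_all_one_to_one(self):
        b = binary_matrix([(i, i) for i in range(4)], (4, 4))
        cats = assign_categories([b], [4, 4])
        for p in range(4):
            assert cats[(0, p)] == {Category.O, Category.S}
            assert cats[(1, p)] == {Category.E}

    def test_boundary_slices_always_start_and_end(self):
        b = binary_matrix([(0, 0)], (1, 1))
        cats = assign_categories([b], [1, 1])
        assert Category.S in cats[(0, 0)]
        assert Category.E in cats[(1, 0)]


class TestForwardLabel:
    def test_worked_example_partitions_into_five_objects(self):
        b = binary_matrix([(0, 0), (2, 1), (2, 2), (3, 4), (4, 4)], (5, 5))
        cats = assign_categories([b], [5, 5])
        assignment = forward_label([5, 5], [b], cats)
        expected = {
            frozenset({(0, 0), (1, 0)}),
            frozenset({(0, 1)}),
            frozenset({(0, 2), (1, 1), (1, 2)}),
            frozenset({(0, 3), (0, 4), (1, 4)}),
            frozenset({(1, 3)}),
        }
        assert assignment.partition() == expected
        assert assignment.n_objects == 5

    def test_single_chain_gets_one_label(self):
        n = 6
        bs = [binary_matrix([(0, 0)], (1, 1), slice_index=i) for i in range(n - 1)]
        cats = assign_categories(bs, [1] * n)
        assignment = forward_label([1] * n, bs, cats)
        assert assignment.n_objects == 1

    def test_empty_matrices_leave_every_segment_alone(self):
        bs = [binary_matrix([], (2, 2), slice_index=i) for i in range(2)]
        cats = assign_categories(bs, [2, 2, 2])
        assignment = forward_label([2, 2, 2], bs, cats)
        assert assignment.n_objects == 6

    def test_deterministic_labels(self):
        b = binary_matrix([(0, 0), (2, 1), (2, 2)], (3, 3))
        cats = assign_categories([b], [3, 3])
        l1 = forward_label([3, 3], [b], cats).final_labels()
        l2 = forward_label([3, 3], [b], cats).final_labels()
        assert l1 == l2


class TestRefineMatrix:
    def test_connect_case_bypasses_validation(self):
        # Diagonal vs anti-diagonal: identical boxes (c=1 >= T_h) but
        # pixel-disjoint; the shortcut still connects them.
        idx = np.arange(6)
        m0 = np.zeros((12, 12), dtype=np.uint8)
        m0[idx, idx] = 1
        m1 = np.zeros((12, 12), dtype=np.uint8)
        m1[idx, 5 - idx] = 1
        s0, s1 = extract_segments(m0, 0), extract_segments(m1, 1)
        c = coarse_matrices([s0, s1], gap=1)[0]
        assert c.entries[(0, 0)] == pytest.approx(1.0)
        b = refine_matrix(c, s0, s1, LinkParams(lam=0.0))
        assert b.entries == {(0, 0): 1.0}

    def test_validate_case_drops_false_connection(self):
        # Parallel diagonal strips: boxes overlap (validation band) but the
        # pixels are disjoint, so lam=0 validation zeroes the entry.
        idx = np.arange(10)
        m0 = np.zeros((20, 20), dtype=np.uint8)
        m0[idx, idx] = 1
        m1 = np.zeros((20, 20), dtype=np.uint8)
        m1[idx, idx + 6] = 1
        s0, s1 = extract_segments(m0, 0), extract_segments(m1, 1)
        c = coarse_matrices([s0, s1], gap=1)[0]
        ((_pq, val),) = tuple(c.entries.items())
        assert 0.01 <= val < 0.4
        b = refine_matrix(c, s0, s1, LinkParams(lam=0.0))
        assert b.entries == {}

    def test_threshold_is_strict(self):
        # P = 2/4 so refined = 0.25 at lam=0; T_s = 0.25 must reject.
        m0 = np.zeros((8, 8), dtype=np.uint8)
        m0[0, 0:3] = 1
        m1 = np.zeros((8, 8), dtype=np.uint8)
        m1[0, 1:4] = 1
        s0, s1 = extract_segments(m0, 0), extract_segments(m1, 1)
        c = coarse_matrices([s0, s1], gap=1)[0]
        params = LinkParams(lam=0.0, t_fine=0.25, t_high=0.9)
        assert refine_matrix(c, s0, s1, params).entries == {}
        params = LinkParams(lam=0.0, t_fine=0.2499, t_high=0.9)
        assert refine_matrix(c, s0, s1, params).entries == {(0, 0): 1.0}


class TestSkipConnection:
    def _gap_stack(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[4:10, 4:10] = 1
        empty = np.zeros_like(m)
        return stack_of(m, empty, m)

    def test_bridges_single_missing_slice(self):
        res = run_pipeline(self._gap_stack(), LinkParams.mitochondria())
        assert res.n_objects == 1
        assert len(res.skip_pairs) == 1

    def test_disabled_skip_leaves_two_objects(self):
        res = run_pipeline(self._gap_stack(), LinkParams.mitochondria(skip_enabled=False))
        assert res.n_objects == 2

    def test_no_box_overlap_is_never_bridged(self):
        m0 = np.zeros((24, 24), dtype=np.uint8)
        m0[0:5, 0:5] = 1
        m2 = np.zeros((24, 24), dtype=np.uint8)
        m2[12:17, 12:17] = 1
        res = run_pipeline(
            stack_of(m0, np.zeros((24, 24), np.uint8), m2), LinkParams.mitochondria()
        )
        assert res.n_objects == 2
        assert res.skip_pairs == []

    def test_non_starting_target_is_not_bridged(self):
        # A ends on slice 0; C on slice 2 overlaps A's box but is already
        # continued from B on slice 1, so it is not a chain start and the
        # skip stage must leave it alone.
        a = np.zeros((16, 16), dtype=np.uint8)
        a[0:4, 0:10] = 1
        b = np.zeros((16, 16), dtype=np.uint8)
        b[6:10, 0:10] = 1
        c = np.zeros((16, 16), dtype=np.uint8)
        c[2:8, 0:10] = 1
        res = run_pipeline(stack_of(a, b, c), LinkParams.mitochondria())
        assert res.skip_pairs == []
        assert res.n_objects == 2


class TestRunPipeline:
    def test_clean_tubes_give_one_object_each(self):
        masks = np.zeros((5, 48, 48), dtype=np.uint8)
        for x0 in (2, 18, 34):
            masks[:, 10:20, x0 : x0 + 10] = 1
        res = run_pipeline(SliceStack(masks=masks), LinkParams.mitochondria())
        assert res.n_objects == 3
        assert len(res.objects) == 3
        assert set(res.objects["n_segments"]) == {5}

    def test_empty_stack_gives_empty_assignment(self):
        res = run_pipeline(SliceStack(masks=np.zeros((4, 16, 16), np.uint8)))
        assert res.n_objects == 0
        assert len(res.objects) == 0

    def test_raising_fine_threshold_never_merges_objects(self):
        cfg = ScenarioConfig(
            n_slices=10, height=128, width=128, n_objects=4,
            p_split=0.4, p_merge=0.3, seed=42,
        )
        stack, _truth, _ev = generate(cfg)
        counts = [
            run_pipeline(stack, LinkParams.mitochondria(t_fine=ts)).n_objects
            for ts in (0.0, 0.03, 0.1, 0.3)
        ]
        assert counts == sorted(counts)

    def test_partition_equals_own_segment_graph_components(self):
        cfg = ScenarioConfig(
            n_slices=12, height=128, width=128, n_objects=4,
            p_split=0.4, p_merge=0.3, n_gaps=1, seed=9,
        )
        stack, _truth, _ev = generate(cfg)
        res = run_pipeline(stack, LinkParams.mitochondria())
        assert res.assignment.partition() == graph_partition(res)

    def test_gap_changes_object_count_by_exactly_one(self):
        cfg = ScenarioConfig(
            n_slices=10, height=128, width=128, n_objects=3, n_gaps=1, seed=4
        )
        stack, _truth, _ev = generate(cfg)
        with_skip = run_pipeline(stack, LinkParams.mitochondria())
        without = run_pipeline(stack, LinkParams.mitochondria(skip_enabled=False))
        assert without.n_objects == with_skip.n_objects + 1


class TestCoarseMatrices:
    def test_no_box_overlap_gives_empty_matrices(self):
        m0 = np.zeros((16, 16), dtype=np.uint8)
        m0[0:4, 0:4] = 1
        m1 = np.zeros((16, 16), dtype=np.uint8)
        m1[10:14, 10:14] = 1
        segs = [extract_segments(m0, 0), extract_segments(m1, 1)]
        assert coarse_matrices(segs, gap=1)[0].entries == {}

    def test_identical_boxes_score_one(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[2:8, 3:9] = 1
        segs = [extract_segments(m, 0), extract_segments(m, 1)]
        assert coarse_matrices(segs, gap=1)[0].entries == {(0, 0): pytest.approx(1.0)}

    def test_gap_two_spans_slice_pairs_i_i_plus_2(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[2:8, 3:9] = 1
        segs = [extract_segments(m, i) for i in range(4)]
        mats = coarse_matrices(segs, gap=2)
        assert [m_.slice_index for m_ in mats] == [0, 1]
        assert all(m_.gap == 2 for m_ in mats)
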