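"""Distance transform, skeletonization, pruning and the skeleton graph."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from leafdissect.errors import EmptyMaskError, TopologyError
from leafdissect.skeleton import (
    build_graph,
    distance_transform,
    find_base_node,
    path_chain_length,
    prune_skeleton,
    skeletonize,
)


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """Independent oracle: per-foreground-pixel minimum distance over
    all background pixels (image frame counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape)
    if len(fg):
        out[tuple(fg.T)] = cdist(fg, bg).min(axis=1)
    return out[1:-1, 1:-1]


class TestDistanceTransform:
    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            distance_transform(np.zeros((5, 5), dtype=bool))

    def test_three_by_three_block(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[3:6, 3:6] = True
        d = distance_transform(mask)
        assert d[4, 4] == pytest.approx(2.0)
        for r, c in [(3, 3), (3, 4), (5, 5)]:
            assert d[r, c] == pytest.approx(1.0)
        assert (d[~mask] == 0).all()

    def test_single_pixel(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        assert distance_transform(mask)[3, 3] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            mask = rng.random((20, 20)) < 0.4
            if not mask.any():
                continue
            assert np.allclose(distance_transform(mask), brute_force_edt(mask))

    def test_lipschitz_between_neighbors(self):
        """|d(x) - d(y)| <= sqrt(2) for 8-neighboring foreground pixels."""
        rng = np.random.default_rng(3)
        mask = rng.random((30, 30)) < 0.6
        mask[0, 0] = True
        d = distance_transform(mask)
        for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
            a = d[max(dr, 0) or None : d.shape[0] + min(dr, 0), :]
            shifted = np.roll(np.roll(d, -dr, axis=0), -dc, axis=1)
            both = mask & np.roll(np.roll(mask, -dr, axis=0), -dc, axis=1)
            both[-1, :] = both[:, -1] = both[:, 0] = False
            assert (np.abs(d - shifted)[both] <= np.sqrt(2) + 1e-9).all()


class TestSkeletonize:
    def test_skeleton_is_thin_subset_and_connected(self, two_pair_truth):
        from skimage.measure import label

        mask = two_pair_truth.mask
        skel = skeletonize(mask)
        assert (mask | ~skel).all()  # skeleton subseteq foreground
        # no fully-set 2x2 block
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        assert not blocks.any()
        assert label(skel, connectivity=2).max() == 1

    def test_rectangle_skeleton_contains_central_row(self):
        mask = np.zeros((9, 55), dtype=bool)
        mask[2:7, 2:53] = True  # 5x51 solid rectangle
        skel = skeletonize(mask)
        # interior central-row pixels are equidistant from both long sides
        assert skel[4, 10:45].all()

    def test_one_pixel_path_is_its_own_skeleton(self):
        mask = np.zeros((20, 20), dtype=bool)
        rr = np.arange(3, 17)
        mask[rr, 8] = True
        assert np.array_equal(skeletonize(mask), mask)

    def test_disk_collapses_to_small_center_cluster(self):
        from skimage.draw import disk

        mask = np.zeros((31, 31), dtype=bool)
        rr, cc = disk((15, 15), 10)
        mask[rr, cc] = True
        assert skeletonize(mask).sum() <= 5


def _spur_skeleton(spur_len: int):
    """100-px horizontal trunk with a vertical spur of given length."""
    skel = np.zeros((60, 110), dtype=bool)
    skel[30, 5:105] = True
    skel[30 - spur_len : 30, 50] = True
    return skel


class TestPruning:
    def test_short_spur_removed_long_trunk_kept(self):
        skel = _spur_skeleton(10)
        pruned = prune_skeleton(skel, None, 25)
        assert not pruned[:30, 50].any()
        assert pruned[30, 5:105].all()

    def test_spur_longer_than_threshold_is_retained(self):
        skel = _spur_skeleton(30)
        pruned = prune_skeleton(skel, None, 25)
        assert pruned[30 - 30 : 30, 50].all()

    def test_zero_threshold_is_identity(self):
        skel = _spur_skeleton(10)
        assert np.array_equal(prune_skeleton(skel, None, 0), skel)

    def test_pruning_is_idempotent(self):
        skel = _spur_skeleton(10)
        once = prune_skeleton(skel, None, 25)
        twice = prune_skeleton(once, None, 25)
        assert np.array_equal(once, twice)

    def test_pure_path_is_never_pruned_away(self):
        skel = np.zeros((40, 40), dtype=bool)
        skel[20, 5:15] = True  # 10-px junction-free path
        assert np.array_equal(prune_skeleton(skel, None, 25), skel)

    def test_medially_salient_branch_survives(self):
        """A short branch whose distance values climb well above the
        fork's is blade skeleton, not a spur, and must be kept."""
        skel = _spur_skeleton(10)
        distance = np.ones_like(skel, dtype=float)
        distance[30 - 10 : 30, 50] = np.linspace(8, 2, 10)  # rising inward
        pruned = prune_skeleton(skel, distance, 25)
        assert pruned[:30, 50].sum() == 10


class TestGraph:
    def test_path_graph_counts(self):
        skel = np.zeros((5, 5), dtype=bool)
        skel[2, 1:4] = True
        g = build_graph(skel, np.ones((5, 5)))
        assert g.graph.number_of_nodes() == 3
        assert len(g.extremal_nodes) == 2
        assert len(g.junction_nodes) == 0

    def test_y_shape_counts(self):
        skel = np.zeros((11, 11), dtype=bool)
        skel[5, 1:6] = True  # stem
        skel[[4, 3, 2], [6, 7, 8]] = True  # upper arm
        skel[[6, 7, 8], [6, 7, 8]] = True  # lower arm
        g = build_graph(skel, np.ones((11, 11)))
        assert len(g.extremal_nodes) == 3
        assert len(g.junction_nodes) >= 1

    def test_node_count_equals_pixel_count(self, two_pair_truth):
        mask = two_pair_truth.mask
        skel = skeletonize(mask)
        g = build_graph(skel, distance_transform(mask))
        assert g.graph.number_of_nodes() == int(skel.sum())

    def test_base_node_is_bottom_of_vertical_line(self):
        skel = np.zeros((20, 9), dtype=bool)
        skel[3:17, 4] = True
        g = build_graph(skel, np.ones((20, 9)))
        assert find_base_node(g) == (16, 4)

    def test_base_node_tie_breaks_leftmost(self):
        skel = np.zeros((12, 20), dtype=bool)
        skel[2, 3:17] = True  # horizontal: both tips on the same row
        g = build_graph(skel, np.ones((12, 20)))
        assert find_base_node(g) == (2, 3)

    def test_base_node_near_synthetic_petiole_end(self, two_pair_truth, two_pair_result):
        base_truth = np.asarray(two_pair_truth.landmark_axis[0])
        base = np.asarray(two_pair_result.base)
        assert np.hypot(*(base - base_truth)) <= 2.0

    def test_cycle_without_tips_raises(self):
        import networkx as nx

        from leafdissect.skeleton import SkeletonGraph

        g = nx.cycle_graph(6)
        ring = nx.relabel_nodes(g, {i: (0, i) for i in range(6)})
        for n in ring.nodes:
            ring.nodes[n]["d"] = 1.0
        with pytest.raises(TopologyError):
            find_base_node(SkeletonGraph(graph=ring))

    def test_skeleton_passes_near_every_truth_branch_point(self, two_pair_truth):
        mask = two_pair_truth.mask
        skel = prune_skeleton(skeletonize(mask), distance_transform(mask), 25)
        pts = np.argwhere(skel)
        tol = max(1.0, two_pair_truth.spec.stem_width / 2) + 1.0
        for b in two_pair_truth.branch_positions:
            assert cdist([b], pts).min() <= tol


def test_chain_length_weights_diagonals():
    path = [(0, 0), (0, 1), (1, 2), (2, 2)]  # axial, diagonal, axial
    assert path_chain_length(path) == pytest.approx(2 + np.sqrt(2))
    assert path_chain_length([(3, 3)]) == 0.0
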