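import itertools

import networkx as nx
import numpy as np
import pytest

from bootseg import (
    AffinityVolume,
    LabelVolume,
    SegParams,
    affinities_to_mask,
    agglomerate,
    build_rag,
    generate_synthetic_labels,
    grid_search,
    labels_to_affinities,
    segment,
    voi,
    watershed_fragments,
)
from bootseg.postproc import SupervoxelGraph
from bootseg import SynthConfig


def pooled_oracle(affs):
    """Loop application of the documented pooling rule (mean over in-bounds
    incident relations)."""
    shape = affs.data.shape[1:]
    out = np.zeros(shape)
    for idx in np.ndindex(shape):
        vals = []
        for c, off in enumerate(affs.neighborhood):
            n = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= x < s for x, s in zip(n, shape)):
                vals.append(affs.data[(c,) + idx])
            p = tuple(i - o for i, o in zip(idx, off))
            if all(0 <= x < s for x, s in zip(p, shape)):
                vals.append(affs.data[(c,) + p])
        out[idx] = np.mean(vals) if vals else 0.0
    return out


class TestAffinitiesToMask:
    def test_all_ones_all_true(self):
        affs = AffinityVolume(np.ones((3, 4, 4, 4)))
        assert affinities_to_mask(affs, 0.5).all()

    def test_all_zero_all_false(self):
        affs = AffinityVolume(np.zeros((3, 4, 4, 4)))
        assert not affinities_to_mask(affs, 0.0).any()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_loop_oracle(self, seed):
        data = np.random.default_rng(seed).random((3, 5, 5, 5))
        affs = AffinityVolume(data)
        for t in (0.2, 0.5, 0.8):
            np.testing.assert_array_equal(
                affinities_to_mask(affs, t), pooled_oracle(affs) > t
            )


class TestWatershedFragments:
    def test_two_separated_balls_two_fragments(self):
        from skimage.morphology import ball

        mask = np.zeros((16, 16, 40), bool)
        b = ball(5)
        mask[2:13, 2:13, 2:13] = b
        mask[2:13, 2:13, 25:36] = b
        frags = watershed_fragments(mask, seed_min_distance=3.0)
        assert frags.ids().size == 2
        assert (frags.data > 0).sum() == mask.sum()

    def test_single_ball_one_fragment(self):
        from skimage.morphology import ball

        mask = np.zeros((16, 16, 16), bool)
        mask[2:13, 2:13, 2:13] = ball(5)
        frags = watershed_fragments(mask, seed_min_distance=100.0)
        assert frags.ids().size == 1

    def test_fragments_are_connected_within_mask(self, small_synth_labels):
        from scipy import ndimage

        mask = small_synth_labels.data > 0
        frags = watershed_fragments(mask, 24.0, small_synth_labels.voxel_size)
        assert ((frags.data > 0) == mask).all()
        for l in frags.ids()[:20]:
            _, n = ndimage.label(frags.data == l)
            assert n == 1

    def test_empty_mask_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            frags = watershed_fragments(np.zeros((4, 4, 4), bool))
        assert not frags.data.any()


class TestBuildRag:
    def _two_block_affs(self, crossing=0.2):
        frag = np.zeros((2, 2, 4), np.uint32)
        frag[:, :, :2] = 1
        frag[:, :, 2:] = 2
        affs = np.ones((3, 2, 2, 4), np.float32)
        affs[2, :, :, 1] = crossing  # x-relation between column 1 and 2
        affs[2, :, :, 3] = 0  # out of bounds
        return LabelVolume(frag), AffinityVolume(affs)

    def test_single_edge_with_mean_score(self):
        frag, affs = self._two_block_affs(0.2)
        rag = build_rag(frag, affs)
        assert rag.graph.number_of_nodes() == 2
        assert rag.graph.number_of_edges() == 1
        assert rag.graph[1][2]["score"] == pytest.approx(0.2)

    def test_non_touching_fragments_no_edge(self):
        frag = np.zeros((1, 1, 5), np.uint32)
        frag[0, 0, 0] = 1
        frag[0, 0, 4] = 2
        rag = build_rag(LabelVolume(frag), AffinityVolume(np.ones((3, 1, 1, 5))))
        assert rag.graph.number_of_edges() == 0

    def test_node_count_and_attributes(self, small_synth_labels):
        affs = labels_to_affinities(small_synth_labels)
        frags = watershed_fragments(small_synth_labels.data > 0, 24.0,
                                    small_synth_labels.voxel_size)
        rag = build_rag(frags, affs)
        assert rag.graph.number_of_nodes() == frags.ids().size
        for _, d in rag.graph.nodes(data=True):
            assert d["size"] > 0 and len(d["center"]) == 3


from oracles import agglomerate_oracle


def make_rag(n_nodes, edges):
    """RAG on a trivial 1-voxel-per-node fragment volume."""
    frag = np.arange(1, n_nodes + 1, dtype=np.uint32).reshape(1, 1, -1)
    g = nx.Graph()
    g.add_nodes_from(range(1, n_nodes + 1))
    for u, v, s, n in edges:
        g.add_edge(u, v, aff_sum=s, n_pairs=n, score=s / n)
    return SupervoxelGraph(graph=g, fragments=LabelVolume(frag))


class TestAgglomerate:
    def test_threshold_zero_merges_each_component(self):
        rag = make_rag(4, [(1, 2, 0.1, 1), (3, 4, 0.2, 1)])
        out = agglomerate(rag, 0.0)
        assert len(np.unique(out.data)) == 2

    def test_threshold_above_one_keeps_fragments(self):
        rag = make_rag(3, [(1, 2, 0.9, 1), (2, 3, 0.9, 1)])
        out = agglomerate(rag, 1.0 + 1e-9)
        assert len(np.unique(out.data)) == 3

    def test_four_node_chain_hand_simulated(self):
        # chain A-B-C-D with scores 0.9, 0.3, 0.8 at threshold 0.5:
        # A,B merge (0.9), C,D merge (0.8), the 0.3 bridge stays cut
        rag = make_rag(4, [(1, 2, 0.9, 1), (2, 3, 0.3, 1), (3, 4, 0.8, 1)])
        out = agglomerate(rag, 0.5).data.ravel()
        assert out[0] == out[1] and out[2] == out[3] and out[0] != out[2]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_hierarchy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        edges = []
        for u, v in itertools.combinations(range(1, n + 1), 2):
            if rng.random() < 0.5:
                k = int(rng.integers(1, 4))
                edges.append((u, v, float(rng.random() * k), k))
        rag = make_rag(n, edges)
        for m in (0.2, 0.5, 0.8):
            got = agglomerate(rag, m).data
            want = agglomerate_oracle(rag.graph, rag.fragments, m)
            # compare up to relabeling
            assert len(np.unique(got)) == len(np.unique(want))
            pairs = set(zip(got.ravel(), want.ravel()))
            assert len(pairs) == len(np.unique(got))


class TestSegment:
    def test_roundtrip_three_instances(self):
        lab = generate_synthetic_labels(
            SynthConfig(shape=(24, 24, 24), instance_range=(3, 3),
                        min_instance_size=32, seed=2)
        )
        seg = segment(labels_to_affinities(lab))
        vs, vm = voi(seg, lab)
        assert vs + vm == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_affinities_empty_segmentation(self):
        seg = segment(AffinityVolume(np.zeros((3, 8, 8, 8))))
        assert not seg.data.any()

    def test_segment_count_monotone_in_merge_threshold(self, small_synth_labels):
        affs = labels_to_affinities(small_synth_labels)
        counts = []
        for m in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            seg = segment(affs, SegParams(merge_threshold=m))
            counts.append(seg.ids().size)
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_min_segment_size_filter(self, small_synth_labels):
        affs = labels_to_affinities(small_synth_labels)
        seg = segment(affs, SegParams(min_segment_size=200))
        sizes = np.bincount(seg.data.ravel())[1:]
        assert (sizes[sizes > 0] >= 200).all() or seg.ids().size == 0


class TestGridSearch:
    def test_single_point_returned(self, small_synth_labels):
        affs = labels_to_affinities(small_synth_labels)
        best, table = grid_search(affs, {"merge_threshold": [0.5]},
                                  small_synth_labels)
        assert best.merge_threshold == 0.5 and len(table) == 1

    def test_planted_optimum_selected(self, small_synth_labels):
        affs = labels_to_affinities(small_synth_labels)
        best, table = grid_search(
            affs,
            {"merge_threshold": [0.5, 1.0], "threshold": [0.1, 0.95]},
            small_synth_labels,
        )
        assert best.threshold == 0.1 and best.merge_threshold == 0.5
        assert min(r["metric"] for r in table) == pytest.approx(0.0, abs=1e-9)

    def test_ties_broken_lexicographically(self, small_synth_labels):
        affs = labels_to_affinities(small_synth_labels)
        # both merge thresholds below 1 give the exact segmentation -> tie
        best, table = grid_search(affs, {"merge_threshold": [0.3, 0.6]},
                                  small_synth_labels)
        assert best.merge_threshold == 0.3
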