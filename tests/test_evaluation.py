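import itertools

import networkx as nx
import numpy as np
import pytest

from bootseg import (
    LabelVolume,
    SkeletonSet,
    evaluate_segmentation,
    filter_gt,
    mcm_edits,
    read_swc_dir,
    skeletonize,
    voi,
    write_swc_dir,
)
from bootseg.evaluation import _multiway_cut

VS = (40.0, 8.0, 8.0)


def make_skeleton(objects, voxel_size=VS):
    """Hand-built SkeletonSet: objects = {id: (voxel list, edge list)}."""
    skels = {}
    vs = np.asarray(voxel_size)
    for obj, (voxels, edges) in objects.items():
        g = nx.Graph()
        for i, v in enumerate(voxels):
            g.add_node(i, voxel=tuple(v), pos=tuple(np.asarray(v) * vs))
        for u, w in edges:
            d = np.linalg.norm((np.asarray(voxels[u]) - voxels[w]) * vs)
            g.add_edge(u, w, length=float(d))
        skels[obj] = g
    return SkeletonSet(skels, voxel_size)


class TestFilterGt:
    def test_strict_500_voxel_boundary(self):
        lab = np.zeros((10, 50, 50), np.uint32)
        lab[0, :10, :50] = 1          # 500 voxels: kept
        lab[5].flat[:499] = 2          # 499 voxels: removed
        out = filter_gt(LabelVolume(lab, VS), min_size=500)
        kept = set(np.unique(out.data)) - {0}
        assert len(kept) == 1
        assert (out.data[0, :10, :50] > 0).all()
        assert not out.data[5].any()

    def test_disjoint_components_split_into_two_ids(self):
        lab = np.zeros((3, 8, 8), np.uint32)
        lab[0, :2, :2] = 7
        lab[2, 5:8, 5:8] = 7
        out = filter_gt(LabelVolume(lab, VS), min_size=0)
        assert len(set(np.unique(out.data)) - {0}) == 2

    def test_min_size_zero_only_relabels(self, small_synth_labels):
        out = filter_gt(small_synth_labels, min_size=0)
        assert (out.data > 0).sum() == (small_synth_labels.data > 0).sum()
        n = out.data.max()
        assert set(np.unique(out.data)) == set(range(n + 1))


class TestSkeletonize:
    def test_straight_bar_path_length(self):
        lab = np.zeros((3, 12, 3), np.uint32)
        lab[1, 1:11, 1] = 1  # 10 voxels along y, 8 nm spacing
        sk = skeletonize(LabelVolume(lab, VS))
        assert sk.path_length(1) == pytest.approx(72.0)

    def test_ball_skeleton_connected_and_contained(self):
        from skimage.morphology import ball

        b = ball(5).astype(np.uint32)
        sk = skeletonize(LabelVolume(b, (8.0, 8.0, 8.0)))
        g = sk.skeletons[1]
        assert nx.is_connected(g)
        assert all(b[g.nodes[n]["voxel"]] == 1 for n in g.nodes)

    def test_empty_volume_empty_set(self):
        sk = skeletonize(LabelVolume(np.zeros((4, 4, 4), np.uint32), VS))
        assert len(sk) == 0

    def test_swc_roundtrip(self, tmp_path):
        lab = np.zeros((3, 12, 3), np.uint32)
        lab[1, 1:11, 1] = 1
        sk = skeletonize(LabelVolume(lab, VS))
        write_swc_dir(sk, str(tmp_path))
        back = read_swc_dir(str(tmp_path), VS)
        assert back.path_length(1) == pytest.approx(sk.path_length(1))


class TestMcmEdits:
    def test_perfect_segmentation_zero_edits(self, small_synth_labels):
        sk = skeletonize(small_synth_labels)
        rep = mcm_edits(sk, small_synth_labels)
        assert rep.splits == 0 and rep.merges == 0

    def test_one_object_in_two_segments_is_one_split(self):
        lab = np.zeros((3, 12, 3), np.uint32)
        lab[1, 1:11, 1] = 1
        seg = lab.copy()
        seg[1, 6:, 1] = 2
        rep = mcm_edits(skeletonize(LabelVolume(lab, VS)), LabelVolume(seg, VS))
        assert rep.splits == 1 and rep.merges == 0

    def test_single_bridge_merge_is_one_cut(self):
        # two 3-node skeletons in one segment, joined by a single adjacency
        objs = {
            1: ([(1, 1, 1), (1, 2, 1), (1, 3, 1)], [(0, 1), (1, 2)]),
            2: ([(1, 4, 2), (1, 5, 3), (1, 6, 3)], [(0, 1), (1, 2)]),
        }
        sk = make_skeleton(objs)
        seg = np.ones((3, 8, 8), np.uint32)
        rep = mcm_edits(sk, LabelVolume(seg, VS))
        assert rep.merges == 1
        assert rep.n_objects == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_multiway_cut_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        g = nx.gnp_random_graph(n, 0.45, seed=seed)
        objs = {i: set() for i in range(2 + seed % 2)}
        for node in g.nodes:
            objs[node % len(objs)].add(node)
        got = _multiway_cut(g, objs)

        # oracle: enumerate all edge subsets
        def separated(h):
            for comp in nx.connected_components(h):
                hits = sum(1 for o in objs.values() if comp & o)
                if hits > 1:
                    return False
            return True

        edges = list(g.edges)
        want = None
        for k in range(len(edges) + 1):
            for sub in itertools.combinations(edges, k):
                h = g.copy()
                h.remove_edges_from(sub)
                if separated(h):
                    want = k
                    break
            if want is not None:
                break
        assert got == want

    def test_empty_skeletons_raise(self, small_synth_labels):
        with pytest.raises(ValueError):
            mcm_edits(SkeletonSet({}, VS), small_synth_labels)

    def test_metrics_invariant_to_label_permutation(self, small_synth_labels):
        sk = skeletonize(small_synth_labels)
        perm = small_synth_labels.data.copy()
        ids = np.unique(perm)[1:]
        remap = np.zeros(perm.max() + 1, perm.dtype)
        remap[ids] = ids[::-1]
        permuted = LabelVolume(remap[perm], VS)
        a = mcm_edits(sk, small_synth_labels)
        b = mcm_edits(sk, permuted)
        assert (a.splits, a.merges) == (b.splits, b.merges)


class TestVoi:
    def test_zero_for_relabeled_identical(self, small_synth_labels):
        ids = np.unique(small_synth_labels.data)[1:]
        remap = np.zeros(small_synth_labels.data.max() + 1,
                         small_synth_labels.data.dtype)
        remap[ids] = ids[::-1]
        seg = LabelVolume(remap[small_synth_labels.data], VS)
        assert voi(seg, small_synth_labels) == (0.0, 0.0)

    def test_half_split_is_one_bit(self):
        gt = LabelVolume(np.ones((2, 2, 2), np.uint32), VS)
        seg = np.ones((2, 2, 2), np.uint32)
        seg[1] = 2
        vs, vm = voi(LabelVolume(seg, VS), gt)
        assert vs == pytest.approx(1.0) and vm == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gt = rng.integers(0, 4, (6, 6, 6)).astype(np.uint32)
        seg = rng.integers(0, 5, (6, 6, 6)).astype(np.uint32)
        got = voi(LabelVolume(seg, VS), LabelVolume(gt, VS))

        # naive double-loop oracle
        joint = {}
        for idx in np.ndindex(gt.shape):
            if gt[idx] == 0:
                continue
            joint[(gt[idx], seg[idx])] = joint.get((gt[idx], seg[idx]), 0) + 1
        n = sum(joint.values())
        pg, ps = {}, {}
        for (g, s), c in joint.items():
            pg[g] = pg.get(g, 0) + c
            ps[s] = ps.get(s, 0) + c
        hj = -sum(c / n * np.log2(c / n) for c in joint.values())
        hg = -sum(c / n * np.log2(c / n) for c in pg.values())
        hs = -sum(c / n * np.log2(c / n) for c in ps.values())
        assert got[0] == pytest.approx(hj - hg, abs=1e-10)
        assert got[1] == pytest.approx(hj - hs, abs=1e-10)

    def test_corrective_merges_monotonically_reduce_voi(self):
        gt = np.ones((2, 2, 4), np.uint32)
        seg = np.arange(1, 17, dtype=np.uint32).reshape(2, 2, 4)
        totals = []
        # merge the over-segmented pieces pairwise toward ground truth
        while len(np.unique(seg)) >= 1:
            totals.append(sum(voi(LabelVolume(seg, VS), LabelVolume(gt, VS))))
            ids = np.unique(seg)
            if len(ids) == 1:
                break
            seg = np.where(seg == ids[-1], ids[0], seg)
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        assert totals[-1] == pytest.approx(0.0)

    def test_no_foreground_raises(self):
        with pytest.raises(ValueError):
            voi(LabelVolume(np.zeros((2, 2, 2), np.uint32), VS),
                LabelVolume(np.zeros((2, 2, 2), np.uint32), VS))


class TestEvaluateSegmentation:
    def test_perfect_segmentation_all_zero(self, small_synth_labels):
        rep = evaluate_segmentation(small_synth_labels, small_synth_labels,
                                    min_gt_size=0)
        assert rep["voi_sum"] == pytest.approx(0.0, abs=1e-9)
        assert rep["total_edits"] == 0

    def test_report_fields_consistent(self, small_synth_labels):
        seg = small_synth_labels.data.copy()
        seg[seg == seg.max()] = 1  # introduce a merge error
        rep = evaluate_segmentation(LabelVolume(seg, VS), small_synth_labels,
                                    min_gt_size=0)
        assert rep["total_edits"] == rep["splits"] + rep["merges"]
        assert rep["edits_per_object"] * rep["n_objects"] == pytest.approx(
            rep["total_edits"]
        )

    def test_deleting_object_adds_its_splits(self, small_synth_labels):
        gt = filter_gt(small_synth_labels, min_size=0)
        sk = skeletonize(gt)
        base = mcm_edits(sk, gt)
        seg = gt.data.copy()
        victim = int(gt.data.max())
        seg[seg == victim] = 0  # deleted object: its nodes all on background
        rep = mcm_edits(sk, LabelVolume(seg, VS))
        # ignored-background policy: the object simply contributes no islands
        assert rep.splits >= base.splits
        assert rep.merges == base.merges
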