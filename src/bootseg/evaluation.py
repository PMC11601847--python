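"""Segmentation accuracy: ground-truth preparation, the skeleton-based
min-cut edit metric (MCM), and variation of information (VOI).

The MCM estimates proofreading effort: how many split and merge edit
operations would a human need to correct a segmentation against
ground-truth skeletons.  We report the raw counts and two normalizations —
edits per ground-truth object, and edits per skeleton path length (per
micrometre) — so volumes of different sizes and object counts are
comparable.

Split edits: a ground-truth object whose skeleton nodes fall into several
segments (or into several disconnected islands of the same segment) needs
one merge-of-parts edit per extra island.  Merge edits: a predicted segment
containing nodes of k > 1 ground-truth objects needs as many cut edits as
the minimum number of edges whose removal separates the k objects in the
skeleton-node adjacency graph inside that segment (computed exactly on
small graphs).

VOI is reported in bits (base-2 entropies), restricted to ground-truth
foreground voxels.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .volumes import LabelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonSet",
    "MCMReport",
    "filter_gt",
    "skeletonize",
    "mcm_edits",
    "voi",
    "evaluate_segmentation",
    "read_swc_dir",
    "write_swc_dir",
]

_N26 = np.array([d for d in itertools.product((-1, 0, 1), repeat=3) if any(d)])


@dataclass
class SkeletonSet:
    """Per-object centerline graphs with physical coordinates.

    ``skeletons`` maps a ground-truth object ID to a connected
    ``networkx.Graph`` whose nodes carry ``pos`` (physical z, y, x) and
    ``voxel`` (integer z, y, x) attributes and whose edges carry ``length``
    (physical Euclidean distance).
    """

    skeletons: dict
    voxel_size: tuple = (1.0, 1.0, 1.0)
    offset: tuple = (0.0, 0.0, 0.0)

    def path_length(self, obj: int) -> float:
        g = self.skeletons[obj]
        return float(sum(d["length"] for _, _, d in g.edges(data=True)))

    @property
    def total_path_length(self) -> float:
        return float(sum(self.path_length(o) for o in self.skeletons))

    def __len__(self):
        return len(self.skeletons)


@dataclass
class MCMReport:
    """Split/merge edit counts with per-object and per-length normalizations."""

    splits: int
    merges: int
    n_objects: int
    total_path_length_um: float
    per_object: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.splits + self.merges

    @property
    def edits_per_object(self) -> float:
        return self.total / self.n_objects if self.n_objects else 0.0

    @property
    def edits_per_path_length(self) -> float:
        """Edits per micrometre of ground-truth skeleton path."""
        return self.total / self.total_path_length_um if self.total_path_length_um else 0.0

    def as_dict(self) -> dict:
        return {
            "splits": self.splits,
            "merges": self.merges,
            "total_edits": self.total,
            "n_objects": self.n_objects,
            "edits_per_object": self.edits_per_object,
            "total_path_length_um": self.total_path_length_um,
            "edits_per_path_length_um": self.edits_per_path_length,
            "per_object": self.per_object,
        }


def filter_gt(labels: LabelVolume, min_size: int = 500) -> LabelVolume:
    """Prepare ground truth: drop small components, relabel contiguously.

    Every label is split into its 26-connected components; components with
    strictly fewer than ``min_size`` voxels are set to background (a
    499-voxel component goes, a 500-voxel one stays); survivors are
    relabeled 1..n in deterministic (original ID, component) order.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    data = labels.data
    out = np.zeros(data.shape, dtype=np.uint32)
    structure = np.ones((3, 3, 3), dtype=bool)
    nxt = 1
    for l in np.unique(data):
        if l == 0:
            continue
        cc, n = ndimage.label(data == l, structure=structure)
        counts = np.bincount(cc.ravel())
        for i in range(1, n + 1):
            if counts[i] >= min_size:
                out[cc == i] = nxt
                nxt += 1
    return LabelVolume(out, labels.voxel_size, labels.offset)


def _graph_from_voxels(voxels: np.ndarray, voxel_size, offset) -> nx.Graph:
    """26-adjacency MST graph over skeleton voxels (physical edge lengths).

    The MST keeps the graph acyclic so thick junctions do not inflate the
    path length with redundant diagonals; disconnected pieces (a thinning
    artifact) are joined by their closest node pair to keep each object's
    graph connected.
    """
    vs = np.asarray(voxel_size, float)
    off = np.asarray(offset, float)
    g = nx.Graph()
    index = {tuple(v): i for i, v in enumerate(voxels)}
    for i, v in enumerate(voxels):
        g.add_node(i, voxel=tuple(int(c) for c in v), pos=tuple(v * vs + off))
    for v in voxels:
        i = index[tuple(v)]
        for d in _N26:
            w = tuple(v + d)
            j = index.get(w)
            if j is not None and j > i:
                g.add_edge(i, j, length=float(np.linalg.norm(d * vs)))
    g = nx.minimum_spanning_tree(g, weight="length")
    comps = [sorted(c) for c in nx.connected_components(g)]
    while len(comps) > 1:
        a = comps.pop()
        pa = np.array([g.nodes[i]["pos"] for i in a])
        rest = [i for c in comps for i in c]
        pr = np.array([g.nodes[i]["pos"] for i in rest])
        d = np.linalg.norm(pa[:, None] - pr[None], axis=2)
        ia, ir = np.unravel_index(np.argmin(d), d.shape)
        g.add_edge(a[ia], rest[ir], length=float(d[ia, ir]))
        comps = [sorted(c) for c in nx.connected_components(g)]
    return g


def skeletonize(labels: LabelVolume) -> SkeletonSet:
    """Centerline skeleton graph for every object of a label volume.

    3D topological thinning per object, then a graph over the skeleton
    voxels with physical edge lengths.  Single-voxel objects yield a single
    node with path length 0.  For data with externally curated skeletons,
    use :func:`read_swc_dir` instead and skip this step.
    """
    skels = {}
    for l in np.unique(labels.data):
        if l == 0:
            continue
        m = labels.data == l
        sk = _sk_skeletonize(m)
        if not sk.any():  # thinning can erase very small objects
            flat = np.argmax(ndimage.distance_transform_edt(m, sampling=labels.voxel_size))
            sk = np.zeros_like(m)
            sk[np.unravel_index(flat, m.shape)] = True
        voxels = np.argwhere(sk)
        skels[int(l)] = _graph_from_voxels(voxels, labels.voxel_size, labels.offset)
    return SkeletonSet(skels, labels.voxel_size, labels.offset)


# ----------------------------------------------------------------- MCM


def _node_segment(seg: LabelVolume, pos) -> int:
    vox = np.round((np.asarray(pos) - np.asarray(seg.offset)) / np.asarray(seg.voxel_size))
    vox = np.clip(vox, 0, np.asarray(seg.shape) - 1).astype(int)
    return int(seg.data[tuple(vox)])


def _exact_multiway_cut(g: nx.Graph, groups: dict) -> int:
    """Minimum number of edges whose removal separates all terminal groups.

    Exhaustive over edge subsets in increasing size (exponential; callers
    restrict to small graphs)."""
    edges = list(g.edges())
    terminals = list(groups.values())

    def separated(h):
        for comp in nx.connected_components(h):
            seen = set()
            for obj, nodes in groups.items():
                if comp & nodes:
                    seen.add(obj)
            if len(seen) > 1:
                return False
        return True

    if separated(g):
        return 0
    for k in range(1, len(edges) + 1):
        for sub in itertools.combinations(edges, k):
            h = g.copy()
            h.remove_edges_from(sub)
            if separated(h):
                return k
    return len(edges)


def _pairwise_st_cut(g: nx.Graph, a: set, b: set) -> int:
    h = nx.Graph()
    for u, v in g.edges():
        h.add_edge(u, v, capacity=1.0)
    src, snk = "__s__", "__t__"
    for n in a:
        h.add_edge(src, n, capacity=float("inf"))
    for n in b:
        h.add_edge(snk, n, capacity=float("inf"))
    if src not in h or snk not in h:
        return 0
    cut, _ = nx.minimum_cut(h, src, snk)
    return int(round(cut))


def _multiway_cut(g: nx.Graph, groups: dict) -> int:
    """Exact for 2 groups (max-flow) or small graphs (enumeration);
    isolating-cut heuristic otherwise."""
    groups = {k: set(v) for k, v in groups.items() if v}
    if len(groups) < 2 or g.number_of_edges() == 0:
        return 0
    if len(groups) == 2:
        a, b = groups.values()
        return _pairwise_st_cut(g, a, b)
    if g.number_of_edges() <= 16:
        return _exact_multiway_cut(g, groups)
    cuts = []
    for obj, nodes in groups.items():
        others = set().union(*(v for k, v in groups.items() if k != obj))
        cuts.append(_pairwise_st_cut(g, nodes, others))
    return int(sum(cuts) - max(cuts))


def mcm_edits(skeletons: SkeletonSet, seg: LabelVolume) -> MCMReport:
    """Count the split and merge edits needed to correct a segmentation.

    Each skeleton node is mapped to the segment under it (nodes on
    background are ignored).  See the module docstring for the exact split
    and merge definitions.
    """
    if len(skeletons) == 0:
        raise ValueError("empty skeleton set")

    node_seg = {}  # (obj, node) -> segment id
    for obj, g in skeletons.skeletons.items():
        for n, d in g.nodes(data=True):
            node_seg[(obj, n)] = _node_segment(seg, d["pos"])

    splits = 0
    per_object = {}
    for obj, g in skeletons.skeletons.items():
        groups = {}
        for n in g.nodes:
            s = node_seg[(obj, n)]
            if s == 0:
                continue
            groups.setdefault(s, set()).add(n)
        if not groups:
            per_object[obj] = {"splits": 0, "merges": 0}
            continue
        n_islands = sum(
            nx.number_connected_components(g.subgraph(nodes))
            for nodes in groups.values()
        )
        s_obj = n_islands - 1
        splits += s_obj
        per_object[obj] = {"splits": s_obj, "merges": 0}

    # merge edits per predicted segment hosting several objects
    seg_nodes: dict[int, dict] = {}
    for (obj, n), s in node_seg.items():
        if s == 0:
            continue
        seg_nodes.setdefault(s, {}).setdefault(obj, set()).add(n)

    merges = 0
    for s, groups in seg_nodes.items():
        if len(groups) < 2:
            continue
        h = nx.Graph()
        members = [(obj, n) for obj, nodes in groups.items() for n in nodes]
        h.add_nodes_from(members)
        # intra-object skeleton edges inside the segment
        for obj, nodes in groups.items():
            g = skeletons.skeletons[obj]
            for u, v in g.subgraph(nodes).edges():
                h.add_edge((obj, u), (obj, v))
        # bridging adjacencies between objects: 26-adjacent skeleton voxels
        vox = {m: skeletons.skeletons[m[0]].nodes[m[1]]["voxel"] for m in members}
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if a[0] == b[0]:
                    continue
                if max(abs(x - y) for x, y in zip(vox[a], vox[b])) <= 1:
                    h.add_edge(a, b)
        cut = _multiway_cut(h, {obj: {(obj, n) for n in nodes}
                                for obj, nodes in groups.items()})
        merges += cut
        share = cut / len(groups)
        for obj in groups:
            per_object[obj]["merges"] = per_object[obj].get("merges", 0) + share

    return MCMReport(
        splits=int(splits),
        merges=int(merges),
        n_objects=len(skeletons),
        total_path_length_um=skeletons.total_path_length / 1000.0,
        per_object=per_object,
    )


# ----------------------------------------------------------------- VOI


def voi(seg: LabelVolume, gt: LabelVolume) -> tuple[float, float]:
    """Variation of information, split and merge terms, in bits.

    ``voi_split = H(seg | gt)`` (over-segmentation), ``voi_merge =
    H(gt | seg)`` (under-segmentation), computed from the joint label
    contingency table over ground-truth foreground voxels.  Invariant to
    relabeling of either input.
    """
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch {seg.shape} vs {gt.shape}")
    fg = gt.data != 0
    if not fg.any():
        raise ValueError("no foreground voxels in ground truth")
    g = gt.data[fg].astype(np.int64)
    s = seg.data[fg].astype(np.int64)
    n = g.size

    def entropy(counts):
        p = counts / n
        return float(-np.sum(p * np.log2(p)))

    _, gc = np.unique(g, return_counts=True)
    _, sc = np.unique(s, return_counts=True)
    _, jc = np.unique(g * (s.max() + 1) + s, return_counts=True)
    h_g, h_s, h_gs = entropy(gc), entropy(sc), entropy(jc)
    # conditional entropies are >= 0; clamp float cancellation noise
    return max(0.0, h_gs - h_g), max(0.0, h_gs - h_s)  # H(seg|gt), H(gt|seg)


def evaluate_segmentation(
    seg: LabelVolume,
    gt_labels: LabelVolume,
    skeletons: SkeletonSet | None = None,
    min_gt_size: int = 500,
    out_json: str | None = None,
) -> dict:
    """Full evaluation: GT filtering, VOI, and skeleton edit metrics.

    Filters/relabels the ground truth, skeletonizes it unless skeletons are
    supplied, and reports VOI together with the MCM edit counts and their
    normalizations as a machine-readable dict (optionally written to JSON).
    """
    gt = filter_gt(gt_labels, min_size=min_gt_size)
    if gt.data.max() == 0:
        raise ValueError("ground truth empty after size filtering")
    vs_split, vs_merge = voi(seg, gt)
    if skeletons is None:
        skeletons = skeletonize(gt)
    report = mcm_edits(skeletons, seg)
    result = {
        "voi_split": vs_split,
        "voi_merge": vs_merge,
        "voi_sum": vs_split + vs_merge,
        "voi_units": "bits, ground-truth foreground only",
        **report.as_dict(),
    }
    if out_json:
        with open(out_json, "w") as f:
            json.dump(result, f, indent=2)
    return result


# ----------------------------------------------------------------- SWC


def write_swc_dir(skeletons: SkeletonSet, directory: str):
    """One SWC file per object (coordinates in physical nm, x y z order)."""
    os.makedirs(directory, exist_ok=True)
    for obj, g in skeletons.skeletons.items():
        lines = ["# bootseg skeleton, coords nm (x y z)"]
        order = {n: i + 1 for i, n in enumerate(sorted(g.nodes))}
        tree = nx.bfs_tree(g, sorted(g.nodes)[0]) if g.number_of_nodes() > 1 else None
        for n in sorted(g.nodes):
            z, y, x = g.nodes[n]["pos"]
            if tree is not None and n in tree and list(tree.predecessors(n)):
                parent = order[list(tree.predecessors(n))[0]]
            else:
                parent = -1
            lines.append(f"{order[n]} 0 {x:.3f} {y:.3f} {z:.3f} 1.0 {parent}")
        with open(os.path.join(directory, f"skeleton_{obj}.swc"), "w") as f:
            f.write("\n".join(lines) + "\n")


def read_swc_dir(directory: str, voxel_size=(1.0, 1.0, 1.0), offset=(0.0, 0.0, 0.0)) -> SkeletonSet:
    """Load skeletons from ``skeleton_<id>.swc`` files (physical nm coords)."""
    skels = {}
    vs = np.asarray(voxel_size, float)
    off = np.asarray(offset, float)
    for fn in sorted(os.listdir(directory)):
        if not fn.endswith(".swc"):
            continue
        obj = int(fn.split("_")[-1].split(".")[0])
        g = nx.Graph()
        rows = {}
        with open(os.path.join(directory, fn)) as f:
            for line in f:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                nid, _, x, y, z, _, parent = line.split()
                rows[int(nid)] = (float(z), float(y), float(x), int(parent))
        for nid, (z, y, x, _) in rows.items():
            pos = np.array([z, y, x])
            vox = tuple(int(c) for c in np.round((pos - off) / vs))
            g.add_node(nid, pos=(z, y, x), voxel=vox)
        for nid, (_, _, _, parent) in rows.items():
            if parent != -1 and parent in rows:
                pa = np.array(g.nodes[parent]["pos"])
                pb = np.array(g.nodes[nid]["pos"])
                g.add_edge(parent, nid, length=float(np.linalg.norm(pa - pb)))
        skels[obj] = g
    return SkeletonSet(skels, tuple(vs), tuple(off))
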