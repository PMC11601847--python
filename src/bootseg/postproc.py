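"""Affinities to instance segmentation: threshold, distance-transform
watershed, region adjacency graph, hierarchical agglomeration.

The chain is the standard boundary-based pipeline: predicted affinities are
pooled per voxel and thresholded into a binary foreground mask; an
anisotropy-aware Euclidean distance transform of the mask is seeded at its
local maxima and flooded by watershed into supervoxels (an
over-segmentation); touching supervoxels become edges of a region adjacency
graph scored by the mean affinity over their shared boundary; edges are
then merged hierarchically in order of decreasing score down to a merge
threshold.

Everything is deterministic: equal-score edges are processed by ascending
``(u, v)`` ID pair, and seed ordering is lexicographic in voxel coordinates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .targets import AffinityVolume
from .volumes import LabelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SegParams",
    "SupervoxelGraph",
    "affinities_to_mask",
    "watershed_fragments",
    "build_rag",
    "agglomerate",
    "segment",
    "grid_search",
]


@dataclass
class SegParams:
    """Post-processing parameters (the grid-search axes).

    ``threshold`` is applied to the per-voxel pooled affinity; the default
    is deliberately low so that, for near-binary affinities, every voxel
    with at least one confident same-object neighbor stays foreground.
    ``seed_min_distance`` is the minimum separation of watershed seeds in
    physical units.  ``min_segment_size`` of 0 disables the size filter
    (the strict size filter belongs to ground-truth preparation, not to
    predictions).
    """

    threshold: float = 0.1
    seed_min_distance: float = 40.0  # nm
    merge_threshold: float = 0.5
    min_segment_size: int = 0

    def __post_init__(self):
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        if not (0.0 <= self.merge_threshold <= 1.0 + 1e-9):
            raise ValueError("merge_threshold must be in [0, 1]")
        if self.seed_min_distance < 0 or self.min_segment_size < 0:
            raise ValueError("negative parameter")

    def astuple(self):
        return (self.threshold, self.seed_min_distance, self.merge_threshold,
                self.min_segment_size)


@dataclass
class SupervoxelGraph:
    """Region adjacency graph over watershed fragments.

    Node attributes: ``center`` (physical coords), ``size`` (voxels).
    Edge attributes: ``score`` (mean boundary affinity), ``aff_sum``,
    ``n_pairs``.  ``fragments`` keeps the provenance labeling.
    """

    graph: nx.Graph
    fragments: LabelVolume


def _incident_slices(shape, off):
    src = tuple(slice(0, s - abs(o)) if o >= 0 else slice(abs(o), s)
                for s, o in zip(shape, off))
    dst = tuple(slice(abs(o), s) if o >= 0 else slice(0, s - abs(o))
                for s, o in zip(shape, off))
    return src, dst


def affinities_to_mask(affs: AffinityVolume, threshold: float) -> np.ndarray:
    """Threshold pooled affinities into a binary foreground mask.

    Pooling rule: the mean over all *in-bounds incident* relations of a
    voxel — each offset relation (v, v+o) contributes its affinity value to
    both endpoints.  Background voxels (all incident affinities 0) never
    pass a non-negative threshold.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    data = affs.data
    shape = data.shape[1:]
    sums = np.zeros(shape, dtype=np.float64)
    counts = np.zeros(shape, dtype=np.int64)
    for c, off in enumerate(affs.neighborhood):
        src, dst = _incident_slices(shape, off)
        a = data[c][src]
        sums[src] += a
        counts[src] += 1
        sums[dst] += a
        counts[dst] += 1
    with np.errstate(invalid="ignore"):
        pooled = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return pooled > threshold


def watershed_fragments(
    mask: np.ndarray,
    seed_min_distance: float = 40.0,
    voxel_size=(1.0, 1.0, 1.0),
) -> LabelVolume:
    """Seeded watershed over-segmentation of a foreground mask.

    The Euclidean distance transform (physical units, anisotropy-aware) is
    seeded at its local maxima with the given minimum physical separation;
    watershed floods the negated distance within the mask.  Every mask voxel
    is assigned; background stays 0; each fragment is a 6-connected region.
    """
    mask = np.asarray(mask, bool)
    vs = np.asarray(voxel_size, float)
    if not mask.any():
        logger.warning("watershed_fragments: empty mask -> empty labeling")
        return LabelVolume(np.zeros(mask.shape, np.uint32), tuple(vs))

    edt = ndimage.distance_transform_edt(mask, sampling=vs)
    radii = [max(1, int(round(seed_min_distance / v))) for v in vs]
    footprint = np.ones([2 * r + 1 for r in radii], dtype=bool)
    cc, _ = ndimage.label(mask)  # 6-connected components
    coords = peak_local_max(edt, footprint=footprint, labels=cc, exclude_border=False)
    # guarantee at least one seed per mask component
    seeded = set(cc[tuple(coords.T)]) if len(coords) else set()
    extra = []
    for comp in np.unique(cc):
        if comp == 0 or comp in seeded:
            continue
        m = cc == comp
        flat = np.argmax(np.where(m, edt, -1.0))
        extra.append(np.unravel_index(flat, mask.shape))
    if extra:
        coords = np.vstack([coords, np.array(extra)]) if len(coords) else np.array(extra)
    order = np.lexsort(coords.T[::-1])  # deterministic seed numbering
    coords = coords[order]
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)

    frags = watershed(-edt, markers=markers, mask=mask, connectivity=1)
    return LabelVolume(frags.astype(np.uint32), tuple(vs))


def build_rag(fragments: LabelVolume, affs: AffinityVolume) -> SupervoxelGraph:
    """Region adjacency graph over fragments.

    One node per fragment (center of mass in physical coordinates, voxel
    count); one edge per face-touching fragment pair, scored by the mean
    affinity over the boundary voxel pairs between the two fragments.
    """
    frag = fragments.data
    if frag.shape != affs.data.shape[1:]:
        raise ValueError(f"fragments {frag.shape} vs affinities {affs.data.shape[1:]}")
    g = nx.Graph()
    ids = np.unique(frag)
    ids = ids[ids != 0]
    if len(ids):
        centers = ndimage.center_of_mass(frag > 0, frag, ids)
        sizes = ndimage.sum_labels(np.ones_like(frag), frag, ids)
        vs = np.asarray(fragments.voxel_size)
        off = np.asarray(fragments.offset)
        for i, c, s in zip(ids, centers, sizes):
            g.add_node(int(i), center=tuple(np.asarray(c) * vs + off), size=int(s))

    acc: dict[tuple[int, int], list] = {}
    for c, o in enumerate(affs.neighborhood):
        src, dst = _incident_slices(frag.shape, o)
        a, b = frag[src], frag[dst]
        sel = (a != b) & (a != 0) & (b != 0)
        if not sel.any():
            continue
        u = np.minimum(a[sel], b[sel]).astype(np.int64)
        v = np.maximum(a[sel], b[sel]).astype(np.int64)
        vals = affs.data[c][src][sel].astype(np.float64)
        key = u * (frag.max() + 1) + v
        uniq, inv = np.unique(key, return_inverse=True)
        ssum = np.bincount(inv, weights=vals)
        cnt = np.bincount(inv)
        for k, s, n in zip(uniq, ssum, cnt):
            uu, vv = int(k // (frag.max() + 1)), int(k % (frag.max() + 1))
            e = acc.setdefault((uu, vv), [0.0, 0])
            e[0] += float(s)
            e[1] += int(n)
    for (u, v), (s, n) in acc.items():
        g.add_edge(u, v, aff_sum=s, n_pairs=n, score=s / n)
    return SupervoxelGraph(graph=g, fragments=fragments)


def agglomerate(rag: SupervoxelGraph, merge_threshold: float = 0.5) -> LabelVolume:
    """Hierarchical agglomeration of the supervoxel graph.

    Edges are processed in order of decreasing score; an edge merges its two
    clusters when its current score is at least the merge threshold.  After
    a merge, edges to common neighbors are combined and rescored as the mean
    affinity over the union of boundary pairs — equivalent to truncating the
    merge hierarchy at the threshold.  Ties are broken by ascending node-ID
    pair.  The result is relabeled contiguously.
    """
    g = rag.graph
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # cluster-level edges keyed by sorted representative pair
    edges = {
        tuple(sorted((u, v))): [d["aff_sum"], d["n_pairs"]]
        for u, v, d in g.edges(data=True)
    }
    while edges:
        best, best_score = None, -1.0
        for (u, v), (s, n) in edges.items():
            sc = s / n
            if sc > best_score or (sc == best_score and (best is None or (u, v) < best)):
                best, best_score = (u, v), sc
        if best_score < merge_threshold:
            break
        u, v = best
        edges.pop(best)
        ru, rv = find(u), find(v)
        keep, drop = (ru, rv) if ru < rv else (rv, ru)
        parent[drop] = keep
        # re-key and combine affected edges
        new_edges = {}
        for (a, b), sn in edges.items():
            a2, b2 = find(a), find(b)
            if a2 == b2:
                continue  # became internal
            key = (a2, b2) if a2 < b2 else (b2, a2)
            if key in new_edges:
                new_edges[key][0] += sn[0]
                new_edges[key][1] += sn[1]
            else:
                new_edges[key] = list(sn)
        edges = new_edges

    roots = sorted({find(n) for n in g.nodes})
    root_id = {r: i + 1 for i, r in enumerate(roots)}
    mapping = np.zeros(int(rag.fragments.data.max()) + 1, dtype=np.uint32)
    for n in g.nodes:
        mapping[n] = root_id[find(n)]
    out = mapping[rag.fragments.data]
    return LabelVolume(out, rag.fragments.voxel_size, rag.fragments.offset)


def _filter_small_segments(seg: LabelVolume, affs: AffinityVolume, min_size: int) -> LabelVolume:
    """Merge segments below ``min_size`` into their largest face-neighbor
    (ties by smallest ID); zero them if isolated."""
    data = seg.data.copy()
    ids, counts = np.unique(data, return_counts=True)
    small = {int(i) for i, c in zip(ids, counts) if i != 0 and c < min_size}
    if not small:
        return seg
    sizes = {int(i): int(c) for i, c in zip(ids, counts) if i != 0}
    neighbors: dict[int, set] = {s: set() for s in small}
    for o in affs.neighborhood:
        src, dst = _incident_slices(data.shape, o)
        a, b = data[src], data[dst]
        sel = (a != b) & (a != 0) & (b != 0)
        for x, y in zip(a[sel].ravel(), b[sel].ravel()):
            x, y = int(x), int(y)
            if x in small:
                neighbors[x].add(y)
            if y in small:
                neighbors[y].add(x)
    for s in sorted(small):
        cand = [n for n in neighbors[s] if n not in small]
        if cand:
            target = max(cand, key=lambda n: (sizes[n], -n))
            data[data == s] = target
        else:
            data[data == s] = 0
    # contiguous relabel
    ids = np.unique(data)
    ids = ids[ids != 0]
    mapping = np.zeros(int(data.max()) + 1, dtype=np.uint32)
    for i, l in enumerate(sorted(int(x) for x in ids), start=1):
        mapping[l] = i
    return LabelVolume(mapping[data], seg.voxel_size, seg.offset)


def segment(affs: AffinityVolume, params: SegParams | None = None) -> LabelVolume:
    """Full affinity-to-segmentation chain.

    Threshold -> watershed fragments -> RAG -> agglomeration, followed by
    the optional minimum-segment-size filter.  With ideal (binary)
    affinities of a wall-separated label volume this recovers the labels
    exactly up to relabeling.
    """
    params = params or SegParams()
    mask = affinities_to_mask(affs, params.threshold)
    frags = watershed_fragments(mask, params.seed_min_distance, affs.voxel_size)
    if frags.data.max() == 0:
        return frags
    rag = build_rag(frags, affs)
    seg = agglomerate(rag, params.merge_threshold)
    if params.min_segment_size > 0:
        seg = _filter_small_segments(seg, affs, params.min_segment_size)
    return seg


def grid_search(
    affs: AffinityVolume,
    param_grid: dict,
    gt: LabelVolume,
    metric: str = "voi",
    skeletons=None,
):
    """Exhaustive search over post-processing parameters.

    ``param_grid`` maps :class:`SegParams` field names to value lists; every
    combination is evaluated against the ground truth with the chosen metric
    (``"voi"``: split + merge VOI; ``"mcm"``: total skeleton edits, requires
    ``skeletons``).  Returns ``(best_params, table)`` where the table lists
    every grid point with its metric.  Ties are broken by lexicographic
    parameter order, so the search is deterministic.
    """
    from .evaluation import mcm_edits, voi

    if metric not in ("voi", "mcm"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "mcm" and skeletons is None:
        raise ValueError("metric 'mcm' requires skeletons")
    names = sorted(param_grid)
    if not names or any(len(param_grid[n]) == 0 for n in names):
        raise ValueError("empty parameter grid")

    table = []
    best = None
    for values in itertools.product(*(sorted(param_grid[n]) for n in names)):
        params = replace(SegParams(), **dict(zip(names, values)))
        seg = segment(affs, params)
        if metric == "voi":
            vs, vm = voi(seg, gt)
            score = vs + vm
        else:
            score = float(mcm_edits(skeletons, seg).total)
        table.append({"params": params, "metric": score})
        if best is None or score < best[0]:
            best = (score, params)
    return best[1], table
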