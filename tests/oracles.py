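"""Independent brute-force oracles used by the test suite.

Each oracle applies the *definition* of an operation directly (loops,
enumeration, naive summation) without sharing code with the implementation
it checks.
"""

import itertools

import networkx as nx
import numpy as np

from bootseg.targets import _gaussian_kernel


def affinity_oracle(lab, neighborhood):
    """Exhaustive per voxel/offset application of the affinity rule."""
    out = np.zeros((len(neighborhood),) + lab.shape)
    for c, off in enumerate(neighborhood):
        for idx in np.ndindex(lab.shape):
            n = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= ni < s for ni, s in zip(n, lab.shape)):
                if lab[idx] == lab[n] != 0:
                    out[(c,) + idx] = 1.0
    return out


def lsd_oracle(lab, sigma, voxel_size):
    """Direct Gaussian-weighted own-label moments per voxel (no convolutions)."""
    nd = lab.ndim
    sigma = np.broadcast_to(np.atleast_1d(np.asarray(sigma, float)), (nd,))
    vs = np.asarray(voxel_size, float)
    kernels = [_gaussian_kernel(s) for s in sigma / vs]
    radii = [(len(k) - 1) // 2 for k in kernels]
    pairs = [(a, b) for a in range(nd) for b in range(a + 1, nd)]
    out = np.zeros((2 * nd + len(pairs) + 1,) + lab.shape)
    w_full = kernels[0]
    for k in kernels[1:]:
        w_full = np.multiply.outer(w_full, k)

    for idx in np.ndindex(lab.shape):
        l = lab[idx]
        if l == 0:
            continue
        lo = [i - r for i, r in zip(idx, radii)]
        hi = [i + r + 1 for i, r in zip(idx, radii)]
        sl = tuple(slice(max(a, 0), min(b, s)) for a, b, s in zip(lo, hi, lab.shape))
        wsl = tuple(slice(s.start - a, s.stop - a) for s, a in zip(sl, lo))
        w = w_full[wsl] * (lab[sl] == l)
        m0 = w.sum()
        grids = np.meshgrid(*(np.arange(s.start, s.stop, dtype=float) for s in sl),
                            indexing="ij")
        mu = np.array([(w * g).sum() / m0 for g in grids])
        cov = np.empty((nd, nd))
        for a in range(nd):
            for b in range(nd):
                cov[a, b] = (w * grids[a] * grids[b]).sum() / m0 - mu[a] * mu[b]
        vals = []
        for a in range(nd):
            vals.append(0.5 + (mu[a] - idx[a]) * vs[a] / (6 * sigma[a]))
        for a in range(nd):
            vals.append(cov[a, a] * vs[a] ** 2 / (3 * sigma[a]) ** 2)
        for a, b in pairs:
            denom = np.sqrt(max(cov[a, a] * cov[b, b], 0)) + 1e-10
            vals.append(0.5 + 0.5 * cov[a, b] / denom)
        vals.append(m0)
        out[(slice(None),) + idx] = np.clip(vals, 0, 1)
    return out


def agglomerate_oracle(graph, fragments, m):
    """Independent greedy hierarchy: recompute every cluster-pair score from
    the original edge sums each round, merge the best >= m."""
    clusters = {n: {n} for n in graph.nodes}
    while True:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            s = n = 0
            for u in clusters[a]:
                for v in clusters[b]:
                    if graph.has_edge(u, v):
                        s += graph[u][v]["aff_sum"]
                        n += graph[u][v]["n_pairs"]
            if n == 0:
                continue
            key = tuple(sorted((a, b)))
            if best is None or s / n > best[0] or (s / n == best[0] and key < best[1]):
                best = (s / n, key)
        if best is None or best[0] < m:
            break
        a, b = best[1]
        clusters[min(a, b)] = clusters.pop(a) | clusters.pop(b)
    mapping = {}
    for i, r in enumerate(sorted(clusters), 1):
        for n in clusters[r]:
            mapping[n] = i
    out = np.zeros_like(fragments.data)
    for n, l in mapping.items():
        out[fragments.data == n] = l
    return out


def multiway_cut_enum(g: nx.Graph, groups: dict) -> int:
    """Minimum multiway cut by exhaustive enumeration over edge subsets."""
    groups = {k: set(v) for k, v in groups.items() if v}

    def separated(h):
        for comp in nx.connected_components(h):
            if sum(1 for o in groups.values() if comp & o) > 1:
                return False
        return True

    edges = list(g.edges)
    for k in range(len(edges) + 1):
        for sub in itertools.combinations(edges, k):
            h = g.copy()
            h.remove_edges_from(sub)
            if separated(h):
                return k
    return len(edges)


def naive_voi(seg: np.ndarray, gt: np.ndarray):
    """Double-loop contingency-table VOI (bits, gt-foreground only)."""
    joint = {}
    for idx in np.ndindex(gt.shape):
        if gt[idx] == 0:
            continue
        key = (int(gt[idx]), int(seg[idx]))
        joint[key] = joint.get(key, 0) + 1
    n = sum(joint.values())
    pg, ps = {}, {}
    for (g, s), c in joint.items():
        pg[g] = pg.get(g, 0) + c
        ps[s] = ps.get(s, 0) + c
    hj = -sum(c / n * np.log2(c / n) for c in joint.values())
    hg = -sum(c / n * np.log2(c / n) for c in pg.values())
    hs = -sum(c / n * np.log2(c / n) for c in ps.values())
    return hj - hg, hj - hs
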