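"""Training targets and losses: direct-neighbor affinities, local shape
descriptors (LSDs), masked weighted-MSE, and LSD error maps.

Affinity convention
-------------------
Channel ``c`` at voxel ``v`` encodes the connectivity between ``v`` and
``v + offset_c`` for a unit offset along one axis: 1 if both voxels carry the
same nonzero instance ID, 0 otherwise (including across the volume border).
Background-background pairs are 0 — background is "no object", which is what
lets watershed post-processing leave it unsegmented.

LSD convention
--------------
Per-voxel Gaussian-weighted statistics of the voxel's *own-label* mask,
window truncated at 3 sigma (physical units):

* 3D, 10 channels: ``[mean-offset z,y,x | covariance diag z,y,x |
  pairwise correlation zy,zx,yx | size]``
* 2D, 6 channels (per section): ``[mean-offset y,x | cov diag y,x |
  correlation yx | size]``

Mean offsets are normalized from ``[-3s, 3s]`` to ``[0, 1]`` (0.5 = zero
offset), variances by ``(3s)^2``, correlations from ``[-1, 1]`` to
``[0, 1]``, and size is the Gaussian-weighted mask fraction of the window.
Background voxels map to the all-zero descriptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import AnnotationMask, LabelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityVolume",
    "LSDVolume",
    "LossWeights",
    "DEFAULT_NEIGHBORHOOD_3D",
    "DEFAULT_NEIGHBORHOOD_2D",
    "labels_to_affinities",
    "compute_lsds",
    "compute_section_lsds",
    "masked_weighted_mse",
    "masked_weighted_mse_grad",
    "balance_weights",
    "lsd_error_map",
    "open_error_mask",
]

DEFAULT_NEIGHBORHOOD_3D = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
DEFAULT_NEIGHBORHOOD_2D = ((0, 1, 0), (0, 0, 1))

_EPS = 1e-10


@dataclass
class AffinityVolume:
    """Per-voxel direct-neighbor connectivity, one channel per offset."""

    data: np.ndarray  # (C, z, y, x)
    neighborhood: tuple = DEFAULT_NEIGHBORHOOD_3D
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.neighborhood = tuple(tuple(int(c) for c in o) for o in self.neighborhood)
        if self.data.ndim != 4:
            raise ValueError(f"affinities must be (C, z, y, x), got {self.data.shape}")
        if self.data.shape[0] != len(self.neighborhood):
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.neighborhood)} offsets"
            )


@dataclass
class LSDVolume:
    """Per-voxel local shape descriptors, channel-first."""

    data: np.ndarray  # (C, z, y, x)
    sigma: tuple = (10.0, 10.0, 10.0)  # physical units (nm), per axis used
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"LSDs must be (C, z, y, x), got {self.data.shape}")


@dataclass
class LossWeights:
    """Non-negative per-voxel (optionally per-channel) loss weights."""

    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.size and self.data.min() < 0:
            raise ValueError("weights must be non-negative")


def _check_unit_offsets(neighborhood):
    for o in neighborhood:
        o = tuple(int(c) for c in o)
        if sum(abs(c) for c in o) != 1:
            raise ValueError(
                f"only direct-neighbor (unit) offsets are supported, got {o}"
            )


def labels_to_affinities(
    labels: LabelVolume | np.ndarray,
    neighborhood=DEFAULT_NEIGHBORHOOD_3D,
) -> AffinityVolume:
    """Binary direct-neighbor affinities of a label volume.

    ``aff[c][v] = 1`` iff ``labels[v] == labels[v + offset_c]`` and both are
    nonzero; 0 otherwise.  Offsets whose neighbor falls outside the volume
    give 0.
    """
    _check_unit_offsets(neighborhood)
    lab = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    vs = labels.voxel_size if isinstance(labels, LabelVolume) else (1.0, 1.0, 1.0)
    affs = np.zeros((len(neighborhood),) + lab.shape, dtype=np.float32)
    for c, off in enumerate(neighborhood):
        src = tuple(slice(0, s - abs(o)) if o >= 0 else slice(abs(o), s)
                    for s, o in zip(lab.shape, off))
        dst = tuple(slice(abs(o), s) if o >= 0 else slice(0, s - abs(o))
                    for s, o in zip(lab.shape, off))
        a = lab[src]
        b = lab[dst]
        affs[c][src] = ((a == b) & (a != 0)).astype(np.float32)
    return AffinityVolume(affs, neighborhood=neighborhood, voxel_size=vs)


def _gaussian_kernel(sigma_vox: float) -> np.ndarray:
    """Sampled Gaussian, truncated at 3 sigma, normalized to sum 1."""
    r = max(1, int(np.ceil(3.0 * sigma_vox)))
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma_vox**2))
    return k / k.sum()


def _smooth(arr: np.ndarray, kernels) -> np.ndarray:
    out = arr.astype(np.float64)
    for ax, k in enumerate(kernels):
        out = ndimage.correlate1d(out, k, axis=ax, mode="constant", cval=0.0)
    return out


def _lsds_nd(lab: np.ndarray, sigma_phys, voxel_size) -> np.ndarray:
    """Generic N-dim LSD computation (N = 2 or 3); returns (C, *spatial)."""
    ndim = lab.ndim
    sigma_phys = np.broadcast_to(np.atleast_1d(np.asarray(sigma_phys, float)), (ndim,))
    voxel_size = np.asarray(voxel_size, float)
    if np.any(sigma_phys <= 0):
        raise ValueError(f"sigma must be strictly positive, got {tuple(sigma_phys)}")
    sigma_vox = sigma_phys / voxel_size
    kernels = [_gaussian_kernel(s) for s in sigma_vox]

    pairs = [(a, b) for a in range(ndim) for b in range(a + 1, ndim)]
    n_channels = 2 * ndim + len(pairs) + 1
    out = np.zeros((n_channels,) + lab.shape, dtype=np.float64)

    coords = [np.arange(s, dtype=np.float64) for s in lab.shape]
    grids = np.meshgrid(*coords, indexing="ij")

    for l in np.unique(lab):
        if l == 0:
            continue
        m = lab == l
        mass = _smooth(m.astype(np.float64), kernels)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = [_smooth(m * g, kernels) / mass for g in grids]
            # raw second moments, then central covariances (voxel units)
            cov = {}
            for a in range(ndim):
                for b in range(a, ndim):
                    p = _smooth(m * grids[a] * grids[b], kernels) / mass
                    cov[(a, b)] = p - mu[a] * mu[b]

        idx = np.nonzero(m)
        for a in range(ndim):
            off_phys = (mu[a][idx] - grids[a][idx]) * voxel_size[a]
            out[a][idx] = 0.5 + off_phys / (6.0 * sigma_phys[a])
        for a in range(ndim):
            var_phys = cov[(a, a)][idx] * voxel_size[a] ** 2
            out[ndim + a][idx] = var_phys / (3.0 * sigma_phys[a]) ** 2
        for i, (a, b) in enumerate(pairs):
            denom = np.sqrt(np.clip(cov[(a, a)][idx] * cov[(b, b)][idx], 0, None)) + _EPS
            rho = cov[(a, b)][idx] / denom
            out[2 * ndim + i][idx] = 0.5 + 0.5 * rho
        out[-1][idx] = mass[idx]

    return np.clip(out, 0.0, 1.0)


def compute_lsds(labels: LabelVolume, sigma) -> LSDVolume:
    """3D local shape descriptors (10 channels) of a label volume.

    ``sigma`` is the Gaussian scale in physical units (scalar or per axis);
    the window is truncated at 3 sigma.  Background voxels get the all-zero
    descriptor.
    """
    data = _lsds_nd(labels.data, sigma, labels.voxel_size)
    sig = tuple(np.broadcast_to(np.atleast_1d(np.asarray(sigma, float)), (3,)))
    return LSDVolume(data.astype(np.float32), sigma=sig, voxel_size=labels.voxel_size)


def compute_section_lsds(labels: LabelVolume, sigma) -> LSDVolume:
    """Stacked per-section 2D LSDs (6 channels) of a label volume.

    Each z-section is treated as an independent 2D image; sigma applies to
    the in-plane (y, x) axes in physical units.
    """
    vs_yx = labels.voxel_size[1:]
    sig2 = np.broadcast_to(np.atleast_1d(np.asarray(sigma, float))[-2:], (2,))
    sections = [
        _lsds_nd(labels.data[z], sig2, vs_yx) for z in range(labels.shape[0])
    ]
    data = np.stack(sections, axis=1)  # (6, z, y, x)
    return LSDVolume(
        data.astype(np.float32),
        sigma=(float(sig2[0]), float(sig2[1])),
        voxel_size=labels.voxel_size,
    )


def masked_weighted_mse(pred, target, weights) -> float:
    """Weighted MSE ``sum(w (p - t)^2) / max(sum(w), eps)``.

    Voxels with zero weight contribute nothing to the loss or its gradient,
    which is what restricts supervision to the annotated regions of a
    sparsely labeled volume.  Normalizing by the weight total (not the voxel
    count) keeps sparse and dense batches on a comparable loss scale.
    """
    pred, target, w = _broadcast_loss_args(pred, target, weights)
    denom = max(float(w.sum()), _EPS)
    return float(np.sum(w * (pred - target) ** 2) / denom)


def masked_weighted_mse_grad(pred, target, weights) -> np.ndarray:
    """Gradient of :func:`masked_weighted_mse` with respect to ``pred``.

    Exactly zero wherever the weight is zero.
    """
    pred, target, w = _broadcast_loss_args(pred, target, weights)
    denom = max(float(w.sum()), _EPS)
    return (2.0 * w * (pred - target) / denom).astype(np.float64)


def _broadcast_loss_args(pred, target, weights):
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    w = weights.data if isinstance(weights, LossWeights) else np.asarray(weights)
    w = np.asarray(w, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"pred {pred.shape} vs target {target.shape}")
    try:
        w = np.broadcast_to(w, pred.shape)
    except ValueError:
        raise ValueError(f"weights {w.shape} not broadcastable to {pred.shape}")
    return pred, target, w


def balance_weights(target, mask: AnnotationMask | np.ndarray, mode: str = "uniform") -> LossWeights:
    """Per-voxel loss weights from an annotation mask.

    ``uniform``: the mask cast to {0, 1}.  ``balanced``: additionally, for a
    (near-)binary target, rescales so the boundary class (target 0) and the
    interior class (target 1) carry equal total weight inside the mask —
    useful because boundary voxels are a small minority.
    """
    m = mask.data if isinstance(mask, AnnotationMask) else np.asarray(mask, bool)
    target = np.asarray(target)
    if target.ndim == m.ndim + 1:
        m = np.broadcast_to(m[None], target.shape)
    elif target.shape != m.shape:
        raise ValueError(f"mask {m.shape} does not match target {target.shape}")

    if not m.any():
        logger.warning("balance_weights: empty annotation mask -> all-zero weights")
        return LossWeights(np.zeros(target.shape), meta={"mode": mode})

    if mode == "uniform":
        w = m.astype(np.float64)
    elif mode == "balanced":
        w = m.astype(np.float64)
        pos = m & (target > 0.5)
        neg = m & ~(target > 0.5)
        n_pos, n_neg = pos.sum(), neg.sum()
        if n_pos and n_neg:
            total = float(n_pos + n_neg)
            w[pos] = 0.5 * total / n_pos
            w[neg] = 0.5 * total / n_neg
    else:
        raise ValueError(f"unknown weighting mode {mode!r}")
    return LossWeights(w, meta={"mode": mode})


def lsd_error_map(model_lsds, seg_lsds, *, return_diff: bool = False):
    """Per-voxel L2 norm over channels of the LSD difference.

    Comparing a model's predicted LSDs against LSDs recomputed from its own
    segmentation highlights regions where the segmentation disagrees with the
    learned shape statistics — a proofreading heat-map.  With
    ``return_diff``, the per-channel signed difference is also returned.
    """
    a = model_lsds.data if isinstance(model_lsds, LSDVolume) else np.asarray(model_lsds)
    b = seg_lsds.data if isinstance(seg_lsds, LSDVolume) else np.asarray(seg_lsds)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    diff = a.astype(np.float64) - b.astype(np.float64)
    err = np.sqrt(np.sum(diff**2, axis=0))
    if return_diff:
        return err, diff
    return err


def open_error_mask(error: np.ndarray, threshold: float, structuring_radius: int) -> np.ndarray:
    """Binary opening of the thresholded LSD error map.

    Removes high-error shells thinner than the structuring element — the
    minor boundary disagreements that are not real morphology errors —
    leaving only substantial error blobs.  Radius 0 is pure thresholding.
    """
    if threshold < 0 or structuring_radius < 0:
        raise ValueError("threshold and structuring_radius must be >= 0")
    error = np.asarray(error)
    mask = error > threshold
    if structuring_radius == 0:
        return mask
    from skimage.morphology import ball, disk

    selem = ball(structuring_radius) if error.ndim == 3 else disk(structuring_radius)
    return ndimage.binary_opening(mask, structure=selem)
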