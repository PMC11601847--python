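"""Training and tiled inference for the three networks of the pipeline.

1. ``train_sparse_2d`` — sparse-to-dense: a 2D U-Net learns dense 2D local
   shape descriptors from sparse instance annotations on one or a few
   sections.  Supervision is restricted to the annotated region by zeroing
   the loss weights outside the annotation mask, so the net extrapolates to
   unlabeled areas from what it learns in labeled ones.
2. ``train_3d_synthetic`` — a 3D U-Net learns to infer 3D direct-neighbor
   affinities from stacked (degraded) per-section 2D LSDs.  It trains purely
   on synthetic volumes generated on the fly and never consumes raw images,
   which keeps it dataset- and modality-agnostic.
3. ``train_mtlsd_3d`` — a 3D multi-task U-Net (affinities + 3D LSDs) trains
   on a dense pseudo ground-truth segmentation, without any masking.

Inference is overlap-tiled with a receptive-field context margin and is
deterministic; tiled and single-tile predictions agree to floating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import synth as _synth
from .nn import Adam, NetSpec, UNet, tiled_predict
from .targets import (
    AffinityVolume,
    LSDVolume,
    balance_weights,
    compute_lsds,
    labels_to_affinities,
    masked_weighted_mse,
    masked_weighted_mse_grad,
    _lsds_nd,
)
from .volumes import AnnotationMask, LabelVolume, RawVolume

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentParams",
    "TrainConfig",
    "sample_fov",
    "augment",
    "train_sparse_2d",
    "train_3d_synthetic",
    "train_mtlsd_3d",
    "predict_2d_stack",
    "predict_3d",
    "smoothed",
    "default_2d_spec",
    "default_3d_spec",
    "default_mtlsd_spec",
]


@dataclass
class AugmentParams:
    """Geometric + intensity augmentation settings.

    Geometric transforms are applied identically to raw, labels and mask;
    intensity transforms touch the raw image only.  Elastic deformation uses
    linear interpolation for intensities and nearest-neighbor for labels and
    mask (so augmented labels remain a subset of the input label set).
    """

    flip: bool = True
    transpose: bool = True
    intensity_scale: float = 0.1
    intensity_shift: float = 0.1
    elastic_magnitude: float = 0.0
    elastic_sigma: float = 8.0

    @classmethod
    def none(cls) -> "AugmentParams":
        return cls(flip=False, transpose=False, intensity_scale=0.0,
                   intensity_shift=0.0, elastic_magnitude=0.0)


@dataclass
class TrainConfig:
    """Desk-scale training defaults (CPU, minutes).

    ``patch_size`` is (z, y, x); use z = 1 for 2D training.  ``lsd_sigma``
    is the physical Gaussian scale (nm) of the LSD targets.  Every source of
    randomness derives from ``seed``.
    """

    patch_size: tuple = (16, 32, 32)
    iterations: int = 500
    batch_size: int = 1
    learning_rate: float = 2e-3
    lsd_sigma: float = 48.0
    weight_mode: str = "uniform"
    min_mask_fraction: float = 0.05
    augment: AugmentParams = field(default_factory=AugmentParams)
    seed: int = 0
    checkpoint_every: int = 0  # 0 = only final
    checkpoint_path: str | None = None


def default_2d_spec(features: int = 8) -> NetSpec:
    return NetSpec(ndim=2, in_channels=1, heads={"lsds": 6}, features=features)


def default_3d_spec(features: int = 8) -> NetSpec:
    return NetSpec(ndim=3, in_channels=6, heads={"affs": 3}, features=features,
                   down_factors=(1, 2, 2))


def default_mtlsd_spec(features: int = 8) -> NetSpec:
    return NetSpec(ndim=3, in_channels=1, heads={"affs": 3, "lsds": 10},
                   features=features, down_factors=(1, 2, 2))


def smoothed(trace, window: int = 50) -> np.ndarray:
    """Moving average of a loss trace (window clipped to the trace length)."""
    trace = np.asarray(trace, dtype=float)
    w = max(1, min(window, len(trace)))
    kernel = np.ones(w) / w
    return np.convolve(trace, kernel, mode="valid")


# ------------------------------------------------------------- sampling


def sample_fov(
    raw: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    patch_size: tuple,
    rng: np.random.Generator,
    min_mask_fraction: float = 0.05,
    max_tries: int = 100,
):
    """Sample an aligned (raw, labels, mask) patch, biased to annotations.

    Rejection sampling: uniform random corners, accepted once the annotation
    mask covers at least ``min_mask_fraction`` of the patch.  With fraction
    0 this reduces to uniform sampling.  If rejection fails (very sparse
    annotations), the patch is centered on a random annotated voxel.
    """
    if not mask.any():
        raise ValueError("cannot sample fields of view: annotation mask is empty")
    shape = mask.shape
    patch_size = tuple(int(p) for p in patch_size)
    if any(p > s for p, s in zip(patch_size, shape)):
        raise ValueError(f"patch {patch_size} larger than volume {shape}")
    hi = [s - p for s, p in zip(shape, patch_size)]

    def cut(corner):
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
        return raw[sl], labels[sl], mask[sl]

    for _ in range(max_tries):
        corner = [int(rng.integers(0, h + 1)) for h in hi]
        r, l, m = cut(corner)
        if min_mask_fraction <= 0 or m.mean() >= min_mask_fraction:
            return r, l, m
    # fallback: center on an annotated voxel
    idx = np.argwhere(mask)
    v = idx[int(rng.integers(0, len(idx)))]
    corner = [int(np.clip(c - p // 2, 0, h)) for c, p, h in zip(v, patch_size, hi)]
    return cut(corner)


def augment(raw, labels, mask, params: AugmentParams, rng: np.random.Generator):
    """Apply augmentations; geometric ones identically to all three arrays."""
    raw = np.asarray(raw, dtype=np.float64)
    labels = np.asarray(labels)
    mask = np.asarray(mask)
    nd = raw.ndim

    if params.flip:
        for ax in range(nd):
            if raw.shape[ax] > 1 and rng.random() < 0.5:
                raw = np.flip(raw, ax)
                labels = np.flip(labels, ax)
                mask = np.flip(mask, ax)
    if params.transpose and raw.shape[-1] == raw.shape[-2] and rng.random() < 0.5:
        order = list(range(nd))
        order[-1], order[-2] = order[-2], order[-1]
        raw = raw.transpose(order)
        labels = labels.transpose(order)
        mask = mask.transpose(order)
    if params.elastic_magnitude > 0:
        disp = []
        for _ in range(2):
            d = ndimage.gaussian_filter(rng.standard_normal(raw.shape),
                                        sigma=params.elastic_sigma)
            d *= params.elastic_magnitude / (np.abs(d).max() + 1e-12)
            disp.append(d)
        grids = list(np.meshgrid(*(np.arange(s, dtype=float) for s in raw.shape),
                                 indexing="ij"))
        grids[-2] = grids[-2] + disp[0]
        grids[-1] = grids[-1] + disp[1]
        coords = np.stack(grids)
        raw = ndimage.map_coordinates(raw, coords, order=1, mode="reflect")
        labels = ndimage.map_coordinates(labels, coords, order=0, mode="reflect")
        mask = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0,
                                       mode="reflect").astype(bool)
    if params.intensity_scale > 0:
        raw = raw * (1.0 + rng.uniform(-params.intensity_scale, params.intensity_scale))
    if params.intensity_shift > 0:
        raw = raw + rng.uniform(-params.intensity_shift, params.intensity_shift)
    if params.intensity_scale > 0 or params.intensity_shift > 0:
        raw = np.clip(raw, 0.0, 1.0)
    return np.ascontiguousarray(raw), np.ascontiguousarray(labels), np.ascontiguousarray(mask)


# ------------------------------------------------------------- training


def _check_finite(loss, step, trace):
    if not np.isfinite(loss):
        recent = [float(x) for x in trace[-5:]]
        raise RuntimeError(
            f"training diverged at step {step}: loss={loss!r}, recent={recent}"
        )


def _maybe_checkpoint(net, cfg: TrainConfig, step: int, final: bool = False):
    if cfg.checkpoint_path is None:
        return
    if final or (cfg.checkpoint_every and (step + 1) % cfg.checkpoint_every == 0):
        net.save(cfg.checkpoint_path, extra_meta={"step": step + 1, "seed": cfg.seed})


def train_sparse_2d(
    raw: RawVolume,
    labels: LabelVolume,
    mask: AnnotationMask,
    spec: NetSpec | None = None,
    cfg: TrainConfig | None = None,
):
    """Train the sparse-to-dense 2D LSD net on sparsely annotated sections.

    Per step: sample a field of view from annotated sections, augment,
    compute 2D LSD targets from the (augmented) sparse labels, and take a
    masked weighted-MSE step — zero weight, hence zero gradient, outside the
    annotation mask.  Returns ``(net, loss_trace)``.
    """
    spec = spec or default_2d_spec()
    cfg = cfg or TrainConfig(patch_size=(1, 64, 64))
    if spec.ndim != 2:
        raise ValueError("train_sparse_2d needs a 2D net spec")
    if not mask.data.any():
        raise ValueError("refusing to train: annotation mask is empty")
    pz, py, px = cfg.patch_size
    if pz != 1:
        raise ValueError("2D training expects patch_size (1, y, x)")
    for p, f in zip((py, px), spec.down_factors):
        if p % f:
            raise ValueError(f"patch size {cfg.patch_size} not divisible by {spec.down_factors}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x2D11]))
    net = UNet(spec, rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x11])))
    opt = Adam(lr=cfg.learning_rate)
    vs_yx = raw.voxel_size[1:]

    # only sections carrying annotation are eligible
    zs = np.nonzero(mask.data.reshape(mask.data.shape[0], -1).any(axis=1))[0]
    trace = []
    for step in range(cfg.iterations):
        z = int(zs[rng.integers(0, len(zs))])
        r, l, m = sample_fov(
            raw.data[z], labels.data[z], mask.data[z], (py, px), rng,
            cfg.min_mask_fraction,
        )
        r, l, m = augment(r, l, m, cfg.augment, rng)
        target = _lsds_nd(l, cfg.lsd_sigma, vs_yx)
        weights = balance_weights(target, m, mode=cfg.weight_mode)

        pred, cache = net.forward(r[None])
        loss = masked_weighted_mse(pred["lsds"], target, weights)
        _check_finite(loss, step, trace)
        g = masked_weighted_mse_grad(pred["lsds"], target, weights)
        grads = net.backward(cache, {"lsds": g})
        opt.step(net.params, grads)
        trace.append(loss)
        _maybe_checkpoint(net, cfg, step)
    _maybe_checkpoint(net, cfg, cfg.iterations - 1, final=True)
    return net, np.asarray(trace)


def train_3d_synthetic(
    spec: NetSpec | None = None,
    synth_cfg: "_synth.SynthConfig | None" = None,
    cfg: TrainConfig | None = None,
):
    """Train the 2D-stack-to-3D affinity net on on-the-fly synthetic data.

    Each step draws a fresh synthetic label volume (seeded from the training
    seed and the step index), simulates degraded stacked 2D LSDs as input and
    supervises the 3D affinity head.  No raw images are consumed.
    Returns ``(net, loss_trace)``.
    """
    spec = spec or default_3d_spec()
    cfg = cfg or TrainConfig()
    synth_cfg = synth_cfg or _synth.SynthConfig()
    if spec.ndim != 3 or "affs" not in spec.heads:
        raise ValueError("train_3d_synthetic needs a 3D spec with an 'affs' head")
    for p, f in zip(cfg.patch_size, spec.down_factors):
        if p % f:
            raise ValueError(f"patch {cfg.patch_size} not divisible by {spec.down_factors}")

    net = UNet(spec, rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x3D])))
    opt = Adam(lr=cfg.learning_rate)
    # training volumes are patch-sized; keep the configured instance density
    # (instances per voxel) and scale the fragment cutoff down with them
    ratio = float(np.prod(cfg.patch_size)) / float(np.prod(synth_cfg.shape))
    lo = max(2, int(round(synth_cfg.instance_range[0] * ratio)))
    hi = max(lo + 1, int(round(synth_cfg.instance_range[1] * ratio)))
    base = replace(
        synth_cfg,
        shape=tuple(cfg.patch_size),
        instance_range=(lo, hi),
        min_instance_size=min(synth_cfg.min_instance_size, 32),
    )
    trace = []
    for step in range(cfg.iterations):
        seed = int(np.random.SeedSequence([cfg.seed, 0x51, step]).generate_state(1)[0] % (2**31))
        inp, target, weights = _synth.make_training_pair(replace(base, seed=seed))
        if inp.data.shape[0] != spec.in_channels:
            raise ValueError(
                f"net expects {spec.in_channels} input channels, "
                f"stacked 2D LSDs provide {inp.data.shape[0]}"
            )
        pred, cache = net.forward(inp.data.astype(np.float64))
        loss = masked_weighted_mse(pred["affs"], target.data, weights)
        _check_finite(loss, step, trace)
        g = masked_weighted_mse_grad(pred["affs"], target.data, weights)
        grads = net.backward(cache, {"affs": g})
        opt.step(net.params, grads)
        trace.append(loss)
        _maybe_checkpoint(net, cfg, step)
    _maybe_checkpoint(net, cfg, cfg.iterations - 1, final=True)
    return net, np.asarray(trace)


def train_mtlsd_3d(
    raw: RawVolume,
    pseudo_gt: LabelVolume,
    spec: NetSpec | None = None,
    cfg: TrainConfig | None = None,
):
    """Train the 3D multi-task (affinities + LSDs) net on pseudo ground truth.

    The pseudo ground truth is consumed dense, with no annotation mask and
    no proofreading: every voxel supervises both heads every step.  The
    joint loss is the sum of the two head losses.  Dense targets are
    precomputed once from the pseudo ground truth; augmentation is
    intensity-only by default so the precomputed targets stay valid.
    Returns ``(net, trace)`` where ``trace`` has ``total``, ``affs`` and
    ``lsds`` per-step losses.
    """
    spec = spec or default_mtlsd_spec()
    cfg = cfg or TrainConfig(augment=AugmentParams(flip=False, transpose=False))
    if spec.ndim != 3 or set(spec.heads) != {"affs", "lsds"}:
        raise ValueError("train_mtlsd_3d needs a 3D spec with affs and lsds heads")
    if cfg.augment.flip or cfg.augment.transpose or cfg.augment.elastic_magnitude > 0:
        cfg = replace(cfg, augment=replace(cfg.augment, flip=False, transpose=False,
                                           elastic_magnitude=0.0))
        logger.info("geometric augmentation disabled for dense precomputed targets")

    affs_t = labels_to_affinities(pseudo_gt).data.astype(np.float64)
    lsds_t = compute_lsds(pseudo_gt, cfg.lsd_sigma).data.astype(np.float64)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x3D71]))
    net = UNet(spec, rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x31])))
    opt = Adam(lr=cfg.learning_rate)
    full = np.ones(pseudo_gt.shape, bool)
    trace = {"total": [], "affs": [], "lsds": []}
    for step in range(cfg.iterations):
        sl = tuple(
            slice(c, c + p)
            for c, p in zip(
                [int(rng.integers(0, s - p + 1)) for s, p in zip(pseudo_gt.shape, cfg.patch_size)],
                cfg.patch_size,
            )
        )
        r, _, _ = augment(raw.data[sl], pseudo_gt.data[sl], full[sl], cfg.augment, rng)
        ta = affs_t[(slice(None),) + sl]
        tl = lsds_t[(slice(None),) + sl]
        w = np.ones(1)  # dense supervision, no mask

        pred, cache = net.forward(r[None])
        la = masked_weighted_mse(pred["affs"], ta, np.broadcast_to(w, ta.shape))
        ll = masked_weighted_mse(pred["lsds"], tl, np.broadcast_to(w, tl.shape))
        loss = la + ll
        _check_finite(loss, step, trace["total"])
        grads = net.backward(cache, {
            "affs": masked_weighted_mse_grad(pred["affs"], ta, np.broadcast_to(w, ta.shape)),
            "lsds": masked_weighted_mse_grad(pred["lsds"], tl, np.broadcast_to(w, tl.shape)),
        })
        opt.step(net.params, grads)
        trace["total"].append(loss)
        trace["affs"].append(la)
        trace["lsds"].append(ll)
        _maybe_checkpoint(net, cfg, step)
    _maybe_checkpoint(net, cfg, cfg.iterations - 1, final=True)
    return net, {k: np.asarray(v) for k, v in trace.items()}


# ------------------------------------------------------------ inference


def predict_2d_stack(raw: RawVolume, net: UNet, tile: tuple | None = None) -> LSDVolume:
    """Predict per-section 2D LSDs for every section of a volume.

    Sections are predicted independently (duplicated sections give identical
    predictions) with overlap-tiled inference; output clipped to [0, 1].
    """
    if net.spec.ndim != 2:
        raise ValueError("predict_2d_stack needs a 2D net")
    out = []
    for z in range(raw.shape[0]):
        pred = tiled_predict(net, raw.data[z][None].astype(np.float64), tile=tile)
        out.append(pred["lsds"])
    data = np.stack(out, axis=1).astype(np.float32)
    return LSDVolume(data, sigma=(0.0, 0.0), voxel_size=raw.voxel_size)


def predict_3d(inp, net: UNet, tile: tuple | None = None) -> dict:
    """Tiled 3D inference; returns a dict with 'affs' (and 'lsds' for MTLSD).

    ``inp`` may be a stacked-2D :class:`LSDVolume`, a :class:`RawVolume`
    (single channel) or a channel-first array.
    """
    if net.spec.ndim != 3:
        raise ValueError("predict_3d needs a 3D net")
    if isinstance(inp, LSDVolume):
        x, vs = inp.data, inp.voxel_size
    elif isinstance(inp, RawVolume):
        x, vs = inp.data[None], inp.voxel_size
    else:
        x = np.asarray(inp)
        vs = (1.0, 1.0, 1.0)
        if x.ndim == 3:
            x = x[None]
    if x.shape[0] != net.spec.in_channels:
        raise ValueError(f"net expects {net.spec.in_channels} channels, got {x.shape[0]}")
    pred = tiled_predict(net, x.astype(np.float64), tile=tile)
    out = {}
    if "affs" in pred:
        out["affs"] = AffinityVolume(pred["affs"].astype(np.float32), voxel_size=vs)
    if "lsds" in pred:
        out["lsds"] = LSDVolume(pred["lsds"].astype(np.float32), voxel_size=vs)
    return out
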