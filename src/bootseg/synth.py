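"""On-the-fly synthetic training data for the 2D-stack-to-3D network.

The 3D network never sees real images: it learns the generic task "fuse a
stack of per-section 2D shape descriptors into 3D connectivity" from
synthetic label volumes alone, and is therefore dataset- and
modality-agnostic.  This module generates:

* neuropil-like 3D instance label volumes (space-filling, convoluted,
  separated by thin background walls, like plasma membranes between
  processes),
* simulated stacked 2D LSD predictions of those labels, degraded per
  section (mis-alignment shifts, noise, whole-section dropout) the way real
  per-section predictions are degraded,
* raw-like intensity volumes (dark membranes, per-instance texture, noise)
  so the sparse-to-dense 2D stage is testable end to end without real EM.

Everything is deterministic given the config seed.  The same generator
doubles as the repository-wide fixture factory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .targets import (
    AffinityVolume,
    LossWeights,
    LSDVolume,
    balance_weights,
    compute_section_lsds,
    labels_to_affinities,
)
from .volumes import LabelVolume, RawVolume

__all__ = [
    "SynthConfig",
    "generate_synthetic_labels",
    "simulate_stacked_2d_predictions",
    "make_training_pair",
    "simulate_raw",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic label / degradation model.

    Morphology: instances are watershed basins of smoothed noise seeded at
    random points, separated by 1-voxel background walls, then elastically
    deformed (in-plane displacements varying smoothly along z, mimicking
    section-to-section distortion).  Degradations act per z-section on the
    simulated stacked 2D predictions, independently across sections.
    """

    shape: tuple = (64, 64, 64)  # (z, y, x) voxels
    voxel_size: tuple = (40.0, 8.0, 8.0)  # nm, anisotropic like serial sections
    instance_range: tuple = (8, 20)  # inclusive bounds on seeded instance count
    smoothing_sigma: tuple = (1.0, 3.0, 3.0)  # voxels; shapes basin boundaries
    compactness: float = 0.02  # compact-watershed weight; balances basin sizes
    elastic_magnitude: float = 1.5  # px, in-plane displacement amplitude
    elastic_sigma: float = 12.0  # px, smoothness of the displacement field
    min_instance_size: int = 64  # voxels; smaller fragments are dropped
    min_foreground_fraction: float = 0.5
    lsd_sigma: float = 48.0  # nm, in-plane scale of the 2D descriptors
    shift_range: int = 1  # px, max |per-section in-plane shift|
    dropout_prob: float = 0.05  # per-section probability of a lost section
    noise_scale: float = 0.03  # additive Gaussian noise on the 2D predictions
    lowfreq_scale: float = 0.1  # raw-image low-frequency intensity wobble
    boundary_contrast: float = 0.5  # raw-image membrane darkening
    raw_noise_scale: float = 0.05  # raw-image additive noise
    weight_mode: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.shift_range < 0:
            raise ValueError("shift_range must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if any(s < 4 for s in self.shape):
            raise ValueError(f"shape {self.shape} too small to hold an instance")
        if self.instance_range[0] < 1 or self.instance_range[1] < self.instance_range[0]:
            raise ValueError(f"bad instance_range {self.instance_range}")


def _carve_walls(lab: np.ndarray) -> np.ndarray:
    """Zero one side of every face between two distinct nonzero labels.

    Afterwards no two distinct instances share a face, so every instance is
    recoverable from direct-neighbor affinities alone.  The voxel with the
    larger ID loses (deterministic tie-break).
    """
    out = lab.copy()
    for ax in range(lab.ndim):
        a = [slice(None)] * lab.ndim
        b = [slice(None)] * lab.ndim
        a[ax] = slice(0, -1)
        b[ax] = slice(1, None)
        a, b = tuple(a), tuple(b)
        for _ in range(2):  # repeat: zeroing can expose new adjacencies only once
            la, lb = out[a], out[b]
            clash = (la != lb) & (la != 0) & (lb != 0)
            kill_b = clash & (lb > la)
            kill_a = clash & (la > lb)
            out[b][kill_b] = 0
            out[a][kill_a] = 0
    return out


def _relabel(lab: np.ndarray, min_size: int) -> np.ndarray:
    """Split each ID into 6-connected components, drop small ones, relabel 1..n."""
    out = np.zeros(lab.shape, dtype=np.uint32)
    nxt = 1
    for l in np.unique(lab):
        if l == 0:
            continue
        cc, n = ndimage.label(lab == l)
        for i in range(1, n + 1):
            m = cc == i
            if m.sum() >= min_size:
                out[m] = nxt
                nxt += 1
    return out


def generate_synthetic_labels(cfg: SynthConfig) -> LabelVolume:
    """Generate a neuropil-like dense instance label volume.

    Smoothed Gaussian noise defines an elevation landscape; a watershed from
    randomly placed seeds partitions the volume into convoluted,
    space-filling basins; 1-voxel background walls are carved between
    touching basins; a smooth random in-plane deformation (varying along z)
    convolves the shapes; finally 6-connected components are relabeled and
    tiny fragments dropped.  Each output instance is one 6-connected (hence
    26-connected) component, and distinct instances never share a voxel
    face.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(int(s) for s in cfg.shape)

    noise = rng.standard_normal(shape)
    elev = ndimage.gaussian_filter(noise, sigma=cfg.smoothing_sigma)
    # rank-normalize the elevation so basin growth is not dominated by the
    # few deepest minima; the compactness term keeps basin sizes comparable
    # while the noise landscape keeps their boundaries convoluted
    order = np.argsort(elev, axis=None)
    elev = np.empty(elev.size)
    elev[order] = np.linspace(0.0, 1.0, elev.size)
    elev = elev.reshape(shape)

    n = int(rng.integers(cfg.instance_range[0], cfg.instance_range[1] + 1))
    flat = rng.choice(int(np.prod(shape)), size=n, replace=False)
    seeds = np.unravel_index(np.sort(flat), shape)
    markers = np.zeros(shape, dtype=np.int32)
    markers[seeds] = np.arange(1, n + 1)

    basins = watershed(elev, markers=markers, compactness=cfg.compactness)
    lab = _carve_walls(basins)

    if cfg.elastic_magnitude > 0:
        lab = _elastic_deform_labels(lab, cfg, rng)
        lab = _carve_walls(lab)  # deformation may re-join instances

    out = _relabel(lab, cfg.min_instance_size)
    n_out = int(out.max())
    if n_out == 0:
        raise ValueError("synthetic generation produced no instances; enlarge shape")
    if n_out > cfg.instance_range[1]:
        # deformation split-offs can exceed the requested count; keep the
        # largest instances so the count honors the configured bounds
        sizes = np.bincount(out.ravel())[1:]
        keep = np.argsort(-sizes, kind="stable")[: cfg.instance_range[1]] + 1
        mask = np.isin(out, keep)
        out = _relabel(np.where(mask, out, 0), cfg.min_instance_size)
    return LabelVolume(out, cfg.voxel_size, (0.0, 0.0, 0.0))


def _elastic_deform_labels(lab: np.ndarray, cfg: SynthConfig, rng) -> np.ndarray:
    """Smooth random in-plane displacement, nearest-neighbor for labels."""
    shape = lab.shape
    disp = []
    for _ in range(2):  # y and x components; z undisplaced (section integrity)
        d = rng.standard_normal(shape)
        d = ndimage.gaussian_filter(d, sigma=(cfg.elastic_sigma / 4, cfg.elastic_sigma, cfg.elastic_sigma))
        d *= cfg.elastic_magnitude / (np.abs(d).max() + 1e-12)
        disp.append(d)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    coords = np.stack([zz, yy + disp[0], xx + disp[1]])
    return ndimage.map_coordinates(lab, coords, order=0, mode="nearest")


def _int_shift_2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer in-plane shift with zero fill (no wrap-around)."""
    out = np.zeros_like(img)
    ys = slice(max(dy, 0), img.shape[-2] + min(dy, 0))
    xs = slice(max(dx, 0), img.shape[-1] + min(dx, 0))
    yd = slice(max(-dy, 0), img.shape[-2] + min(-dy, 0))
    xd = slice(max(-dx, 0), img.shape[-1] + min(-dx, 0))
    out[..., ys, xs] = img[..., yd, xd]
    return out


def simulate_stacked_2d_predictions(labels: LabelVolume, cfg: SynthConfig) -> LSDVolume:
    """Per-section 2D LSDs of a label volume, degraded like real predictions.

    Each z-section independently receives, in this order: a random integer
    in-plane shift in ``[-shift_range, shift_range]``, additive Gaussian
    noise clipped to [0, 1], and whole-section dropout to zeros with
    probability ``dropout_prob``.  Degradations are independent across
    sections and deterministic given ``cfg.seed``.
    """
    lsds = compute_section_lsds(labels, cfg.lsd_sigma)
    data = lsds.data.copy()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x2D]))
    nz = data.shape[1]
    for z in range(nz):
        if cfg.shift_range > 0:
            dy, dx = rng.integers(-cfg.shift_range, cfg.shift_range + 1, size=2)
            data[:, z] = _int_shift_2d(data[:, z], int(dy), int(dx))
        else:
            rng.integers(-1, 2, size=2)  # keep the stream layout stable
        if cfg.noise_scale > 0:
            data[:, z] = np.clip(
                data[:, z] + rng.normal(0, cfg.noise_scale, data[:, z].shape), 0.0, 1.0
            )
        else:
            rng.normal(0, 1.0, data[:, z].shape)
        if rng.random() < cfg.dropout_prob:
            data[:, z] = 0.0
    return LSDVolume(data, sigma=lsds.sigma, voxel_size=labels.voxel_size)


def make_training_pair(cfg: SynthConfig) -> tuple[LSDVolume, AffinityVolume, LossWeights]:
    """One synthetic training example for the 2D-stack-to-3D network.

    Input: degraded stacked 2D LSDs.  Target: 3D direct-neighbor affinities
    of the *same* synthetic labels.  Weights: over the full volume (dense
    synthetic supervision needs no annotation mask).
    """
    labels = generate_synthetic_labels(cfg)
    target = labels_to_affinities(labels)
    inp = simulate_stacked_2d_predictions(labels, cfg)
    weights = balance_weights(
        target.data, np.ones(labels.shape, bool), mode=cfg.weight_mode
    )
    return inp, target, weights


def simulate_raw(labels: LabelVolume, cfg: SynthConfig) -> RawVolume:
    """Raw-like intensity volume for a label volume.

    Background walls become dark membrane-like boundaries; each instance
    gets its own mean intensity (texture surrogate); a smooth low-frequency
    intensity field and additive noise mimic imaging artifacts.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xAA]))
    lab = labels.data
    img = np.full(lab.shape, 0.75, dtype=np.float64)

    ids = np.unique(lab)
    ids = ids[ids != 0]
    shade = {int(l): 0.65 + 0.25 * rng.random() for l in ids}
    for l, s in shade.items():
        img[lab == l] = s
    img[lab == 0] = 0.75 - cfg.boundary_contrast

    img = ndimage.gaussian_filter(img, sigma=(0.0, 0.7, 0.7))
    if cfg.lowfreq_scale > 0:
        lf = ndimage.gaussian_filter(rng.standard_normal(lab.shape), sigma=(4, 16, 16))
        lf *= cfg.lowfreq_scale / (np.abs(lf).max() + 1e-12)
        img = img + lf
    if cfg.raw_noise_scale > 0:
        img = img + rng.normal(0, cfg.raw_noise_scale, lab.shape)
    return RawVolume(np.clip(img, 0.0, 1.0), labels.voxel_size, labels.offset)


def with_seed(cfg: SynthConfig, seed: int) -> SynthConfig:
    """Copy of a config with a different seed (convenience for streams)."""
    return replace(cfg, seed=int(seed))
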