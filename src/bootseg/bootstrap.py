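"""Orchestration of the two-volume bootstrapping experiment.

The experiment takes two unannotated volumes.  Sparse 2D annotations exist
only on Volume 1.  The pipeline:

1. train the sparse-to-dense 2D LSD net on Volume 1's annotated sections;
2. train the 2D-stack-to-3D affinity net on synthetic volumes;
3. run both nets + post-processing on Volume 2 to produce a dense *pseudo
   ground truth* segmentation;
4. train a 3D multi-task (affinities + LSDs) net on (Volume 2 raw, pseudo
   ground truth) — dense, with no masking and no proofreading;
5. run the multi-task net + post-processing on Volume 1;
6. compute the LSD error map: the element-wise difference between the
   net's predicted LSDs and the LSDs recomputed from its own segmentation,
   a heat-map of likely segmentation errors for targeted proofreading.

Each stage writes its artifacts and a manifest entry (config hash + seed)
into a working directory; a rerun skips stages whose artifacts already
exist under the same configuration, so the pipeline is resumable.  Stage
seeds are derived from the master seed by hashing the stage name, making
every stage independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .models import (
    TrainConfig,
    default_2d_spec,
    default_3d_spec,
    default_mtlsd_spec,
    predict_2d_stack,
    predict_3d,
    train_3d_synthetic,
    train_mtlsd_3d,
    train_sparse_2d,
)
from .nn import NetSpec, UNet
from .postproc import SegParams, segment
from .synth import SynthConfig
from .targets import compute_lsds, lsd_error_map, open_error_mask
from .volumes import AnnotationMask, LabelVolume, RawVolume

__all__ = ["BootstrapConfig", "run_bootstrap", "lsd_error_overlay"]

STAGES = (
    "train_2d",
    "train_3d_synth",
    "pseudo_gt",
    "train_mtlsd",
    "segment_vol1",
    "lsd_errors",
)


@dataclass
class BootstrapConfig:
    """Inputs and per-stage settings of a bootstrapping run.

    Volumes are passed in memory (load them with
    :func:`bootseg.volumes.read_volume` first).  Per-stage training configs
    default to desk-scale settings; ``master_seed`` seeds every stage
    deterministically.
    """

    workdir: str
    vol1_raw: RawVolume = None
    vol1_labels: LabelVolume = None
    vol1_mask: AnnotationMask = None
    vol2_raw: RawVolume = None
    # the 2D stage is cheap, so it gets more features by default: the LSD
    # window (3 sigma ~ 18 px in-plane) needs the extra receptive field
    spec_2d: NetSpec = field(default_factory=lambda: default_2d_spec(features=12))
    spec_3d: NetSpec = field(default_factory=default_3d_spec)
    spec_mtlsd: NetSpec = field(default_factory=default_mtlsd_spec)
    train_2d: TrainConfig = None
    train_3d: TrainConfig = None
    train_mtlsd_cfg: TrainConfig = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    # post-processing operating points for *soft* predicted affinities (the
    # library-wide SegParams defaults target near-binary affinities instead).
    # The two inference stages are calibrated separately: the 2D->3D chain
    # (pseudo ground truth) has mid-range boundary responses, while the
    # multi-task net is sharply bimodal, so only a high merge threshold
    # separates its confident interiors from residual boundary smear.
    seg_params: SegParams = field(
        default_factory=lambda: SegParams(threshold=0.4, merge_threshold=0.7)
    )
    seg_params_final: SegParams = field(
        default_factory=lambda: SegParams(threshold=0.4, merge_threshold=0.9)
    )
    lsd_sigma: float = 48.0
    master_seed: int = 0

    def __post_init__(self):
        for name in ("vol1_raw", "vol1_labels", "vol1_mask", "vol2_raw"):
            if getattr(self, name) is None:
                raise ValueError(f"BootstrapConfig requires {name}")
        if self.train_2d is None:
            self.train_2d = TrainConfig(patch_size=(1, 64, 64), iterations=500)
        if self.train_3d is None:
            self.train_3d = TrainConfig(patch_size=(16, 32, 32), iterations=500)
        if self.train_mtlsd_cfg is None:
            self.train_mtlsd_cfg = TrainConfig(patch_size=(16, 32, 32), iterations=500)


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: hash of the stage name mixed with the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _cfg_hash(cfg: BootstrapConfig, stage: str) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, (RawVolume, LabelVolume, AnnotationMask)):
            return hashlib.sha256(np.ascontiguousarray(o.data).tobytes()).hexdigest()
        if isinstance(o, np.ndarray):
            return hashlib.sha256(np.ascontiguousarray(o).tobytes()).hexdigest()
        if isinstance(o, (list, tuple)):
            return [enc(x) for x in o]
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in o.items()}
        if isinstance(o, (str, int, float, bool)) or o is None:
            return o
        return repr(o)

    payload = json.dumps({"stage": stage, "cfg": enc(cfg)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: str):
        self.path = path
        self.data = {"stages": {}}
        if os.path.exists(path):
            with open(path) as f:
                self.data = json.load(f)

    def done(self, stage: str, cfg_hash: str) -> bool:
        e = self.data["stages"].get(stage)
        return bool(
            e
            and e.get("status") == "done"
            and e.get("config_hash") == cfg_hash
            and all(os.path.exists(p) for p in e.get("artifacts", []))
        )

    def record(self, stage: str, status: str, cfg_hash: str, seed: int, artifacts):
        self.data["stages"][stage] = {
            "status": status,
            "config_hash": cfg_hash,
            "seed": seed,
            "artifacts": list(artifacts),
        }
        with open(self.path, "w") as f:
            json.dump(self.data, f, indent=2)


def run_bootstrap(cfg: BootstrapConfig) -> dict:
    """Execute (or resume) the six-stage bootstrapping pipeline.

    Returns the artifact manifest: per stage, status, config hash, seed and
    artifact paths under ``cfg.workdir``.
    """
    os.makedirs(cfg.workdir, exist_ok=True)
    man = _Manifest(os.path.join(cfg.workdir, "manifest.json"))
    art = lambda *names: [os.path.join(cfg.workdir, n) for n in names]

    def run_stage(stage, fn, artifacts):
        h = _cfg_hash(cfg, stage)
        seed = stage_seed(cfg.master_seed, stage)
        if man.done(stage, h):
            return
        try:
            fn(seed)
        except Exception:
            man.record(stage, "failed", h, seed, artifacts)
            raise
        man.record(stage, "done", h, seed, artifacts)

    # 1 — sparse-to-dense 2D on Volume 1
    ck2d = os.path.join(cfg.workdir, "net2d")

    def s1(seed):
        tc = dataclasses.replace(cfg.train_2d, seed=seed, checkpoint_path=ck2d)
        net, trace = train_sparse_2d(cfg.vol1_raw, cfg.vol1_labels, cfg.vol1_mask,
                                     cfg.spec_2d, tc)
        np.save(os.path.join(cfg.workdir, "loss_2d.npy"), trace)

    run_stage("train_2d", s1, art("net2d.npz", "net2d.json", "loss_2d.npy"))

    # 2 — synthetic-trained 2D-stack-to-3D
    ck3d = os.path.join(cfg.workdir, "net3d")

    def s2(seed):
        tc = dataclasses.replace(cfg.train_3d, seed=seed, checkpoint_path=ck3d)
        net, trace = train_3d_synthetic(cfg.spec_3d, cfg.synth, tc)
        np.save(os.path.join(cfg.workdir, "loss_3d.npy"), trace)

    run_stage("train_3d_synth", s2, art("net3d.npz", "net3d.json", "loss_3d.npy"))

    # 3 — pseudo ground truth on Volume 2
    pgt_path = os.path.join(cfg.workdir, "pseudo_gt.npy")

    def s3(seed):
        net2d = UNet.load(ck2d)
        net3d = UNet.load(ck3d)
        lsds = predict_2d_stack(cfg.vol2_raw, net2d)
        affs = predict_3d(lsds, net3d)["affs"]
        pgt = segment(affs, cfg.seg_params)
        np.save(pgt_path, pgt.data)

    run_stage("pseudo_gt", s3, [pgt_path])

    # 4 — MTLSD on (Volume 2 raw, pseudo ground truth), dense, no mask
    ckmt = os.path.join(cfg.workdir, "net_mtlsd")

    def s4(seed):
        pgt = LabelVolume(np.load(pgt_path), cfg.vol2_raw.voxel_size,
                          cfg.vol2_raw.offset)
        assert not isinstance(pgt, AnnotationMask)  # consumed unmasked, as produced
        tc = dataclasses.replace(cfg.train_mtlsd_cfg, seed=seed, checkpoint_path=ckmt)
        net, trace = train_mtlsd_3d(cfg.vol2_raw, pgt, cfg.spec_mtlsd, tc)
        np.save(os.path.join(cfg.workdir, "loss_mtlsd.npy"), trace["total"])

    run_stage("train_mtlsd", s4,
              art("net_mtlsd.npz", "net_mtlsd.json", "loss_mtlsd.npy"))

    # 5 — segment Volume 1 with the bootstrapped net
    seg1_path = os.path.join(cfg.workdir, "seg_vol1.npy")
    lsds1_path = os.path.join(cfg.workdir, "model_lsds_vol1.npy")

    def s5(seed):
        net = UNet.load(ckmt)
        pred = predict_3d(cfg.vol1_raw, net)
        seg1 = segment(pred["affs"], cfg.seg_params_final)
        np.save(seg1_path, seg1.data)
        np.save(lsds1_path, pred["lsds"].data)

    run_stage("segment_vol1", s5, [seg1_path, lsds1_path])

    # 6 — LSD error heat-map on Volume 1
    err_path = os.path.join(cfg.workdir, "lsd_error_vol1.npy")

    def s6(seed):
        seg1 = LabelVolume(np.load(seg1_path), cfg.vol1_raw.voxel_size,
                           cfg.vol1_raw.offset)
        model_lsds = np.load(lsds1_path)
        seg_lsds = compute_lsds(seg1, cfg.lsd_sigma)
        err = lsd_error_map(model_lsds, seg_lsds.data)
        np.save(err_path, err)

    run_stage("lsd_errors", s6, [err_path])

    return man.data


def lsd_error_overlay(
    error: np.ndarray,
    raw: RawVolume,
    threshold: float = 0.3,
    opening_radius: int = 1,
    sections=None,
):
    """Per-section RGB composites of raw image + opened LSD error mask.

    High-error regions (after binary opening, which removes thin boundary
    shells) are tinted red on the grayscale image.  Pure visualization;
    returns one (y, x, 3) float array per requested section.
    """
    if error.shape != raw.shape:
        raise ValueError(f"error {error.shape} vs raw {raw.shape}")
    mask = open_error_mask(error, threshold, opening_radius)
    if sections is None:
        sections = range(raw.shape[0])
    out = []
    for z in sections:
        img = np.clip(raw.data[z].astype(np.float64), 0, 1)
        rgb = np.stack([img, img, img], axis=-1)
        m = mask[z]
        rgb[m, 0] = 0.6 * rgb[m, 0] + 0.4
        rgb[m, 1] *= 0.6
        rgb[m, 2] *= 0.6
        out.append(rgb)
    return out
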