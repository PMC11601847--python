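"""Minimal CPU U-Nets with manual backpropagation.

Small 2D/3D U-Nets (two resolution levels, 3^d same-padded convolutions,
average-pool down / nearest-neighbor up, sigmoid output heads) implemented
directly on numpy with im2col convolutions and Adam.  Deliberately tiny:
the training stages in this package are desk-scale demonstrations of the
learning problems (sparse-to-dense 2D LSDs, stacked-2D-to-3D affinities,
3D multi-task affinities+LSDs), sized to run in minutes on one CPU core.

All randomness flows through explicit ``numpy.random.Generator`` streams,
so fixed seeds give bit-reproducible runs in a single-threaded setting.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetSpec", "UNet", "Adam", "tiled_predict"]


@dataclass
class NetSpec:
    """Architecture description for a :class:`UNet`.

    ``down_factors`` is per-axis (anisotropy-aware: serial-section volumes
    use (1, 2, 2) so the coarse z axis is not pooled).  ``heads`` maps an
    output name to its channel count; the 3D multi-task net has both an
    ``affs`` (3) and an ``lsds`` (10) head.
    """

    ndim: int  # 2 or 3
    in_channels: int
    heads: dict  # name -> out channels
    features: int = 8
    down_factors: tuple = None

    def __post_init__(self):
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if self.down_factors is None:
            self.down_factors = (2, 2) if self.ndim == 2 else (1, 2, 2)
        self.down_factors = tuple(int(f) for f in self.down_factors)
        if len(self.down_factors) != self.ndim:
            raise ValueError("down_factors must have ndim entries")
        if not self.heads:
            raise ValueError("at least one output head required")

    @property
    def margin(self) -> tuple:
        """Per-axis context margin for tiled inference (multiple of the
        down factor, covering the receptive field of the two-level net)."""
        out = []
        for f in self.down_factors:
            m = 4 + 4 * f  # encoder/decoder convs + pooled bottom convs + alignment
            m = int(np.ceil(m / f) * f)
            out.append(m)
        return tuple(out)


# ---------------------------------------------------------------- layers


def _conv_forward(x, W, b):
    """Same-padded correlation as a sum of shifted matmuls.

    x: (Cin, *sp); W: (Cout, Cin, *k).  Returns (out, padded-input cache).
    """
    k = W.shape[2:]
    pad = [(0, 0)] + [(ks // 2, ks // 2) for ks in k]
    xp = np.pad(x, pad)
    sp = x.shape[1:]
    n = int(np.prod(sp))
    nk = int(np.prod(k))
    W2 = W.reshape(W.shape[0], W.shape[1], nk)
    out = np.zeros((W.shape[0], n))
    for ki in range(nk):
        off = np.unravel_index(ki, k)
        sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, sp))
        out += W2[:, :, ki] @ xp[sl].reshape(x.shape[0], n)
    out += b[:, None]
    return out.reshape((W.shape[0],) + sp), xp


def _conv_backward(grad_out, xp, x_shape, W):
    """Gradients of same-padded correlation (input, weights, bias)."""
    k = W.shape[2:]
    sp = x_shape[1:]
    cin = x_shape[0]
    n = int(np.prod(sp))
    nk = int(np.prod(k))
    g = grad_out.reshape(W.shape[0], n)
    W2 = W.reshape(W.shape[0], cin, nk)
    grad_W2 = np.empty_like(W2)
    grad_xp = np.zeros_like(xp)
    for ki in range(nk):
        off = np.unravel_index(ki, k)
        sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, sp))
        xs = xp[sl].reshape(cin, n)
        grad_W2[:, :, ki] = g @ xs.T
        grad_xp[sl] += (W2[:, :, ki].T @ g).reshape((cin,) + sp)
    grad_b = g.sum(axis=1)
    crop = (slice(None),) + tuple(slice(ks // 2, ks // 2 + s) for ks, s in zip(k, sp))
    return grad_xp[crop], grad_W2.reshape(W.shape), grad_b


def _avgpool(x, factors):
    sp = x.shape[1:]
    for s, f in zip(sp, factors):
        if s % f:
            raise ValueError(f"spatial shape {sp} not divisible by factors {factors}")
    shape = [x.shape[0]]
    for s, f in zip(sp, factors):
        shape += [s // f, f]
    v = x.reshape(shape)
    axes = tuple(range(2, v.ndim, 2))
    return v.mean(axis=axes)


def _avgpool_backward(grad, factors):
    scale = 1.0 / float(np.prod(factors))
    return _upsample(grad, factors) * scale


def _upsample(x, factors):
    out = x
    for ax, f in enumerate(factors):
        out = np.repeat(out, f, axis=ax + 1)
    return out


def _upsample_backward(grad, factors):
    out = grad
    for ax, f in enumerate(factors):
        sp = list(out.shape)
        sp[ax + 1] //= f
        out = out.reshape(sp[: ax + 2] + [f] + sp[ax + 2 :]).sum(axis=ax + 2)
    return out


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable


# ------------------------------------------------------------------ net


class UNet:
    """Two-level U-Net: (conv-relu)x2 -> pool -> (conv-relu)x2 -> up ->
    concat -> (conv-relu)x2 -> per-head 1x1 conv + sigmoid."""

    def __init__(self, spec: NetSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        nd, f = spec.ndim, spec.features
        k = (3,) * nd
        one = (1,) * nd

        def he(co, ci, kk):
            fan_in = ci * int(np.prod(kk))
            return rng.normal(0, np.sqrt(2.0 / fan_in), size=(co, ci) + kk)

        self.params = {
            "e0a_W": he(f, spec.in_channels, k), "e0a_b": np.zeros(f),
            "e0b_W": he(f, f, k), "e0b_b": np.zeros(f),
            "b0a_W": he(2 * f, f, k), "b0a_b": np.zeros(2 * f),
            "b0b_W": he(2 * f, 2 * f, k), "b0b_b": np.zeros(2 * f),
            "d0a_W": he(f, 3 * f, k), "d0a_b": np.zeros(f),
            "d0b_W": he(f, f, k), "d0b_b": np.zeros(f),
        }
        for name, c in spec.heads.items():
            self.params[f"h_{name}_W"] = he(c, f, one) * 0.1
            self.params[f"h_{name}_b"] = np.zeros(c)

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray):
        """x: (in_channels, *spatial). Returns dict head -> output, plus cache."""
        p = self.params
        fac = self.spec.down_factors
        c = {}

        def conv_relu(name, inp):
            z, cols = _conv_forward(inp, p[f"{name}_W"], p[f"{name}_b"])
            a = np.maximum(z, 0.0)
            c[name] = (inp.shape, cols, z > 0)
            return a

        e0 = conv_relu("e0b", conv_relu("e0a", x))
        pooled = _avgpool(e0, fac)
        b0 = conv_relu("b0b", conv_relu("b0a", pooled))
        up = _upsample(b0, fac)
        cat = np.concatenate([up, e0], axis=0)
        d0 = conv_relu("d0b", conv_relu("d0a", cat))

        outs = {}
        for name in self.spec.heads:
            z, cols = _conv_forward(d0, p[f"h_{name}_W"], p[f"h_{name}_b"])
            outs[name] = _sigmoid(z)
            c[f"h_{name}"] = (d0.shape, cols, outs[name])
        c["_split"] = b0.shape[0]
        return outs, c

    # -- backward --------------------------------------------------------
    def backward(self, cache, grad_heads: dict):
        """grad_heads: head name -> dLoss/dOutput. Returns param gradients."""
        p = self.params
        fac = self.spec.down_factors
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        def conv_relu_bwd(name, grad_a):
            x_shape, cols, relu_mask = cache[name]
            gz = grad_a * relu_mask
            gx, gW, gb = _conv_backward(gz, cols, x_shape, p[f"{name}_W"])
            grads[f"{name}_W"] += gW
            grads[f"{name}_b"] += gb
            return gx

        gd0 = None
        for name in self.spec.heads:
            if name not in grad_heads:
                continue
            d0_shape, cols, y = cache[f"h_{name}"]
            gz = grad_heads[name] * y * (1.0 - y)  # sigmoid'
            gx, gW, gb = _conv_backward(gz, cols, d0_shape, p[f"h_{name}_W"])
            grads[f"h_{name}_W"] += gW
            grads[f"h_{name}_b"] += gb
            gd0 = gx if gd0 is None else gd0 + gx
        if gd0 is None:
            return grads

        gcat = conv_relu_bwd("d0a", conv_relu_bwd("d0b", gd0))
        nb = cache["_split"]
        gup, ge0_skip = gcat[:nb], gcat[nb:]
        gb0 = _upsample_backward(gup, fac)
        gpooled = conv_relu_bwd("b0a", conv_relu_bwd("b0b", gb0))
        ge0 = _avgpool_backward(gpooled, fac) + ge0_skip
        conv_relu_bwd("e0a", conv_relu_bwd("e0b", ge0))
        return grads

    # -- persistence -----------------------------------------------------
    def save(self, path: str, extra_meta: dict | None = None):
        np.savez(path if path.endswith(".npz") else path + ".npz", **self.params)
        side = {
            "ndim": self.spec.ndim,
            "in_channels": self.spec.in_channels,
            "heads": self.spec.heads,
            "features": self.spec.features,
            "down_factors": list(self.spec.down_factors),
        }
        if extra_meta:
            side.update(extra_meta)
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as f:
            json.dump(side, f, indent=2)

    @classmethod
    def load(cls, path: str) -> "UNet":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as f:
            side = json.load(f)
        spec = NetSpec(
            ndim=side["ndim"],
            in_channels=side["in_channels"],
            heads=side["heads"],
            features=side["features"],
            down_factors=tuple(side["down_factors"]),
        )
        net = cls(spec)
        with np.load(base + ".npz") as z:
            for k in net.params:
                net.params[k] = z[k]
        return net


@dataclass
class Adam:
    """Adam over a dict of parameter arrays."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict, grads: dict):
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for k, g in grads.items():
            m = self._m.setdefault(k, np.zeros_like(g))
            v = self._v.setdefault(k, np.zeros_like(g))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ------------------------------------------------------------- inference


def _extract_padded(x: np.ndarray, start, size):
    """Window [start, start+size) per spatial axis with zero fill outside."""
    nd = x.ndim - 1
    out = np.zeros((x.shape[0],) + tuple(size), dtype=x.dtype)
    src, dst = [slice(None)], [slice(None)]
    for a in range(nd):
        s0, s1 = start[a], start[a] + size[a]
        c0, c1 = max(s0, 0), min(s1, x.shape[a + 1])
        if c0 >= c1:
            return out
        src.append(slice(c0, c1))
        dst.append(slice(c0 - s0, c1 - s0))
    out[tuple(dst)] = x[tuple(src)]
    return out


def tiled_predict(net: UNet, x: np.ndarray, tile: tuple | None = None) -> dict:
    """Overlap-tiled inference over ``x`` (C, *spatial).

    Each tile is evaluated with a zero-filled context margin equal to the
    net's receptive-field margin and only the central core is written, so
    the result is identical (to floating-point exactness) to evaluating the
    whole volume at once.  Tile cores are aligned to the pooling grid.
    """
    spec = net.spec
    nd = spec.ndim
    if x.ndim != nd + 1:
        raise ValueError(f"input must be (C, *{nd}D), got shape {x.shape}")
    if x.shape[0] != spec.in_channels:
        raise ValueError(f"expected {spec.in_channels} input channels, got {x.shape[0]}")
    sp = x.shape[1:]
    fac = spec.down_factors
    margin = spec.margin
    if tile is None:
        tile = tuple(min(64, int(np.ceil(s / f) * f)) for s, f in zip(sp, fac))
    tile = tuple(int(np.ceil(t / f) * f) for t, f in zip(tile, fac))
    for t, s in zip(tile, sp):
        if t < 1:
            raise ValueError("tile too small")

    outs = {name: np.zeros((c,) + sp, dtype=np.float64) for name, c in spec.heads.items()}
    starts = [list(range(0, s, t)) for s, t in zip(sp, tile)]
    for corner in np.array(np.meshgrid(*starts, indexing="ij")).reshape(nd, -1).T:
        in_start = [c - m for c, m in zip(corner, margin)]
        in_size = [t + 2 * m for t, m in zip(tile, margin)]
        patch = _extract_padded(x, in_start, in_size)
        pred, _ = net.forward(patch)
        core_dst = tuple(
            slice(c, min(c + t, s)) for c, t, s in zip(corner, tile, sp)
        )
        core_src = tuple(
            slice(m, m + (sl.stop - sl.start)) for m, sl in zip(margin, core_dst)
        )
        for name, arr in pred.items():
            outs[name][(slice(None),) + core_dst] = arr[(slice(None),) + core_src]
    return {k: np.clip(v, 0.0, 1.0) for k, v in outs.items()}
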