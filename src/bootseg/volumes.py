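"""Typed containers for volumetric data and readers/writers for standard formats.

All volumes follow serial-section conventions: axis order ``(z, y, x)``,
0-based voxel indices, half-open bounding boxes, and physical coordinates
``offset + index * voxel_size`` in nanometres.  Anisotropy (z coarser than
y, x) is the norm for serial-section EM and is carried explicitly.

Sparse-annotation semantics: *unlabeled is not background*.  A sparse
:class:`LabelVolume` is always accompanied by an :class:`AnnotationMask`
marking the voxels whose label state is actually known (drawn instances
plus a thin collar of annotated background around them); everything outside
the mask is unknown and must be excluded from any loss.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "RawVolume",
    "LabelVolume",
    "AnnotationMask",
    "VolumeStore",
    "read_volume",
    "write_volume",
    "subsample_labels",
]


def _as_triple(v, name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in np.atleast_1d(v))
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 entries (z, y, x), got {v!r}")
    return t


@dataclass
class _Volume:
    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # single section -> depth-1 volume
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dims must be >= 1, got shape {self.data.shape}")
        self.voxel_size = _as_triple(self.voxel_size, "voxel_size")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        self.offset = _as_triple(self.offset, "offset")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray):
        return replace(self, data=data)


@dataclass
class RawVolume(_Volume):
    """Dense 3D intensity volume (e.g. an EM image stack)."""


@dataclass
class LabelVolume(_Volume):
    """Dense 3D volume of non-negative integer instance IDs; 0 = background."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.uint8)
            else:
                raise TypeError(f"label data must be integer, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("label IDs must be non-negative")

    def ids(self) -> np.ndarray:
        """Sorted nonzero instance IDs present in the volume."""
        u = np.unique(self.data)
        return u[u != 0]


@dataclass
class AnnotationMask(_Volume):
    """Boolean volume marking voxels whose label state is known."""

    def __post_init__(self):
        super().__post_init__()
        self.data = self.data.astype(bool)


@dataclass
class VolumeStore:
    """Handle describing where and how a volume is stored on disk."""

    path: str
    key: str | None
    dtype: np.dtype
    chunks: tuple | None = None
    meta: dict = field(default_factory=dict)


_LABEL_KINDS = (LabelVolume,)


def _default_meta(warn_for: str) -> tuple[tuple, tuple]:
    logger.warning(
        "%s: no voxel_size/offset metadata found; defaulting to (1,1,1)/(0,0,0)",
        warn_for,
    )
    return (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)


def _format_of(path: str) -> str:
    p = path.lower()
    if p.endswith((".zarr", ".n5")) or ".zarr" in p or ".n5" in p:
        return "zarr"
    if p.endswith((".h5", ".hdf5", ".hdf")):
        return "hdf5"
    if p.endswith((".tif", ".tiff")):
        return "tiff"
    raise ValueError(f"unrecognised volume format for path {path!r}")


def read_volume(path: str, key: str | None = None, *, as_labels: bool = False):
    """Read a 3D volume (or 2D section stack) from Zarr/N5, HDF5 or TIFF.

    Returns a :class:`LabelVolume` when ``as_labels`` is set (the stored dtype
    must then be integer), otherwise a :class:`RawVolume`.  Missing
    ``voxel_size``/``offset`` metadata defaults to unit spacing at the origin
    with a logged warning.
    """
    fmt = _format_of(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if fmt == "zarr":
        import zarr

        root = zarr.open_group(path, mode="r") if key else None
        arr = root[key] if key else zarr.open_array(path, mode="r")
        data = np.asarray(arr[:])
        attrs = dict(arr.attrs)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            if key is None or key not in f:
                raise KeyError(f"dataset {key!r} not found in {path}")
            ds = f[key]
            data = ds[:]
            attrs = dict(ds.attrs)
    else:  # tiff
        import tifffile

        data = tifffile.imread(path)
        attrs = {}

    if "voxel_size" in attrs:
        voxel_size = tuple(attrs["voxel_size"])
        offset = tuple(attrs.get("offset", (0.0, 0.0, 0.0)))
    else:
        voxel_size, offset = _default_meta(f"{path}:{key}")

    if as_labels:
        if not np.issubdtype(data.dtype, np.integer):
            raise TypeError(
                f"{path}:{key} has dtype {data.dtype}; labels must be integer"
            )
        return LabelVolume(data, voxel_size, offset)
    return RawVolume(data, voxel_size, offset)


def write_volume(volume, path: str, key: str | None = None, *, overwrite: bool = False) -> VolumeStore:
    """Write a volume so that :func:`read_volume` round-trips it bit-exactly.

    An existing dataset at ``path``/``key`` raises unless ``overwrite`` is set.
    Label volumes are stored with a dtype wide enough for their largest ID.
    """
    fmt = _format_of(path)
    data = volume.data
    if isinstance(volume, _LABEL_KINDS):
        data = data.astype(np.min_scalar_type(int(data.max()) if data.size else 0))
        if data.dtype == np.uint8 and isinstance(volume, LabelVolume):
            data = data.astype(np.uint32) if data.max() > 255 else data
    attrs = {"voxel_size": list(volume.voxel_size), "offset": list(volume.offset)}

    if fmt == "zarr":
        import zarr

        root = zarr.open_group(path, mode="a")
        if key in root:
            if not overwrite:
                raise FileExistsError(f"{path}:{key} exists (pass overwrite=True)")
            del root[key]
        arr = root.create_array(key, shape=data.shape, dtype=data.dtype)
        arr[:] = data
        arr.attrs.update(attrs)
        chunks = tuple(arr.chunks)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "a") as f:
            if key in f:
                if not overwrite:
                    raise FileExistsError(f"{path}:{key} exists (pass overwrite=True)")
                del f[key]
            ds = f.create_dataset(key, data=data)
            for k, v in attrs.items():
                ds.attrs[k] = v
            chunks = ds.chunks
    else:  # tiff
        import tifffile

        if os.path.exists(path) and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        tifffile.imwrite(path, data)
        chunks = None
        logger.warning("TIFF output stores no voxel_size/offset metadata")

    return VolumeStore(path=path, key=key, dtype=data.dtype, chunks=chunks, meta=attrs)


def subsample_labels(
    labels: LabelVolume,
    ids: set | None = None,
    *,
    count: int | None = None,
    seed: int | None = None,
    collar: int = 2,
) -> tuple[LabelVolume, AnnotationMask]:
    """Keep a subset of instances, emulating a sparse annotation.

    Either an explicit set of ``ids`` or a ``count`` (with ``seed``) of
    randomly chosen instances is retained.  The returned mask covers the kept
    instances plus a ``collar``-voxel dilated background rim around them,
    approximating the annotated background a human draws along instance
    boundaries; everything else is unknown.
    """
    present = labels.ids()
    if ids is not None:
        ids = set(int(i) for i in ids)
        unknown = ids - set(int(i) for i in present)
        if unknown:
            raise ValueError(f"IDs not present in volume: {sorted(unknown)}")
    else:
        if count is None:
            ids = set(int(i) for i in present)
        else:
            if count > len(present):
                raise ValueError(f"requested {count} IDs but only {len(present)} present")
            rng = np.random.default_rng(seed)
            ids = set(int(i) for i in rng.choice(present, size=count, replace=False))

    keep = np.isin(labels.data, sorted(ids)) if ids else np.zeros(labels.shape, bool)
    out = np.where(keep, labels.data, 0)

    if ids == set(int(i) for i in present) and len(ids) > 0:
        mask = np.ones(labels.shape, bool)  # fully annotated volume
    elif not ids:
        mask = np.zeros(labels.shape, bool)
    else:
        mask = keep.copy()
        if collar > 0:
            mask = ndimage.binary_dilation(mask, iterations=collar)

    return (
        LabelVolume(out, labels.voxel_size, labels.offset),
        AnnotationMask(mask, labels.voxel_size, labels.offset),
    )
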