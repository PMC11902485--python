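"""Volumetric image I/O and multi-modal channel assembly.

Arrays follow the (slice, row, col) axis convention throughout the package:
axis 0 walks across transversal slices (the "(2+1)D temporal" axis), axes 1
and 2 are the in-plane row/column directions.  On disk, NIfTI-1 and Analyze
7.5 store voxels in (col, row, slice) order, so readers/writers transpose.

Tissue label codes are 0 = background, 1 = CSF, 2 = GM, 3 = WM.  iSeg-style
files that encode tissues as 0/10/150/250 can be remapped on read via
:data:`ISEG_LABEL_CODES`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import FormatError, ShapeError

#: Default class names, index == label code.
CLASS_NAMES = ("background", "CSF", "GM", "WM")

#: Conventional iSeg label encoding -> package label codes.
ISEG_LABEL_CODES = {0: 0, 10: 1, 150: 2, 250: 3}


@dataclass
class IntensityVolume:
    """A single-modality 3-D intensity grid.

    Parameters
    ----------
    values : ndarray, shape (slices, rows, cols)
        Voxel intensities.
    spacing : tuple of float
        Voxel edge length in mm per axis, (slice, row, col) order.
    origin : tuple of float
        Position of voxel (0, 0, 0) in mm.
    validity_mask : ndarray of bool, optional
        True where the voxel holds a valid measurement; False marks a void.
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    validity_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ShapeError(f"expected a non-empty 3-D grid, got shape {self.values.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ShapeError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.validity_mask is not None:
            self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
            if self.validity_mask.shape != self.values.shape:
                raise ShapeError("validity_mask extents differ from values extents")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class LabelVolume:
    """Integer tissue map paired with an :class:`IntensityVolume` geometry."""

    labels: np.ndarray
    class_names: tuple = CLASS_NAMES
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ShapeError(f"expected a 3-D label grid, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise ShapeError("label grid holds non-integer values")
            self.labels = rounded.astype(np.int64)
        n = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= n):
            raise ShapeError(
                f"label values must lie in [0, {n - 1}], got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def n_classes(self):
        return len(self.class_names)


@dataclass
class MultiModalVolume:
    """Co-registered modalities stacked into a channels-last 4-D grid."""

    channels: np.ndarray
    channel_labels: list = field(default_factory=list)
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    validity_mask: np.ndarray | None = None

    def __post_init__(self):
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4:
            raise ShapeError(f"expected a 4-D (slice,row,col,channel) grid, got {self.channels.shape}")
        if len(self.channel_labels) != self.channels.shape[3]:
            raise ShapeError(
                f"{self.channels.shape[3]} channels but {len(self.channel_labels)} channel labels"
            )
        if self.validity_mask is not None:
            self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
            if self.validity_mask.shape != self.channels.shape[:3]:
                raise ShapeError("validity_mask extents differ from spatial extents")

    @property
    def spatial_shape(self):
        return self.channels.shape[:3]

    @property
    def n_channels(self):
        return self.channels.shape[3]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_ANALYZE_SUFFIXES = (".hdr", ".img")


def _load_image(path, format_hint=None):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # header/payload errors surface uniformly
        raise FormatError(f"cannot read {path!r} as NIfTI-1/Analyze: {exc}") from exc
    if data.ndim != 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path!r}: expected a 3-D volume, header declares {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # disk order (col, row, slice) -> package order (slice, row, col)
    values = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return values, spacing, origin


def read_volume(path, format_hint=None) -> IntensityVolume:
    """Read a NIfTI-1 (.nii/.nii.gz) or Analyze 7.5 (.hdr/.img) volume.

    The voxel order is normalized to (slice, row, col): a header declaring
    112 slices of 144x192 pixels yields extents (112, 192, 144).
    """
    values, spacing, origin = _load_image(path, format_hint)
    return IntensityVolume(values=values, spacing=spacing, origin=origin)


def read_label_volume(path, remap=None, class_names=CLASS_NAMES) -> LabelVolume:
    """Read a label map, optionally remapping on-disk codes.

    ``remap`` maps stored voxel values to class indices, e.g.
    :data:`ISEG_LABEL_CODES` for 0/10/150/250 encodings.
    """
    values, spacing, origin = _load_image(path)
    labels = np.rint(values).astype(np.int64)
    if remap is not None:
        out = np.full_like(labels, -1)
        for src, dst in remap.items():
            out[labels == src] = dst
        if (out < 0).any():
            bad = np.unique(labels[out < 0])
            raise FormatError(f"{path!r}: label codes {bad.tolist()} missing from remap table")
        labels = out
    return LabelVolume(labels=labels, class_names=class_names, spacing=spacing, origin=origin)


def write_volume(volume, path) -> None:
    """Write an :class:`IntensityVolume` or :class:`LabelVolume` to disk.

    Format follows the extension: ``.nii``/``.nii.gz`` for NIfTI-1,
    ``.hdr``/``.img`` for Analyze 7.5.  Labels are stored as unsigned 8-bit.
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent!r}")
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.uint8)
    elif isinstance(volume, IntensityVolume):
        data = volume.values
    else:
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    disk = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    sp = volume.spacing
    affine = np.diag([sp[2], sp[1], sp[0], 1.0])
    affine[:3, 3] = volume.origin[::-1]
    lower = str(path).lower()
    if lower.endswith(_NIFTI_SUFFIXES):
        img = nib.Nifti1Image(disk, affine)
    elif lower.endswith(_ANALYZE_SUFFIXES):
        img = nib.AnalyzeImage(disk, affine)
    else:
        raise FormatError(f"unsupported extension for {path!r} (use .nii, .nii.gz, .hdr or .img)")
    img.header.set_zooms((sp[2], sp[1], sp[0]))
    nib.save(img, path)


def stack_modalities(t1: IntensityVolume, t2: IntensityVolume, replication: int = 3) -> MultiModalVolume:
    """Stack two co-registered modalities into the network's channel layout.

    Each modality is replicated ``replication`` times (image-as-RGB
    convention), giving ``2 * replication`` channels in the order
    [T1 x replication, T2 x replication]; the default 3 reproduces the
    6-channel input of the reference architecture.
    """
    if replication < 1:
        raise ValueError("replication must be a positive integer")
    if t1.shape != t2.shape:
        raise ShapeError(f"modalities disagree on extents: {t1.shape} vs {t2.shape}")
    if not np.allclose(t1.spacing, t2.spacing):
        raise ShapeError(f"modalities disagree on spacing: {t1.spacing} vs {t2.spacing}")
    chans = [t1.values] * replication + [t2.values] * replication
    labels = ["T1"] * replication + ["T2"] * replication
    mask = None
    if t1.validity_mask is not None or t2.validity_mask is not None:
        mask = np.ones(t1.shape, dtype=bool)
        if t1.validity_mask is not None:
            mask &= t1.validity_mask
        if t2.validity_mask is not None:
            mask &= t2.validity_mask
    return MultiModalVolume(
        channels=np.stack(chans, axis=-1),
        channel_labels=labels,
        spacing=t1.spacing,
        origin=t1.origin,
        validity_mask=mask,
    )
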