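"""Percentile-landmark intensity standardization and void filling.

MRI intensity scales are arbitrary: the same tissue maps to different raw
values in different acquisitions.  The standardization here follows the
percentile-landmark scheme of Nyul-style histogram alignment: for each
record and modality, the 25th/50th/75th foreground percentiles (plus robust
outer anchors) are located, a cohort reference scale is formed by averaging
the landmarks over the training records, and each record is mapped onto the
reference by a monotone piecewise-linear transfer function that sends every
landmark exactly onto its reference counterpart.

Void voxels (dropouts flagged in the validity mask) are repaired before
landmark extraction by an iterative local-median fill.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, UsageError
from .volume_io import IntensityVolume

DEFAULT_PERCENTILES = (25.0, 50.0, 75.0)
DEFAULT_OUTER_PERCENTILES = (1.0, 99.0)

_FOREGROUND_RULES = {
    "positive": lambda v: v > 0,
    "nonzero": lambda v: v != 0,
    "all": lambda v: np.ones(v.shape, dtype=bool),
}


@dataclass
class LandmarkSet:
    """Per-record intensity landmarks for one modality.

    ``anchors`` holds the intensities at (low outer, *interior percentiles*,
    high outer); with defaults that is (p1, p25, p50, p75, p99) of the
    foreground distribution.
    """

    modality: str
    anchors: tuple
    percentile_spec: tuple = DEFAULT_PERCENTILES
    outer_percentiles: tuple = DEFAULT_OUTER_PERCENTILES

    def __post_init__(self):
        self.anchors = tuple(float(a) for a in self.anchors)
        self.percentile_spec = tuple(float(p) for p in self.percentile_spec)
        self.outer_percentiles = tuple(float(p) for p in self.outer_percentiles)
        if len(self.anchors) != len(self.percentile_spec) + 2:
            raise UsageError("anchor arity must equal len(percentile_spec) + 2 outer anchors")
        if any(b < a for a, b in zip(self.anchors, self.anchors[1:])):
            raise DegenerateInputError(f"anchors must be non-decreasing, got {self.anchors}")


@dataclass
class StandardScale:
    """Cohort reference anchors onto which every record is mapped."""

    modality: str
    reference_anchors: tuple
    percentile_spec: tuple = DEFAULT_PERCENTILES
    outer_percentiles: tuple = DEFAULT_OUTER_PERCENTILES

    def __post_init__(self):
        self.reference_anchors = tuple(float(a) for a in self.reference_anchors)
        if any(b <= a for a, b in zip(self.reference_anchors, self.reference_anchors[1:])):
            raise DegenerateInputError(
                f"reference anchors must be strictly increasing, got {self.reference_anchors}"
            )


def _foreground_values(volume: IntensityVolume, foreground_rule):
    if callable(foreground_rule):
        mask = np.asarray(foreground_rule(volume.values), dtype=bool)
    else:
        try:
            mask = _FOREGROUND_RULES[foreground_rule](volume.values)
        except KeyError:
            raise UsageError(
                f"unknown foreground rule {foreground_rule!r}; "
                f"known: {sorted(_FOREGROUND_RULES)} or a callable"
            ) from None
    if volume.validity_mask is not None:
        mask = mask & volume.validity_mask
    return volume.values[mask], mask


def compute_landmarks(
    volume: IntensityVolume,
    percentiles=DEFAULT_PERCENTILES,
    foreground_rule="positive",
    modality="",
    outer_percentiles=DEFAULT_OUTER_PERCENTILES,
) -> LandmarkSet:
    """Locate percentile landmarks of the foreground intensity distribution.

    Quantiles use linear interpolation between order statistics.  The outer
    anchors default to the 1st/99th percentiles, robust against stray
    extreme voxels.
    """
    fg, _ = _foreground_values(volume, foreground_rule)
    if fg.size == 0:
        raise DegenerateInputError("volume has no foreground voxels under the given rule")
    pts = (outer_percentiles[0],) + tuple(percentiles) + (outer_percentiles[1],)
    anchors = np.percentile(fg.astype(np.float64), pts, method="linear")
    return LandmarkSet(
        modality=modality,
        anchors=tuple(anchors),
        percentile_spec=tuple(percentiles),
        outer_percentiles=tuple(outer_percentiles),
    )


def build_standard_scale(landmark_sets) -> StandardScale:
    """Average landmarks across records into the cohort reference scale."""
    sets = list(landmark_sets)
    if not sets:
        raise UsageError("need at least one landmark set")
    first = sets[0]
    for ls in sets[1:]:
        if ls.modality != first.modality:
            raise UsageError(
                f"mixed modalities in one scale: {first.modality!r} vs {ls.modality!r}"
            )
        if ls.percentile_spec != first.percentile_spec or ls.outer_percentiles != first.outer_percentiles:
            raise UsageError("landmark sets use different percentile specifications")
    mean_anchors = np.mean([ls.anchors for ls in sets], axis=0)
    return StandardScale(
        modality=first.modality,
        reference_anchors=tuple(mean_anchors),
        percentile_spec=first.percentile_spec,
        outer_percentiles=first.outer_percentiles,
    )


def standardize_intensity(
    volume: IntensityVolume,
    landmarks: LandmarkSet,
    scale: StandardScale,
    foreground_rule="positive",
) -> IntensityVolume:
    """Map a record onto the cohort reference scale.

    Foreground voxels go through the monotone piecewise-linear map sending
    ``landmarks.anchors[k] -> scale.reference_anchors[k]`` (linear between
    consecutive anchors, clamped onto the outer reference anchors beyond the
    record's outer anchors); every landmark maps onto its reference value
    exactly.  Voxels outside the foreground rule (air, value 0 under the
    default rule) pass through unchanged so that the foreground set — and
    with it the landmark definition — is preserved by the mapping.
    """
    if len(landmarks.anchors) != len(scale.reference_anchors):
        raise UsageError(
            f"anchor arity mismatch: {len(landmarks.anchors)} landmarks vs "
            f"{len(scale.reference_anchors)} reference anchors"
        )
    _, fg_mask = _foreground_values(volume, foreground_rule)
    src = np.asarray(landmarks.anchors, dtype=np.float64)
    dst = np.asarray(scale.reference_anchors, dtype=np.float64)
    # collapse duplicate source anchors (degenerate records) for interpolation
    keep = np.concatenate(([True], np.diff(src) > 0))
    out = volume.values.astype(np.float64, copy=True)
    fg = out[fg_mask]
    mapped = np.interp(fg, src[keep], dst[keep])
    # enforce exact landmark correspondence (np.interp is exact at knots,
    # but tied source anchors must resolve to their own reference values)
    for a, r in zip(src, dst):
        mapped[fg == a] = r
    out[fg_mask] = mapped
    return IntensityVolume(
        values=out,
        spacing=volume.spacing,
        origin=volume.origin,
        validity_mask=None if volume.validity_mask is None else volume.validity_mask.copy(),
    )


def fill_missing(volume: IntensityVolume, max_iterations: int = 100) -> IntensityVolume:
    """Repair void voxels by iterated 3x3x3 valid-neighborhood medians.

    Each sweep replaces every void voxel that has at least one valid voxel
    in its 3x3x3 neighborhood with the median of those valid neighbors;
    freshly filled voxels count as valid from the next sweep on, so
    arbitrarily large void pockets close from the rim inward.  Valid voxels
    are never modified.
    """
    if volume.validity_mask is None:
        raise UsageError("fill_missing requires a validity mask")
    mask = volume.validity_mask.copy()
    if not mask.any():
        raise DegenerateInputError("volume has zero valid voxels; nothing to interpolate from")
    values = volume.values.astype(np.float64, copy=True)
    if mask.all():
        return IntensityVolume(values, volume.spacing, volume.origin, mask)

    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    for _ in range(max_iterations):
        if mask.all():
            break
        padded = np.pad(values, 1, constant_values=np.nan)
        padded[1:-1, 1:-1, 1:-1][~mask] = np.nan
        voids = np.argwhere(~mask)
        z, y, x = voids[:, 0] + 1, voids[:, 1] + 1, voids[:, 2] + 1
        neigh = np.stack([padded[z + dz, y + dy, x + dx] for dz, dy, dx in offsets], axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighborhoods
            med = np.nanmedian(neigh, axis=1)
        fillable = ~np.isnan(med)
        if not fillable.any():  # isolated void component with no valid rim
            break
        idx = voids[fillable]
        values[idx[:, 0], idx[:, 1], idx[:, 2]] = med[fillable]
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not mask.all():
        raise DegenerateInputError(
            f"{int((~mask).sum())} void voxels remain after {max_iterations} fill sweeps"
        )
    return IntensityVolume(values, volume.spacing, volume.origin, mask)


# ---------------------------------------------------------------------------
# JSON sidecar serialization
# ---------------------------------------------------------------------------

def landmarks_to_dict(obj):
    d = {
        "modality": obj.modality,
        "percentile_spec": list(obj.percentile_spec),
        "outer_percentiles": list(obj.outer_percentiles),
    }
    if isinstance(obj, LandmarkSet):
        d["kind"] = "landmarks"
        d["anchors"] = list(obj.anchors)
    else:
        d["kind"] = "standard_scale"
        d["reference_anchors"] = list(obj.reference_anchors)
    return d


def landmarks_from_dict(d):
    common = dict(
        modality=d["modality"],
        percentile_spec=tuple(d["percentile_spec"]),
        outer_percentiles=tuple(d["outer_percentiles"]),
    )
    if d["kind"] == "landmarks":
        return LandmarkSet(anchors=tuple(d["anchors"]), **common)
    return StandardScale(reference_anchors=tuple(d["reference_anchors"]), **common)


def save_landmarks(obj, path):
    with open(path, "w") as fh:
        json.dump(landmarks_to_dict(obj), fh, indent=2)


def load_landmarks(path):
    with open(path) as fh:
        return landmarks_from_dict(json.load(fh))
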