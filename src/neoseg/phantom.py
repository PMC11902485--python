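"""Synthetic infant-brain phantom cohorts.

A phantom is a pair of co-registered T1/T2-like volumes with ground-truth
tissue labels, built from nested smoothly-perturbed ellipsoids: a WM core,
a GM ribbon around it, a CSF shell, and air outside.  The geometry fixes
the GM:WM voxel ratio near 2:1 (as in real infant records), and the default
intensity model emulates the six-month isointense regime: GM and WM means
sit within half a pooled standard deviation of each other while CSF is far
separated, with inverted CSF contrast between T1 and T2.  Per-record global
scale/offset jitter emulates scanner-to-scanner intensity differences, and
a small fraction of in-brain voxels is knocked out as voids.

All values are synthetic emulation targets, not measured tissue parameters.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import DegenerateInputError, UsageError
from .volume_io import IntensityVolume, LabelVolume, MultiModalVolume, CLASS_NAMES, write_volume


def _default_geometry():
    # fractions of the brain radius; GM:WM continuum ratio =
    # (gm_radius^3 - wm_radius^3) / wm_radius^3 = 2 when gm = 3^(1/3) * wm
    return {
        "axis_fraction": 0.42,      # brain semi-axis / volume extent, per axis
        "wm_radius": 0.61,
        "gm_radius": 0.61 * 3.0 ** (1.0 / 3.0),
        "perturb_amplitude": 0.04,  # low-order harmonic boundary ripple
    }


def _default_intensities():
    # arbitrary scanner units; pooled noise std is `noise_std` for every tissue
    return {
        "noise_std": 0.06,
        "T1": {"CSF": 0.30, "center": 0.65, "wm_brighter": True},
        "T2": {"CSF": 0.90, "center": 0.45, "wm_brighter": False},
    }


@dataclass
class PhantomSpec:
    """Parameters of one synthetic record (or a cohort of them)."""

    extents: tuple = (32, 48, 32)
    tissue_geometry: dict = field(default_factory=_default_geometry)
    intensity_model: dict = field(default_factory=_default_intensities)
    gm_wm_separation: float = 0.5   # GM-WM mean gap in pooled-std units
    record_jitter: dict = field(default_factory=lambda: {"scale": (0.7, 1.3), "offset": (0.0, 0.15)})
    void_fraction: float = 0.02
    seed: int = 0
    require_divisible: bool = True  # extents must fit 4 pooling levels

    def __post_init__(self):
        self.extents = tuple(int(e) for e in self.extents)
        if len(self.extents) != 3 or min(self.extents) < 8:
            raise UsageError(f"extents must be 3 values >= 8, got {self.extents}")
        if self.require_divisible and any(e % 16 for e in self.extents):
            raise UsageError(
                f"extents {self.extents} not divisible by 16 (4 pooling levels); "
                "set require_divisible=False to allow padding at predict time"
            )
        if not (0.0 <= self.void_fraction <= 0.2):
            raise UsageError(f"void_fraction must lie in [0, 0.2], got {self.void_fraction}")
        if self.intensity_model["noise_std"] <= 0:
            raise UsageError("noise_std must be positive")
        if self.gm_wm_separation < 0:
            raise UsageError("gm_wm_separation must be non-negative")


@dataclass
class PhantomRecord:
    """One generated record: two modalities, labels, and its identifier."""

    record_id: str
    t1: IntensityVolume
    t2: IntensityVolume
    labels: LabelVolume

    def stacked(self, replication: int = 1) -> MultiModalVolume:
        from .volume_io import stack_modalities
        return stack_modalities(self.t1, self.t2, replication=replication)


def _tissue_means(model, separation):
    std = model["noise_std"]
    gap = separation * std
    means = {}
    for mod in ("T1", "T2"):
        m = model[mod]
        sign = 1.0 if m["wm_brighter"] else -1.0
        means[mod] = {
            "CSF": m["CSF"],
            "GM": m["center"] - sign * gap / 2.0,
            "WM": m["center"] + sign * gap / 2.0,
        }
    return means


def _label_geometry(spec: PhantomSpec, rng) -> np.ndarray:
    geo = spec.tissue_geometry
    ext = spec.extents
    center = [(e - 1) / 2.0 for e in ext]
    axes = [geo["axis_fraction"] * e for e in ext]
    zz, yy, xx = np.meshgrid(*[np.arange(e, dtype=np.float64) for e in ext], indexing="ij")
    dz = (zz - center[0]) / axes[0]
    dy = (yy - center[1]) / axes[1]
    dx = (xx - center[2]) / axes[2]
    r = np.sqrt(dz * dz + dy * dy + dx * dx)
    # low-order angular ripple; multiplicative in r, so region-volume ratios
    # (and with them the GM:WM count ratio) are preserved
    norm = np.maximum(r, 1e-12)
    theta = np.arccos(np.clip(dz / norm, -1.0, 1.0))
    phi = np.arctan2(dy, dx)
    p1, p2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    ripple = np.sin(2.0 * theta + p1) + np.sin(3.0 * phi + p2) * np.sin(theta)
    r_eff = r * (1.0 + geo["perturb_amplitude"] * 0.5 * ripple)

    labels = np.zeros(ext, dtype=np.int64)
    labels[r_eff < 1.0] = 1                      # CSF shell
    labels[r_eff < geo["gm_radius"]] = 2         # GM ribbon
    labels[r_eff < geo["wm_radius"]] = 3         # WM core
    for code, name in enumerate(CLASS_NAMES):
        if not (labels == code).any():
            raise DegenerateInputError(f"phantom geometry produced an empty {name} class")
    return labels


def generate_phantom(spec: PhantomSpec):
    """Generate one record; fully determined by ``spec.seed``.

    Returns a (MultiModalVolume, LabelVolume) pair with channels [T1, T2]
    and void voxels flagged False in the validity mask.
    """
    rec = _generate_record(spec, spec.seed, record_id="phantom")
    return rec.stacked(replication=1), rec.labels


def _generate_record(spec: PhantomSpec, seed: int, record_id: str) -> PhantomRecord:
    rng = np.random.default_rng(seed)
    labels = _label_geometry(spec, rng)
    means = _tissue_means(spec.intensity_model, spec.gm_wm_separation)
    std = spec.intensity_model["noise_std"]
    brain = labels > 0

    jit = spec.record_jitter
    volumes = {}
    for mod in ("T1", "T2"):
        vals = np.zeros(spec.extents, dtype=np.float64)
        for code, tissue in ((1, "CSF"), (2, "GM"), (3, "WM")):
            m = labels == code
            vals[m] = means[mod][tissue] + std * rng.standard_normal(int(m.sum()))
        scale = rng.uniform(*jit["scale"])
        offset = rng.uniform(*jit["offset"])
        vals[brain] = scale * vals[brain] + offset
        # keep foreground strictly positive so air (exactly 0) stays separable
        vals[brain] = np.maximum(vals[brain], 0.02)
        volumes[mod] = vals

    mask = np.ones(spec.extents, dtype=bool)
    if spec.void_fraction > 0:
        idx = np.argwhere(brain)
        n_void = int(round(spec.void_fraction * len(idx)))
        if n_void:
            chosen = idx[rng.choice(len(idx), size=n_void, replace=False)]
            mask[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = False
            for vals in volumes.values():
                vals[~mask] = 0.0

    t1 = IntensityVolume(volumes["T1"], validity_mask=mask.copy())
    t2 = IntensityVolume(volumes["T2"], validity_mask=mask.copy())
    return PhantomRecord(record_id=record_id, t1=t1, t2=t2,
                         labels=LabelVolume(labels))


def generate_cohort(n: int, spec: PhantomSpec, out_dir=None):
    """Generate ``n`` records from seeds seed+0 .. seed+n-1.

    Each record draws its own geometry ripple phases, noise and global
    intensity jitter.  With ``out_dir`` set, volumes are written as NIfTI
    and a JSON manifest listing per-record paths is produced.
    """
    if n < 1:
        raise UsageError("cohort size must be >= 1")
    records = [
        _generate_record(spec, spec.seed + i, record_id=f"rec{i:02d}") for i in range(n)
    ]
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest = {"spec": _spec_to_jsonable(spec), "records": []}
        for rec in records:
            entry = {"id": rec.record_id}
            for mod, vol in (("t1", rec.t1), ("t2", rec.t2)):
                path = os.path.join(out_dir, f"{rec.record_id}_{mod}.nii.gz")
                write_volume(vol, path)
                entry[mod] = os.path.basename(path)
            lpath = os.path.join(out_dir, f"{rec.record_id}_labels.nii.gz")
            write_volume(rec.labels, lpath)
            entry["labels"] = os.path.basename(lpath)
            mpath = os.path.join(out_dir, f"{rec.record_id}_mask.nii.gz")
            write_volume(LabelVolume(rec.t1.validity_mask.astype(np.int64),
                                     class_names=("void", "valid")), mpath)
            entry["mask"] = os.path.basename(mpath)
            manifest["records"].append(entry)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return records


def _spec_to_jsonable(spec: PhantomSpec):
    d = asdict(spec)
    d["extents"] = list(spec.extents)
    d["record_jitter"] = {k: list(v) for k, v in spec.record_jitter.items()}
    return d
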