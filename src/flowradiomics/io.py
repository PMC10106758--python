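"""File formats and run configuration.

Velocity fields are stored as one 4D NIfTI per velocity component (x, y, z)
plus a JSON sidecar carrying spacing, frame duration and VENC; masks as 2D
NIfTI aligned to the plane grid; centerlines as JSON; all tabular outputs
(feature tables, ICC tables, signatures) as CSV; configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import VelocityField
from .geometry import Centerline

__all__ = [
    "RunConfig",
    "write_velocity_field",
    "read_velocity_field",
    "write_mask",
    "read_mask",
    "write_centerline",
    "read_centerline",
]

_COMPONENTS = ("x", "y", "z")


@dataclass
class RunConfig:
    """All pipeline settings with their standard defaults.

    Defaults match the pipeline constants: 1 mm MPR resolution, fixed
    normalization ranges, bin width 25, moderate-or-better selection from
    a two-way random absolute-agreement single-rating ICC, and stratified
    5-fold cross-validation for the classifier.
    """

    n_ascending: int = 5
    n_descending: int = 3
    mpr_resolution_mm: float = 1.0
    plane_extent_mm: float = 48.0
    bin_width: float = 25.0
    icc_model: str = "two_way_random_absolute_single"
    min_category: str = "moderate"
    classifier_protocol: str = "cv5"
    classifier_C: float = 1.0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in artifacts."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_velocity_field(field: VelocityField, prefix: str | Path) -> list[Path]:
    """Write one 4D NIfTI per component plus a JSON sidecar.

    Files are ``<prefix>_vx.nii``, ``_vy.nii``, ``_vz.nii`` and
    ``<prefix>.json``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*field.spacing, 1.0])
    affine[:3, 3] = field.origin
    paths = []
    for c, name in enumerate(_COMPONENTS):
        # NIfTI stores (x, y, z, t)
        data = np.moveaxis(field.velocity[..., c], 0, -1)
        img = nib.Nifti1Image(data, affine)
        img.header.set_xyzt_units("mm", "msec")
        p = prefix.parent / f"{prefix.name}_v{name}.nii"
        nib.save(img, p)
        paths.append(p)
    sidecar = {
        "spacing_mm": field.spacing.tolist(),
        "origin_mm": field.origin.tolist(),
        "frame_duration_ms": field.frame_duration_ms,
        "venc_cm_s": field.venc,
        "n_timeframes": field.n_timeframes,
        "meta": {k: v for k, v in field.meta.items()
                 if isinstance(v, (str, int, float, bool))},
    }
    jpath = prefix.parent / f"{prefix.name}.json"
    jpath.write_text(json.dumps(sidecar, indent=1))
    paths.append(jpath)
    return paths


def read_velocity_field(prefix: str | Path) -> VelocityField:
    """Read a component-wise NIfTI velocity field written by this package."""
    prefix = Path(prefix)
    jpath = prefix.parent / f"{prefix.name}.json"
    if not jpath.exists():
        raise FileNotFoundError(f"missing sidecar {jpath}")
    sidecar = json.loads(jpath.read_text())
    comps = []
    shape = None
    for name in _COMPONENTS:
        p = prefix.parent / f"{prefix.name}_v{name}.nii"
        if not p.exists():
            raise FileNotFoundError(f"missing component file {p}")
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(f"component file {p} has shape {data.shape}, "
                             f"expected {shape}")
        comps.append(np.moveaxis(data, -1, 0))  # back to (t, x, y, z)
    velocity = np.stack(comps, axis=-1)
    if velocity.shape[0] != sidecar["n_timeframes"]:
        raise ValueError(f"sidecar {jpath} declares "
                         f"{sidecar['n_timeframes']} timeframes but files "
                         f"contain {velocity.shape[0]}")
    venc = sidecar.get("venc_cm_s")
    if venc is None:
        import warnings

        warnings.warn("sidecar has no VENC; noise-level checks disabled")
    return VelocityField(
        velocity=velocity,
        spacing=np.asarray(sidecar["spacing_mm"]),
        origin=np.asarray(sidecar["origin_mm"]),
        frame_duration_ms=sidecar["frame_duration_ms"],
        venc=venc,
        meta=sidecar.get("meta", {}),
    )


def write_mask(mask: np.ndarray, path: str | Path,
               pixel_size_mm: float = 1.0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def write_centerline(cl: Centerline, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "points_mm": cl.points.tolist(),
        "landmarks_arclength_mm": cl.landmarks,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_centerline(path: str | Path) -> Centerline:
    payload = json.loads(Path(path).read_text())
    return Centerline.from_points(
        np.asarray(payload["points_mm"]), payload["landmarks_arclength_mm"]
    )
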