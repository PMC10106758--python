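"""Cross-section placement along the aortic centerline and MPR resampling.

Twelve standardized analysis planes are placed on the centerline: the four
landmark planes (A1.1 proximal ascending, B1 pre-brachiocephalic, B4.1
post-subclavian, D1.1 mid-descending) plus equidistant intermediate planes
within the ascending and descending segments. Each plane's normal is the
local centerline tangent oriented toward increasing arc length, and the
velocity field is resampled onto a 1 mm cell-centred in-plane grid by
trilinear interpolation. Out-of-volume pixels are flagged invalid, never
extrapolated.

ROI propagation across timeframes replaces deformable motion tracking with
rigid centroid tracking: per timeframe the mask is translated by the shift
of the through-plane-speed centroid inside a search window, which preserves
the ROI area exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import VelocityField

__all__ = [
    "Centerline",
    "PlaneDefinition",
    "PlaneSample",
    "place_planes",
    "plane_grid_points",
    "resample_mpr",
    "resample_volume_on_plane",
    "propagate_roi",
]

#: Landmark labels in their anatomical order along the aorta.
LANDMARK_ORDER = ("A1.1", "B1", "B4.1", "D1.1")

#: Default MPR in-plane resolution (mm) and plane extent (mm).
MPR_RESOLUTION_MM = 1.0
DEFAULT_PLANE_EXTENT_MM = 48.0

#: Fixed global reference vector used to construct reproducible in-plane axes.
_REFERENCE_VECTORS = (
    np.array([1.0, 0.0, 0.0]),
    np.array([0.0, 1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
)


@dataclass
class Centerline:
    """Ordered polyline centerline with landmark arc-length positions."""

    points: np.ndarray        # (N, 3) mm
    arc_length: np.ndarray    # (N,) mm, strictly increasing, starts at 0
    tangents: np.ndarray      # (N, 3) unit vectors
    landmarks: dict[str, float]   # label -> arc length (mm)

    @classmethod
    def from_points(cls, points: np.ndarray,
                    landmarks: dict[str, float]) -> "Centerline":
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
            raise ValueError("centerline needs at least two 3D points")
        seg = np.diff(points, axis=0)
        ds = np.linalg.norm(seg, axis=1)
        if np.any(ds <= 0):
            raise ValueError("centerline arc length must be strictly increasing")
        s = np.concatenate([[0.0], np.cumsum(ds)])
        tangents = np.empty_like(points)
        tangents[1:-1] = points[2:] - points[:-2]
        tangents[0] = points[1] - points[0]
        tangents[-1] = points[-1] - points[-2]
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        cl = cls(points=points, arc_length=s, tangents=tangents,
                 landmarks=dict(landmarks))
        cl._validate_landmarks()
        return cl

    def _validate_landmarks(self) -> None:
        missing = [k for k in LANDMARK_ORDER if k not in self.landmarks]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")
        vals = [self.landmarks[k] for k in LANDMARK_ORDER]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError(
                "landmarks must be ordered A1.1 < B1 < B4.1 < D1.1 by arc length"
            )

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float) -> np.ndarray:
        return np.array([
            np.interp(s, self.arc_length, self.points[:, i]) for i in range(3)
        ])

    def tangent_at(self, s: float) -> np.ndarray:
        t = np.array([
            np.interp(s, self.arc_length, self.tangents[:, i]) for i in range(3)
        ])
        return t / np.linalg.norm(t)


@dataclass
class PlaneDefinition:
    """Oriented cross-section on the centerline.

    The normal equals the local centerline tangent (increasing arc length);
    the two in-plane axes are orthonormal and reproducible: the first is
    the normalized projection of a fixed global reference vector onto the
    plane, the second is ``normal x first``.
    """

    label: str
    origin: np.ndarray
    normal: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    extent: float = DEFAULT_PLANE_EXTENT_MM

    @classmethod
    def from_origin_normal(cls, label: str, origin: np.ndarray,
                           normal: np.ndarray,
                           extent: float = DEFAULT_PLANE_EXTENT_MM):
        normal = np.asarray(normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
        for ref in _REFERENCE_VECTORS:
            proj = ref - np.dot(ref, normal) * normal
            nrm = np.linalg.norm(proj)
            if nrm > 1e-8:
                axis_u = proj / nrm
                break
        axis_v = np.cross(normal, axis_u)
        return cls(label=label, origin=np.asarray(origin, dtype=float),
                   normal=normal, axis_u=axis_u, axis_v=axis_v, extent=extent)


@dataclass
class PlaneSample:
    """Velocity vectors resampled onto a plane's regular 2D grid."""

    velocity: np.ndarray      # (nu, nv, 3) m/s
    valid: np.ndarray         # (nu, nv) bool; False where outside the volume
    mask: np.ndarray | None   # ROI, subset of valid pixels (or None)
    plane: PlaneDefinition
    timeframe: int
    resolution: float = MPR_RESOLUTION_MM


def place_planes(centerline: Centerline, n_ascending: int = 5,
                 n_descending: int = 3,
                 extent: float = DEFAULT_PLANE_EXTENT_MM) -> list[PlaneDefinition]:
    """Place the landmark planes plus equidistant intermediate planes.

    ``n_ascending`` planes are interposed between A1.1 and B1 and
    ``n_descending`` between B4.1 and D1.1, each splitting its segment into
    equal arc-length intervals. The defaults yield 12 planes in total.
    """
    lm = centerline.landmarks
    positions: list[tuple[str, float]] = [("A1.1", lm["A1.1"])]
    sa, sb = lm["A1.1"], lm["B1"]
    for i in range(1, n_ascending + 1):
        positions.append((f"asc{i}", sa + i * (sb - sa) / (n_ascending + 1)))
    positions.append(("B1", lm["B1"]))
    positions.append(("B4.1", lm["B4.1"]))
    sc, sd = lm["B4.1"], lm["D1.1"]
    for i in range(1, n_descending + 1):
        positions.append((f"desc{i}", sc + i * (sd - sc) / (n_descending + 1)))
    positions.append(("D1.1", lm["D1.1"]))
    positions.sort(key=lambda p: p[1])
    return [
        PlaneDefinition.from_origin_normal(
            label, centerline.point_at(s), centerline.tangent_at(s), extent
        )
        for label, s in positions
    ]


def plane_grid_points(plane: PlaneDefinition, extent: float | None = None,
                      resolution: float = MPR_RESOLUTION_MM):
    """Physical positions of the plane's cell-centred pixel grid.

    Returns ``(points, shape)`` with points of shape ``(n*n, 3)``.
    """
    e = plane.extent if extent is None else extent
    n = int(round(e / resolution))
    coords = (np.arange(n) - (n - 1) / 2.0) * resolution
    U, V = np.meshgrid(coords, coords, indexing="ij")
    pts = (
        plane.origin[None, :]
        + U.reshape(-1, 1) * plane.axis_u[None, :]
        + V.reshape(-1, 1) * plane.axis_v[None, :]
    )
    return pts, (n, n)


def _interp_volume(volume: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at fractional indices; NaN outside the grid."""
    return ndimage.map_coordinates(
        volume, idx.T, order=1, mode="constant", cval=np.nan
    )


def resample_volume_on_plane(volume: np.ndarray, spacing: np.ndarray,
                             origin: np.ndarray, plane: PlaneDefinition,
                             resolution: float = MPR_RESOLUTION_MM):
    """Trilinearly resample a 3D scalar volume onto a plane grid.

    Returns ``(values, valid)`` 2D arrays; invalid pixels (outside the
    source grid) hold 0 and are flagged False.
    """
    pts, shape = plane_grid_points(plane, resolution=resolution)
    idx = (pts - np.asarray(origin)) / np.asarray(spacing)
    vals = _interp_volume(np.asarray(volume, dtype=float), idx).reshape(shape)
    valid = np.isfinite(vals)
    return np.where(valid, vals, 0.0), valid


def resample_mpr(field: VelocityField, plane: PlaneDefinition, t: int,
                 resolution: float = MPR_RESOLUTION_MM) -> PlaneSample:
    """Resample the three velocity components onto the plane at timeframe t."""
    pts, shape = plane_grid_points(plane, resolution=resolution)
    idx = field.world_to_index(pts)
    comps = []
    for c in range(3):
        comps.append(_interp_volume(field.velocity[t, ..., c], idx).reshape(shape))
    vel = np.stack(comps, axis=-1)
    valid = np.all(np.isfinite(vel), axis=-1)
    if not valid.any():
        raise ValueError(f"plane {plane.label!r} lies fully outside the volume")
    vel = np.where(valid[..., None], vel, 0.0)
    return PlaneSample(velocity=vel, valid=valid, mask=None, plane=plane,
                       timeframe=t, resolution=resolution)


def propagate_roi(mask: np.ndarray, samples: list[PlaneSample],
                  search_margin_mm: float = 6.0) -> list[np.ndarray]:
    """Rigidly propagate a reference-frame ROI to all timeframes.

    Per timeframe the through-plane speed centroid is computed inside a
    search window (the reference mask dilated by ``search_margin_mm``) and
    the mask is translated by the integer-pixel shift of that centroid
    relative to the reference frame. The translation preserves the ROI area
    exactly; zero-flow frames fall back to the untranslated mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("reference ROI mask is empty")
    res = samples[0].resolution
    it = max(1, int(round(search_margin_mm / res)))
    window = ndimage.binary_dilation(mask, iterations=it)

    def speed_centroid(sample: PlaneSample):
        u = np.abs(sample.velocity @ sample.plane.normal)
        w = np.where(window & sample.valid, u, 0.0)
        tot = w.sum()
        if tot <= 0:
            return None
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        return np.array([(w * yy).sum() / tot, (w * xx).sum() / tot])

    ref_c = speed_centroid(samples[0])
    out = []
    for sample in samples:
        c = speed_centroid(sample)
        if ref_c is None or c is None:
            warnings.warn(
                f"no through-plane flow at timeframe {sample.timeframe}; "
                "ROI left untranslated"
            )
            out.append(mask.copy())
            continue
        shift = np.round(c - ref_c).astype(int)
        shifted = np.zeros_like(mask)
        src = mask
        # integer translation without wrap-around
        y0, x0 = shift
        ys = slice(max(0, y0), mask.shape[0] + min(0, y0))
        xs = slice(max(0, x0), mask.shape[1] + min(0, x0))
        ys_src = slice(max(0, -y0), mask.shape[0] - max(0, y0))
        xs_src = slice(max(0, -x0), mask.shape[1] - max(0, x0))
        shifted[ys, xs] = src[ys_src, xs_src]
        if shifted.sum() != mask.sum():
            warnings.warn(
                "ROI translation clipped at the plane border; keeping the "
                "untranslated mask to preserve area"
            )
            shifted = mask.copy()
        out.append(shifted)
    return out
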