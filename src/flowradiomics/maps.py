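"""Cross-sectional flow parameter maps and their fixed-range normalization.

Five scalar maps are derived per plane and timeframe from the resampled
velocity vectors v_i and the plane normal n:

* throughflow        u_i   = v_i . n                       (m/s, signed)
* wall parallelity   WPD_i = u_i / |v_i|                    (dimensionless)
* angle              alpha_i = arccos(v_i/|v_i| . n)        (degrees, 0-180)
* vorticity          w_i   = curl(v) . n / w_ref            (self-normalized)
* normalized helicity LNH_i = (w_i . v_i) / (|w_i| |v_i|)   (dimensionless)

Vorticity is computed on the 3D source grid by spacing-aware central
differences and then resampled onto the plane, because in-plane differences
cannot recover all curl components. For radiomics extraction every map is
affinely rescaled to a fixed integer-valued range: unsigned maps to
[0, 4096], signed maps to [-2048, 2047], with out-of-range values clipped.
Values remain floating point until gray-level discretization.

Degenerate pixels (speed or vorticity magnitude below a small floor) are
given neutral values (WPD 0, angle 90 deg, LNH 0) and flagged, so no map
ever contains NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import VelocityField
from .geometry import PlaneSample, resample_volume_on_plane

__all__ = [
    "MAP_KINDS",
    "ParameterMap",
    "NormalizationSpec",
    "DEFAULT_NORMALIZATION",
    "SPEED_FLOOR",
    "throughflow_map",
    "wpd_map",
    "angle_map",
    "vorticity_field",
    "lnh_map",
    "normal_vorticity_map",
    "compute_parameter_maps",
    "normalize_map",
    "denormalize_map",
]

MAP_KINDS = ("throughflow", "wpd", "angle", "lnh", "vorticity")

#: Speeds (m/s) and vorticity magnitudes (1/s) below this are treated as zero.
SPEED_FLOOR = 1e-6


@dataclass
class ParameterMap:
    kind: str
    values: np.ndarray            # 2D
    units: str
    mask: np.ndarray | None
    low_signal: np.ndarray        # 2D bool, degenerate pixels
    normalized: bool = False
    plane_label: str = ""
    timeframe: int = 0


@dataclass
class NormalizationSpec:
    """Affine mapping from a native input range to a fixed output range."""

    kind: str
    input_range: tuple[float, float]
    output_range: tuple[float, float]
    clip: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.input_range
        if not lo < hi:
            raise ValueError("input_range must satisfy lo < hi")


#: Fixed normalization ranges: unsigned maps to [0, 4096], signed maps to
#: [-2048, 2047]. Throughflow spans +/-6 m/s, the angle 0-180 degrees, WPD
#: [0, 1], and helicity/vorticity [-1, 1].
DEFAULT_NORMALIZATION = {
    "throughflow": NormalizationSpec("throughflow", (-6.0, 6.0), (-2048.0, 2047.0)),
    "angle": NormalizationSpec("angle", (0.0, 180.0), (0.0, 4096.0)),
    "wpd": NormalizationSpec("wpd", (0.0, 1.0), (0.0, 4096.0)),
    "lnh": NormalizationSpec("lnh", (-1.0, 1.0), (-2048.0, 2047.0)),
    "vorticity": NormalizationSpec("vorticity", (-1.0, 1.0), (-2048.0, 2047.0)),
}


def _speeds(sample: PlaneSample):
    v = sample.velocity
    speed = np.linalg.norm(v, axis=-1)
    low = speed < SPEED_FLOOR
    return v, speed, low


def throughflow_map(sample: PlaneSample) -> ParameterMap:
    """Signed through-plane velocity u_i = v_i . n in m/s."""
    u = sample.velocity @ sample.plane.normal
    return ParameterMap("throughflow", u, "m/s", sample.mask,
                        np.zeros_like(u, dtype=bool), False,
                        sample.plane.label, sample.timeframe)


def wpd_map(sample: PlaneSample) -> ParameterMap:
    """Wall parallelity degree WPD_i = u_i / |v_i| in [-1, 1]."""
    v, speed, low = _speeds(sample)
    u = v @ sample.plane.normal
    with np.errstate(invalid="ignore", divide="ignore"):
        wpd = np.where(low, 0.0, u / np.where(low, 1.0, speed))
    return ParameterMap("wpd", wpd, "dimensionless", sample.mask, low, False,
                        sample.plane.label, sample.timeframe)


def angle_map(sample: PlaneSample) -> ParameterMap:
    """Angular deviation of the velocity from the plane normal, degrees."""
    v, speed, low = _speeds(sample)
    u = v @ sample.plane.normal
    cosang = np.clip(u / np.where(low, 1.0, speed), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang = np.where(low, 90.0, ang)
    return ParameterMap("angle", ang, "degrees", sample.mask, low, False,
                        sample.plane.label, sample.timeframe)


def vorticity_field(field: VelocityField, t: int) -> np.ndarray:
    """Curl of the velocity field at timeframe t, shape (nx, ny, nz, 3), 1/s.

    Central differences in the interior, one-sided at the borders; spacings
    are converted from mm to m so the result carries 1/s units.
    """
    if min(field.grid_shape) < 3:
        raise ValueError("vorticity needs at least 3 voxels per axis")
    v = field.velocity[t]
    dx, dy, dz = field.spacing / 1000.0  # m
    d = [np.gradient(v[..., c], dx, dy, dz, edge_order=1) for c in range(3)]
    # d[c][a] = d v_c / d a
    wx = d[2][1] - d[1][2]
    wy = d[0][2] - d[2][0]
    wz = d[1][0] - d[0][1]
    return np.stack([wx, wy, wz], axis=-1)


def _vorticity_on_plane(field: VelocityField, sample: PlaneSample,
                        vort: np.ndarray | None = None) -> np.ndarray:
    if vort is None:
        vort = vorticity_field(field, sample.timeframe)
    comps = [
        resample_volume_on_plane(vort[..., c], field.spacing, field.origin,
                                 sample.plane, sample.resolution)[0]
        for c in range(3)
    ]
    return np.stack(comps, axis=-1)


def lnh_map(sample: PlaneSample, vort_on_plane: np.ndarray,
            absolute: bool = False) -> ParameterMap:
    """Local normalized helicity: cosine between vorticity and velocity.

    Signed by default (the sign encodes helix handedness); ``absolute=True``
    gives the unsigned variant.
    """
    v, speed, low_v = _speeds(sample)
    wmag = np.linalg.norm(vort_on_plane, axis=-1)
    low = low_v | (wmag < SPEED_FLOOR)
    dot = np.einsum("...i,...i->...", vort_on_plane, v)
    denom = np.where(low, 1.0, wmag * speed)
    lnh = np.where(low, 0.0, np.clip(dot / denom, -1.0, 1.0))
    if absolute:
        lnh = np.abs(lnh)
    return ParameterMap("lnh", lnh, "dimensionless", sample.mask, low, False,
                        sample.plane.label, sample.timeframe)


def normal_vorticity_map(sample: PlaneSample, vort_on_plane: np.ndarray,
                         reference: float | None = None) -> ParameterMap:
    """Through-plane vorticity scaled into [-1, 1].

    The signed normal component ``w_i . n`` is divided by ``w_ref``: by
    default the per-plane, per-timeframe maximum of |w . n| over the ROI
    (self-normalization), or a fixed reference in 1/s when given.
    """
    wn = vort_on_plane @ sample.plane.normal
    roi = sample.mask if sample.mask is not None else sample.valid
    if reference is None:
        ref = float(np.abs(wn[roi]).max()) if roi.any() else 0.0
    else:
        ref = float(reference)
    if ref < SPEED_FLOOR:
        vals = np.zeros_like(wn)
        low = np.ones_like(wn, dtype=bool)
    else:
        vals = wn / ref
        if reference is not None:
            vals = np.clip(vals, -1.0, 1.0)
        low = np.zeros_like(wn, dtype=bool)
    return ParameterMap("vorticity", vals, "dimensionless", sample.mask, low,
                        False, sample.plane.label, sample.timeframe)


def compute_parameter_maps(field: VelocityField, sample: PlaneSample,
                           vort: np.ndarray | None = None,
                           normalize: bool = False) -> dict[str, ParameterMap]:
    """All five parameter maps for one plane sample; optionally normalized."""
    vort_plane = _vorticity_on_plane(field, sample, vort)
    maps = {
        "throughflow": throughflow_map(sample),
        "wpd": wpd_map(sample),
        "angle": angle_map(sample),
        "lnh": lnh_map(sample, vort_plane),
        "vorticity": normal_vorticity_map(sample, vort_plane),
    }
    if normalize:
        maps = {k: normalize_map(m) for k, m in maps.items()}
    return maps


def normalize_map(pmap: ParameterMap,
                  spec: NormalizationSpec | None = None) -> ParameterMap:
    """Affinely rescale a map to its fixed output range, clipping outliers.

    Values stay floating point; integer rounding happens only at the
    gray-level discretization step so bin boundaries are controlled in one
    place.
    """
    if pmap.normalized:
        raise ValueError("map is already normalized")
    if spec is None:
        spec = DEFAULT_NORMALIZATION[pmap.kind]
    if spec.kind != pmap.kind:
        raise ValueError(f"normalization spec {spec.kind!r} does not match "
                         f"map kind {pmap.kind!r}")
    lo, hi = spec.input_range
    olo, ohi = spec.output_range
    vals = (pmap.values - lo) * (ohi - olo) / (hi - lo) + olo
    if spec.clip:
        vals = np.clip(vals, olo, ohi)
    return replace(pmap, values=vals, units="normalized", normalized=True)


def denormalize_map(pmap: ParameterMap,
                    spec: NormalizationSpec | None = None) -> ParameterMap:
    """Inverse of :func:`normalize_map` for in-range values."""
    if not pmap.normalized:
        raise ValueError("map is not normalized")
    if spec is None:
        spec = DEFAULT_NORMALIZATION[pmap.kind]
    lo, hi = spec.input_range
    olo, ohi = spec.output_range
    vals = (pmap.values - olo) * (hi - lo) / (ohi - olo) + lo
    return replace(pmap, values=vals, normalized=False)
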