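"""Flow parameter maps: analytic correctness and normalization fidelity."""

import numpy as np
import pytest

from flowradiomics import (
    DEFAULT_NORMALIZATION,
    PhantomSpec,
    ScannerProfile,
    VelocityField,
    angle_map,
    denormalize_map,
    generate_velocity_field,
    lnh_map,
    lumen_mask_on_plane,
    make_centerline,
    normal_vorticity_map,
    normalize_map,
    place_planes,
    resample_mpr,
    throughflow_map,
    vorticity_field,
    wpd_map,
)
from flowradiomics.geometry import PlaneDefinition, PlaneSample
from flowradiomics.maps import NormalizationSpec, ParameterMap


def plane_sample(velocities, normal=(0, 0, 1)):
    v = np.asarray(velocities, dtype=float)
    plane = PlaneDefinition.from_origin_normal("p", [0, 0, 0], normal,
                                               extent=v.shape[0])
    valid = np.ones(v.shape[:2], dtype=bool)
    return PlaneSample(velocity=v, valid=valid, mask=valid, plane=plane,
                       timeframe=0)


class TestPointwiseMaps:
    def test_throughflow_is_dot_product(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 6, 3))
        n = np.array([0.36, 0.48, 0.8])
        s = plane_sample(v, n)
        u = throughflow_map(s)
        expected = np.einsum("ijk,k->ij", v, s.plane.normal)
        assert np.allclose(u.values, expected, atol=1e-12)
        assert u.units == "m/s"

    def test_wpd_known_angles(self):
        v = np.zeros((1, 3, 3))
        v[0, 0] = [0, 0, 2.0]                       # parallel
        v[0, 1] = [np.sin(np.pi / 3), 0, np.cos(np.pi / 3)]   # 60 degrees
        v[0, 2] = [0, 0, 0]                         # degenerate
        s = plane_sample(v)
        w = wpd_map(s)
        assert w.values[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert w.values[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert w.values[0, 2] == 0.0
        assert w.low_signal[0, 2]

    def test_angle_known_cases(self):
        v = np.zeros((1, 4, 3))
        v[0, 0] = [0, 0, 1.0]
        v[0, 1] = [0, 0, -1.0]
        v[0, 2] = [1 / np.sqrt(2), 0, 1 / np.sqrt(2)]
        s = plane_sample(v)
        a = angle_map(s)
        assert a.values[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert a.values[0, 1] == pytest.approx(180.0, abs=1e-9)
        assert a.values[0, 2] == pytest.approx(45.0, abs=1e-9)
        assert a.values[0, 3] == 90.0 and a.low_signal[0, 3]

    def test_wpd_equals_cos_angle_pixelwise(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(8, 8, 3))
        s = plane_sample(v, [0.6, 0.0, 0.8])
        w = wpd_map(s).values
        a = angle_map(s).values
        assert np.allclose(w, np.cos(np.radians(a)), atol=1e-9)


class TestVorticity:
    @staticmethod
    def rigid_rotation_field(omega=10.0, n=16, spacing=1.0):
        ax = spacing * (np.arange(n) - n / 2)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        # v = (-omega*y, omega*x, 0) with x, y in metres
        vel = np.stack([-omega * Y / 1000.0, omega * X / 1000.0,
                        np.zeros_like(X)], axis=-1)
        return VelocityField(vel[None], np.full(3, spacing),
                             np.full(3, -spacing * n / 2), 40.0)

    def test_rigid_rotation_curl_is_2omega(self):
        omega = 10.0
        fld = self.rigid_rotation_field(omega)
        w = vorticity_field(fld, 0)
        interior = (slice(2, -2),) * 3
        assert np.allclose(w[interior][..., 2], 2 * omega, rtol=1e-9)
        assert np.allclose(w[interior][..., :2], 0.0, atol=1e-9)

    def test_uniform_field_zero_curl(self):
        vel = np.tile([0.1, 0.2, 0.3], (1, 8, 8, 8, 1))
        fld = VelocityField(vel, np.ones(3), np.zeros(3), 40.0)
        assert np.allclose(vorticity_field(fld, 0), 0.0, atol=1e-12)

    def test_poiseuille_azimuthal_magnitude(self):
        spec = PhantomSpec(profile_kind="poiseuille", n_timeframes=2,
                           voxel_size=1.0, peak_velocity=1.0)
        fld = generate_velocity_field(
            spec, ScannerProfile(n_timeframes=2, voxel_size=1.0))
        t = 0
        w = vorticity_field(fld, t)
        scale = float(spec.waveform[t])
        ax = [fld.origin[i] + fld.spacing[i] * np.arange(fld.grid_shape[i])
              for i in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        r = np.hypot(X, Y)
        R = spec.tube_radius
        sel = (r > 2.0) & (r < R - 3.0) & (Z > 20) & (Z < 100)
        # |curl| = 2 v_peak r / R^2 with r, R in metres
        expected = 2 * scale * 1.0 * (r[sel] / 1000.0) / (R / 1000.0) ** 2
        got = np.linalg.norm(w[sel], axis=-1)
        assert np.median(np.abs(got - expected) / expected) < 0.05

    def test_curl_of_gradient_vanishes(self):
        # discrete curl of a discrete gradient field is ~0 in the interior
        n = 12
        ax = np.arange(n, dtype=float)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        phi = np.sin(0.4 * X) * np.cos(0.3 * Y) + 0.1 * Z**2
        g = np.stack(np.gradient(phi, ax, ax, ax), axis=-1)
        fld = VelocityField(g[None], np.full(3, 1000.0), np.zeros(3), 40.0)
        w = vorticity_field(fld, 0)
        interior = (slice(2, -2),) * 3
        assert np.abs(w[interior]).max() < 1e-10 * max(1.0, np.abs(g).max())


class TestHelicityAndNormalVorticity:
    def make_plane_maps(self, kind, **kw):
        spec = PhantomSpec(profile_kind=kind, n_timeframes=2, voxel_size=1.0,
                           **kw)
        fld = generate_velocity_field(
            spec, ScannerProfile(n_timeframes=2, voxel_size=1.0))
        cl = make_centerline(spec)
        plane = place_planes(cl, 0, 0)[1]
        s = resample_mpr(fld, plane, 0)
        s.mask = lumen_mask_on_plane(spec, plane) & s.valid
        from flowradiomics.maps import _vorticity_on_plane

        vort = _vorticity_on_plane(fld, s)
        return spec, s, vort

    def test_poiseuille_lnh_near_zero(self):
        spec, s, vort = self.make_plane_maps("poiseuille")
        lnh = lnh_map(s, vort)
        # azimuthal vorticity is orthogonal to axial velocity
        interior = s.mask & ~lnh.low_signal
        # exclude wall-adjacent pixels where discretization mixes directions
        from scipy import ndimage

        core = ndimage.binary_erosion(s.mask, iterations=3)
        assert np.abs(lnh.values[interior & core]).max() < 1e-3

    def test_helical_lnh_sign_flips_with_handedness(self):
        _, s_r, vort_r = self.make_plane_maps("helical", helix_rate=8.0)
        _, s_l, vort_l = self.make_plane_maps("helical", helix_rate=-8.0)
        lnh_r = lnh_map(s_r, vort_r)
        lnh_l = lnh_map(s_l, vort_l)
        from scipy import ndimage

        core = ndimage.binary_erosion(s_r.mask, iterations=3)
        sel = core & ~lnh_r.low_signal & ~lnh_l.low_signal
        assert np.allclose(lnh_l.values[sel], -lnh_r.values[sel], atol=1e-6)

    def test_vortex_on_axis_lnh_is_one(self):
        # swirl + axial flow: on the axis vorticity and velocity align
        _, s, vort = self.make_plane_maps("vortex")
        lnh = lnh_map(s, vort)
        n = lnh.values.shape[0] // 2
        center = lnh.values[n - 1 : n + 1, n - 1 : n + 1]
        assert np.all(center > 0.97)

    def test_normal_vorticity_self_normalized_rigid_rotation(self):
        fld = TestVorticity.rigid_rotation_field(omega=5.0)
        plane = PlaneDefinition.from_origin_normal("p", [0, 0, 0], [0, 0, 1],
                                                   extent=8)
        s = resample_mpr(fld, plane, 0)
        s.mask = s.valid
        from flowradiomics.maps import _vorticity_on_plane

        vort = _vorticity_on_plane(fld, s)
        nv = normal_vorticity_map(s, vort)
        assert np.allclose(nv.values[s.mask], 1.0, atol=1e-6)
        # flipping the normal flips the sign
        s.plane.normal = -s.plane.normal
        nv2 = normal_vorticity_map(s, vort)
        assert np.allclose(nv2.values[s.mask], -nv.values[s.mask], atol=1e-9)

    def test_zero_vorticity_gives_zero_map(self):
        vel = np.tile([0.0, 0.0, 1.0], (1, 8, 8, 8, 1))
        fld = VelocityField(vel, np.ones(3), np.zeros(3), 40.0)
        plane = PlaneDefinition.from_origin_normal("p", [3.5, 3.5, 4],
                                                   [0, 0, 1], extent=6)
        s = resample_mpr(fld, plane, 0)
        s.mask = s.valid
        from flowradiomics.maps import _vorticity_on_plane

        nv = normal_vorticity_map(s, _vorticity_on_plane(fld, s))
        assert np.allclose(nv.values, 0.0)


class TestNormalization:
    def mk(self, kind, values):
        vals = np.atleast_2d(np.asarray(values, dtype=float))
        return ParameterMap(kind, vals, "native", np.ones_like(vals, bool),
                            np.zeros_like(vals, bool))

    def test_table_endpoints(self):
        assert normalize_map(self.mk("wpd", [1.0])).values[0, 0] == 4096
        a = normalize_map(self.mk("angle", [0.0, 180.0]))
        assert a.values[0, 0] == 0 and a.values[0, 1] == 4096
        u = normalize_map(self.mk("throughflow", [6.0, -6.0, 7.0]))
        assert u.values[0, 0] == 2047
        assert u.values[0, 1] == -2048
        assert u.values[0, 2] == 2047  # clipped

    def test_signed_ranges(self):
        lnh = normalize_map(self.mk("lnh", [-1.0, 1.0]))
        assert lnh.values[0, 0] == -2048 and lnh.values[0, 1] == 2047

    def test_round_trip_identity(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-0.99, 0.99, size=(5, 5))
        m = self.mk("lnh", vals)
        back = denormalize_map(normalize_map(m))
        assert np.allclose(back.values, vals, atol=1e-9)

    def test_kind_mismatch_rejected(self):
        spec = DEFAULT_NORMALIZATION["angle"]
        with pytest.raises(ValueError, match="does not match"):
            normalize_map(self.mk("wpd", [0.5]), spec)

    def test_double_normalization_rejected(self):
        m = normalize_map(self.mk("wpd", [0.5]))
        with pytest.raises(ValueError, match="already"):
            normalize_map(m)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="lo < hi"):
            NormalizationSpec("wpd", (1.0, 0.0), (0.0, 4096.0))
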