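"""Optic-flow estimation, sphere geometry and spherical flow summaries."""

import numpy as np
import pytest

from axmorph.optic_flow import (
    Kymograph,
    SphereModel,
    SphericalVelocityField,
    estimate_flow,
    fit_sphere,
    mercator_project,
    mercator_scale_factor,
    mercator_unproject,
    orient_axes,
    project_spherical,
    relative_velocity_kymograph,
    spherical_to_cartesian,
    transverse_extension_rate,
    VolumeMovie,
)
from axmorph.synthetic import synth_flow_movie


def sphere_points(centre, radius, n, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return centre + radius * v


class TestEstimateFlow:
    def test_static_movie_gives_zero_field(self, rng):
        from scipy import ndimage

        frame = ndimage.gaussian_filter(rng.normal(size=(16, 32, 32)), 3)
        movie = VolumeMovie(np.stack([frame, frame]))
        vel, ok = estimate_flow(movie, box=(10, 10, 6))
        assert ok.any()
        assert np.abs(vel[0][ok[0]]).max() < 1e-9

    def test_uniform_translation_recovered(self):
        meso, _, masks, gt = synth_flow_movie(
            "translation", field_params={"velocity": (1.0, 0.0, 0.0)},
            n_frames=3, seed=2,
        )
        vel, ok = estimate_flow(meso, box=(12, 12, 6))
        bulk = ok[0] & masks["mesoderm"]
        assert bulk.sum() > 500
        mean_v = vel[0][bulk].mean(axis=0)
        assert np.abs(mean_v - np.array([1.0, 0.0, 0.0])).max() < 0.1

    def test_rigid_rotation_direction_and_magnitude(self):
        omega = np.deg2rad(0.5) * np.array([0.0, 0.0, 1.0])
        meso, _, masks, gt = synth_flow_movie(
            "rotation", field_params={"omega": omega.tolist()},
            n_frames=3, seed=4,
        )
        vel, ok = estimate_flow(meso, box=(12, 12, 6))
        centre = gt.truth["centre"]
        nz, ny, nx = meso.data.shape[1:]
        zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                                 indexing="ij")
        pts = np.stack([xx, yy, zz], -1).astype(float)
        truth = np.cross(omega, pts - centre)
        sel = ok[0] & masks["mesoderm"] & (np.linalg.norm(truth, axis=-1) > 0.1)
        v = vel[0][sel]
        t = truth[sel]
        cos = (v * t).sum(1) / (np.linalg.norm(v, axis=1) * np.linalg.norm(t, axis=1))
        angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        mag_err = np.abs(np.linalg.norm(v, axis=1) - np.linalg.norm(t, axis=1))
        assert np.mean(angles) < 10.0
        assert np.mean(mag_err / np.linalg.norm(t, axis=1)) < 0.2

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            VolumeMovie(rng.normal(size=(1, 8, 8, 8)))


class TestFitSphere:
    def test_exact_points_recovered_to_machine_precision(self):
        s = fit_sphere(sphere_points(np.array([10.0, 20.0, 30.0]), 50.0, 500))
        assert np.abs(s.centre - [10, 20, 30]).max() < 1e-6
        assert s.radius == pytest.approx(50.0, abs=1e-6)

    def test_noisy_points_radius_error_bounded(self):
        rng = np.random.default_rng(81)
        pts = sphere_points(np.zeros(3), 50.0, 500, seed=8)
        pts = pts + rng.normal(scale=0.5, size=pts.shape)
        s = fit_sphere(pts)
        assert abs(s.radius - 50.0) < 0.1

    def test_coplanar_points_raise(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            fit_sphere(pts)


class TestOrientAxes:
    def _cap_points(self, pole, elong, radius=50.0, n=20000, spread=(0.9, 0.15)):
        """Anisotropic surface patch centred on +meridian, elongated along
        ``elong`` (both unit vectors, orthogonal)."""
        rng = np.random.default_rng(0)
        u = rng.normal(scale=spread[0], size=n)
        w = rng.normal(scale=spread[1], size=n)
        third = np.cross(pole, elong)
        d = (
            np.outer(np.cos(u) * np.cos(w), pole)
            + np.outer(np.sin(u) * np.cos(w), elong)
            + np.outer(np.sin(w), third)
        )
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return radius * d

    def test_meridian_aligned_mask_keeps_pole(self):
        pole = np.array([0.0, 0.0, 1.0])
        elong = np.array([0.0, 0.0, 1.0])
        pts = self._cap_points(np.array([1.0, 0.0, 0.0]), elong)
        sphere = SphereModel(centre=np.zeros(3), radius=50.0)
        out = orient_axes(sphere, pts)
        assert abs(abs(out.pole_axis @ pole) - 1.0) < 5e-3

    def test_known_rotation_recovered_within_one_degree(self):
        angle = np.deg2rad(30)
        elong = np.array([0.0, np.sin(angle), np.cos(angle)])
        pts = self._cap_points(np.array([1.0, 0.0, 0.0]), elong)
        sphere = SphereModel(centre=np.zeros(3), radius=50.0)
        out = orient_axes(sphere, pts)
        err = np.degrees(np.arccos(np.clip(abs(out.pole_axis @ elong), -1, 1)))
        assert err < 1.0

    def test_isotropic_cap_raises_ambiguity(self):
        pts = self._cap_points(
            np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]),
            spread=(0.3, 0.3),
        )
        sphere = SphereModel(centre=np.zeros(3), radius=50.0)
        with pytest.raises(ValueError, match="isotropic|dominant"):
            orient_axes(sphere, pts)


class TestProjectSpherical:
    def _sphere(self):
        return SphereModel(centre=np.zeros(3), radius=10.0)

    def test_radial_field_has_zero_tangential_components(self):
        sphere = self._sphere()
        pts = sphere_points(np.zeros(3), 10.0, 300)
        vel = 2.5 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        f = project_spherical(pts, vel, sphere)
        assert np.abs(f.v_theta).max() < 1e-9
        assert np.abs(f.v_phi).max() < 1e-9
        assert f.v_r == pytest.approx(np.full(len(pts), 2.5))

    def test_unit_azimuthal_field(self):
        sphere = self._sphere()
        pts = sphere_points(np.zeros(3), 10.0, 300)
        pole = sphere.pole_axis
        that = np.cross(pole, pts)
        that /= np.linalg.norm(that, axis=1, keepdims=True)
        f = project_spherical(pts, that, sphere)
        assert f.v_theta == pytest.approx(np.ones(len(pts)), abs=1e-9)
        assert np.abs(f.v_phi).max() < 1e-9

    def test_round_trip_and_speed_preservation(self, rng):
        sphere = self._sphere()
        pts = sphere_points(np.zeros(3), 10.0, 300)
        vel = rng.normal(size=pts.shape)
        f = project_spherical(pts, vel, sphere)
        back = spherical_to_cartesian(f)
        assert np.abs(back - vel).max() < 1e-9
        speeds = np.sqrt(f.v_r**2 + f.v_theta**2 + f.v_phi**2)
        assert speeds == pytest.approx(np.linalg.norm(vel, axis=1), abs=1e-9)

    def test_centre_point_invalid(self):
        sphere = self._sphere()
        with pytest.raises(ValueError):
            project_spherical(np.zeros((1, 3)), np.ones((1, 3)), sphere)


def _field_on_sphere(sphere, v_phi_fn, n=4000, seed=0):
    pts = sphere_points(sphere.centre, sphere.radius, n, seed=seed)
    _, theta, phi = sphere.angles(pts)
    return SphericalVelocityField(
        positions=pts,
        v_r=np.zeros(n),
        v_theta=np.zeros(n),
        v_phi=v_phi_fn(phi),
        theta=theta,
        phi=phi,
        valid=np.ones(n, bool),
        sphere=sphere,
    )


class TestKymograph:
    def test_identical_fields_give_zero(self):
        sphere = SphereModel(centre=np.zeros(3), radius=10.0)
        f = _field_on_sphere(sphere, lambda phi: np.cos(phi))
        times = np.zeros(len(f.phi))
        km = relative_velocity_kymograph(f, f, times, times)
        vals = km.values[~np.isnan(km.values)]
        assert np.abs(vals).max() < 1e-12
        assert km.sign_convention == "ectoderm minus mesoderm"

    def test_prescribed_step_contrast(self):
        """Mesoderm slower by 0.2 for phi < 90 deg: kymograph is +0.2 in those
        phi bins and 0 elsewhere."""
        sphere = SphereModel(centre=np.zeros(3), radius=10.0)
        ecto = _field_on_sphere(sphere, lambda phi: np.ones_like(phi))
        meso = _field_on_sphere(
            sphere, lambda phi: np.where(phi < np.pi / 2, 0.8, 1.0)
        )
        times = np.zeros(len(ecto.phi))
        km = relative_velocity_kymograph(meso, ecto, times, times)
        centres = 0.5 * (km.phi_edges[:-1] + km.phi_edges[1:])
        for i, c in enumerate(centres):
            v = km.values[i, 0]
            if np.isnan(v):
                continue
            expected = 0.2 if c < np.pi / 2 else 0.0
            # skip the bin containing the step itself
            if abs(c - np.pi / 2) < np.diff(km.phi_edges)[0]:
                continue
            assert v == pytest.approx(expected, abs=1e-9)

    def test_default_time_bin_is_five_minutes(self):
        import inspect

        sig = inspect.signature(relative_velocity_kymograph)
        assert sig.parameters["time_bin_min"].default == 5.0

    def test_sign_flip_of_inputs_flips_kymograph(self):
        sphere = SphereModel(centre=np.zeros(3), radius=10.0)
        ecto = _field_on_sphere(sphere, lambda phi: np.ones_like(phi))
        meso = _field_on_sphere(sphere, lambda phi: 0.5 * np.ones_like(phi))
        times = np.zeros(len(ecto.phi))
        km = relative_velocity_kymograph(meso, ecto, times, times)
        km_flipped = relative_velocity_kymograph(ecto, meso, times, times)
        a, b = km.values, km_flipped.values
        mask = ~np.isnan(a)
        assert a[mask] == pytest.approx(-b[mask])


class TestTransverseExtension:
    def _masked_field(self, v_theta_fn, seed=0):
        sphere = SphereModel(centre=np.zeros(3), radius=10.0)
        pts = sphere_points(np.zeros(3), 10.0, 6000, seed=seed)
        _, theta, phi = sphere.angles(pts)
        # tissue strip: theta within (0.5, 2.5)
        valid = (theta > 0.5) & (theta < 2.5)
        return SphericalVelocityField(
            positions=pts, v_r=np.zeros(len(pts)),
            v_theta=v_theta_fn(theta), v_phi=np.zeros(len(pts)),
            theta=theta, phi=phi, valid=valid, sphere=sphere,
        )

    def test_zero_field_gives_zero_profile(self):
        f = self._masked_field(lambda th: np.zeros_like(th))
        _, prof = transverse_extension_rate(f)
        assert np.nanmax(np.abs(prof)) < 1e-12

    def test_theta_divergence_sign(self):
        diverging = self._masked_field(lambda th: 0.3 * (th - 1.5))
        _, prof = transverse_extension_rate(diverging)
        assert np.nanmin(prof) > 0  # broadening everywhere
        converging = self._masked_field(lambda th: -0.3 * (th - 1.5))
        _, prof2 = transverse_extension_rate(converging)
        assert np.nanmax(prof2) < 0  # thinning everywhere

    def test_narrow_mask_raises(self):
        f = self._masked_field(lambda th: np.zeros_like(th))
        f.valid &= (f.theta > 1.49) & (f.theta < 1.51)
        with pytest.raises(ValueError, match="narrower"):
            transverse_extension_rate(f)


class TestMercator:
    def test_equator_maps_to_midline(self):
        x, y, inside = mercator_project(np.array([1.0]), np.array([np.pi / 2]))
        assert inside[0] and y[0] == pytest.approx(0.0, abs=1e-12)

    def test_scale_factor_at_sixty_degrees(self):
        assert mercator_scale_factor(np.deg2rad(60.0)) == pytest.approx(2.0)

    def test_invertible_within_domain(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 200)
        phi = rng.uniform(np.deg2rad(6), np.deg2rad(174), 200)
        x, y, inside = mercator_project(theta, phi)
        assert inside.all()
        t2, p2 = mercator_unproject(x, y)
        assert np.abs(t2 - theta).max() < 1e-9
        assert np.abs(p2 - phi).max() < 1e-9

    def test_polar_points_flagged_outside(self):
        _, y, inside = mercator_project(np.array([0.0]), np.array([0.01]))
        assert not inside[0]
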