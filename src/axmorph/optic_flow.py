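"""3D optic-flow tissue velocimetry on spherical embryo geometry.

Pipeline: (1) estimate a dense 3D velocity field from a two-channel
volumetric time-lapse by local least squares on spatio-temporal intensity
gradients (Lucas–Kanade style) within a sliding box, default 20 x 20 x 8
voxels; (2) fit a sphere to the embryo surface and orient its pole so the
mesoderm's elongation axis lies in the meridian plane; (3) decompose the
Cartesian velocities into spherical components (v_r, v_theta, v_phi); (4)
summarise tissue-relative motion as kymographs of (ectoderm - mesoderm)
velocity over polar-angle and time bins, transverse (theta) extension-rate
profiles and Mercator flow maps.

Angle conventions: ``phi`` is the polar angle measured from the pole (the
animal pole once oriented), ``theta`` in [0, 2π) the azimuth measured from
the meridian reference direction; Mercator latitude is π/2 - phi.  These
conventions are recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VolumeMovie",
    "SphereModel",
    "SphericalVelocityField",
    "Kymograph",
    "estimate_flow",
    "fit_sphere",
    "orient_axes",
    "project_spherical",
    "relative_velocity_kymograph",
    "transverse_extension_rate",
    "mercator_project",
    "mercator_map",
    "MERCATOR_LATITUDE_CUTOFF_DEG",
]

MERCATOR_LATITUDE_CUTOFF_DEG = 85.0


@dataclass
class VolumeMovie:
    """4D intensity movie (t, z, y, x) with physical calibration."""

    data: np.ndarray
    voxel_size: float = 1.0  # µm, isotropic
    frame_interval: float = 1.0  # minutes
    channel: str = "mesoderm"  # or "ectoderm"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4:
            raise ValueError("movie must be 4D (t, z, y, x)")
        if self.data.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be > 0")


@dataclass
class SphereModel:
    """Sphere geometry with an orientation frame.

    ``pole_axis`` points to the pole (phi = 0); ``meridian_ref`` fixes the
    theta = 0 azimuth and is orthogonalised against the pole axis.
    """

    centre: np.ndarray
    radius: float
    pole_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    meridian_ref: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, float)
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        self.pole_axis = self._unit(np.asarray(self.pole_axis, float))
        ref = np.asarray(self.meridian_ref, float)
        ref = ref - (ref @ self.pole_axis) * self.pole_axis
        if np.linalg.norm(ref) < 1e-12:
            raise ValueError("meridian reference is parallel to the pole axis")
        self.meridian_ref = self._unit(ref)

    @staticmethod
    def _unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero-length axis")
        return v / n

    @property
    def third_axis(self) -> np.ndarray:
        """Completes the right-handed frame (pole, meridian_ref, third)."""
        return np.cross(self.pole_axis, self.meridian_ref)

    def angles(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(r, theta, phi) of Cartesian points relative to the sphere frame."""
        d = np.atleast_2d(points) - self.centre
        r = np.linalg.norm(d, axis=-1)
        if np.any(r == 0):
            raise ValueError("point at the sphere centre has undefined angles")
        zc = d @ self.pole_axis
        xc = d @ self.meridian_ref
        yc = d @ self.third_axis
        phi = np.arccos(np.clip(zc / r, -1.0, 1.0))
        theta = np.mod(np.arctan2(yc, xc), 2.0 * np.pi)
        return r, theta, phi


@dataclass
class SphericalVelocityField:
    """Velocities in the sphere's orthonormal basis at sample positions.

    Components: ``v_r`` radial, ``v_theta`` azimuthal, ``v_phi`` polar
    (toward increasing phi, i.e. away from the pole).  ``valid`` masks the
    samples with trustworthy estimates.
    """

    positions: np.ndarray  # (n, 3) Cartesian, µm
    v_r: np.ndarray
    v_theta: np.ndarray
    v_phi: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    valid: np.ndarray
    sphere: SphereModel
    conventions: dict = field(
        default_factory=lambda: {
            "phi": "polar angle from the pole (radians)",
            "theta": "azimuth from the meridian reference, [0, 2pi)",
        }
    )


@dataclass
class Kymograph:
    """Relative-velocity matrix over (phi bin, time bin)."""

    values: np.ndarray  # (n_phi, n_time), NaN = empty bin
    phi_edges: np.ndarray
    time_edges: np.ndarray  # minutes
    sign_convention: str = "ectoderm minus mesoderm"
    component: str = "v_phi"


def estimate_flow(
    movie: VolumeMovie,
    box: tuple[int, int, int] = (20, 20, 8),
    mask: np.ndarray | None = None,
    condition_cutoff: float = 1e3,
    iterations: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense 3D velocity estimate for each consecutive frame pair.

    Solves, per voxel, the least-squares system built from the brightness-
    constancy equation ``g . v + I_t = 0`` accumulated over a sliding box
    centred on the voxel (uniform weights).  The box is (x, y, z) sized;
    estimates are valid only where the mask holds (if given) and the local
    3x3 structure tensor is well conditioned.  ``iterations`` > 1 applies
    warp refinement (the second frame is resampled along the current
    estimate and the residual flow re-estimated), which keeps displacements
    up to a few voxels/frame within the linearisation regime.

    Returns
    -------
    velocities : (t-1, z, y, x, 3) array of (vx, vy, vz) in voxels/frame.
    valid : (t-1, z, y, x) boolean validity mask.

    Displacements should stay below about a quarter of the box per frame for
    the estimate to be trustworthy.
    """
    from scipy import ndimage

    data = movie.data
    n_t = data.shape[0]
    bx, by, bz = box
    size = (bz, by, bx)  # ndimage order (z, y, x)
    shape = data.shape[1:]
    out_v = np.zeros((n_t - 1,) + shape + (3,), float)
    out_ok = np.zeros((n_t - 1,) + shape, bool)
    grid = np.indices(shape, dtype=float)  # (3, z, y, x) in (z, y, x) order

    def solve_pair(a, b):
        avg = 0.5 * (a + b)
        gz, gy, gx = np.gradient(avg)
        it = b - a
        comps = {}
        for (na, ga), (nb, gb) in (
            (("x", gx), ("x", gx)),
            (("x", gx), ("y", gy)),
            (("x", gx), ("z", gz)),
            (("y", gy), ("y", gy)),
            (("y", gy), ("z", gz)),
            (("z", gz), ("z", gz)),
        ):
            comps[na + nb] = ndimage.uniform_filter(ga * gb, size=size)
        rhs = {
            n: -ndimage.uniform_filter(g * it, size=size)
            for n, g in (("x", gx), ("y", gy), ("z", gz))
        }
        A = np.stack(
            [
                np.stack([comps["xx"], comps["xy"], comps["xz"]], -1),
                np.stack([comps["xy"], comps["yy"], comps["yz"]], -1),
                np.stack([comps["xz"], comps["yz"], comps["zz"]], -1),
            ],
            -2,
        )
        bvec = np.stack([rhs["x"], rhs["y"], rhs["z"]], -1)
        # condition of the symmetric 3x3 systems via eigenvalues
        w = np.linalg.eigvalsh(A)
        ok = (w[..., 0] > 1e-12) & (
            w[..., -1] / np.maximum(w[..., 0], 1e-300) < condition_cutoff
        )
        vel = np.zeros(shape + (3,), float)
        if ok.any():
            vel[ok] = np.linalg.solve(A[ok], bvec[ok][..., None])[..., 0]
        return vel, ok

    for t in range(n_t - 1):
        a, b = data[t], data[t + 1]
        vel, ok = solve_pair(a, b)
        for _ in range(max(iterations - 1, 0)):
            # resample the second frame along the current estimate and
            # accumulate the residual flow
            coords = grid + np.stack([vel[..., 2], vel[..., 1], vel[..., 0]])
            b_w = ndimage.map_coordinates(b, coords, order=1, mode="nearest")
            dvel, ok = solve_pair(a, b_w)
            vel = vel + dvel
        if mask is not None:
            ok = ok & np.asarray(mask, bool)
        out_v[t] = vel
        out_ok[t] = ok
    return out_v, out_ok


def fit_sphere(points: np.ndarray) -> SphereModel:
    """Algebraic least-squares sphere fit.

    Solves ``|p|^2 = 2 c . p + (R^2 - |c|^2)`` linearly for the centre c and
    radius R.  Raises on degenerate (coplanar or near-coplanar) inputs.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need at least 4 points of dimension 3")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise ValueError("degenerate sphere fit: points are coplanar or collinear")
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise ValueError("degenerate sphere fit: non-positive radius")
    return SphereModel(centre=centre, radius=float(np.sqrt(r2)))


def orient_axes(
    sphere: SphereModel,
    mesoderm_points: np.ndarray,
    anisotropy_tolerance: float = 1.2,
) -> SphereModel:
    """Orient the pole so the tissue's elongation axis runs along a meridian.

    The principal elongation axis of the mesoderm surface points (second
    moments about their centroid) is projected onto the tangent plane at the
    mask centroid direction; the pole axis is set to that tangential
    direction, which places the elongation axis in the meridian plane through
    the tissue.  The meridian reference is the centroid direction projected
    off the pole.  Raises when the mask is isotropic (leading second-moment
    ratio below ``anisotropy_tolerance``).
    """
    pts = np.asarray(mesoderm_points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("mesoderm mask needs at least 3 points")
    d = pts - sphere.centre
    m = d.mean(axis=0)
    if np.linalg.norm(m) < 1e-9:
        raise ValueError("mask centroid coincides with the sphere centre")
    m = m / np.linalg.norm(m)
    # second moments in the tangent plane at the centroid direction: the
    # radial component only encodes surface curvature, not tissue elongation
    q = d - np.outer(d @ m, m)
    q = q - q.mean(axis=0)
    cov = q.T @ q / len(q)
    w, v = np.linalg.eigh(cov)
    if w[-1] < anisotropy_tolerance * max(w[-2], 1e-300):
        raise ValueError("mask has no dominant elongation axis (isotropic)")
    e = v[:, -1]
    e_t = e - (e @ m) * m
    if np.linalg.norm(e_t) < 1e-9:
        raise ValueError("elongation axis is radial; orientation ambiguous")
    pole = e_t / np.linalg.norm(e_t)
    return SphereModel(
        centre=sphere.centre,
        radius=sphere.radius,
        pole_axis=pole,
        meridian_ref=m,
    )


def _spherical_basis(sphere: SphereModel, positions: np.ndarray):
    d = np.atleast_2d(positions) - sphere.centre
    r = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(r == 0):
        raise ValueError("position at the sphere centre is invalid")
    rhat = d / r
    p = sphere.pole_axis
    # theta-hat: azimuthal tangent = pole x rhat, normalised; undefined at poles
    th = np.cross(np.broadcast_to(p, rhat.shape), rhat)
    n = np.linalg.norm(th, axis=-1, keepdims=True)
    polar = (n[..., 0] < 1e-12)
    n = np.where(n < 1e-12, 1.0, n)
    that = th / n
    # phi-hat: toward increasing polar angle (away from the pole)
    phat = np.cross(that, rhat)
    return rhat, that, phat, polar


def project_spherical(
    positions: np.ndarray,
    velocities: np.ndarray,
    sphere: SphereModel,
    valid: np.ndarray | None = None,
) -> SphericalVelocityField:
    """Decompose Cartesian velocities into (v_r, v_theta, v_phi).

    The decomposition uses the orthonormal basis (r-hat, theta-hat, phi-hat)
    at each position, so speed is preserved:
    ``|v|^2 = v_r^2 + v_theta^2 + v_phi^2``.  On-pole samples (azimuth
    undefined) are invalidated.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    velocities = np.atleast_2d(np.asarray(velocities, float))
    if positions.shape != velocities.shape:
        raise ValueError("positions and velocities must have matching shapes")
    rhat, that, phat, polar = _spherical_basis(sphere, positions)
    v_r = (velocities * rhat).sum(-1)
    v_t = (velocities * that).sum(-1)
    v_p = (velocities * phat).sum(-1)
    r, theta, phi = sphere.angles(positions)
    ok = ~polar
    if valid is not None:
        ok = ok & np.asarray(valid, bool)
    return SphericalVelocityField(
        positions=positions,
        v_r=v_r,
        v_theta=v_t,
        v_phi=v_p,
        theta=theta,
        phi=phi,
        valid=ok,
        sphere=sphere,
    )


def spherical_to_cartesian(field: SphericalVelocityField) -> np.ndarray:
    """Inverse of :func:`project_spherical` (basis orthonormality)."""
    rhat, that, phat, _ = _spherical_basis(field.sphere, field.positions)
    return (
        field.v_r[..., None] * rhat
        + field.v_theta[..., None] * that
        + field.v_phi[..., None] * phat
    )


def relative_velocity_kymograph(
    meso: SphericalVelocityField,
    ecto: SphericalVelocityField,
    meso_times: np.ndarray,
    ecto_times: np.ndarray,
    phi_edges: np.ndarray | None = None,
    time_bin_min: float = 5.0,
    component: str = "v_phi",
) -> Kymograph:
    """Kymograph of the (ectoderm - mesoderm) velocity component.

    Each tissue's samples are averaged (over theta and within the tissue's
    validity mask) per (phi bin, time bin); the kymograph is the ectoderm
    average minus the mesoderm average.  Bins with no samples from either
    tissue are NaN (missing, not zero).  The default time bin is 5 minutes.
    """
    if phi_edges is None:
        phi_edges = np.linspace(0.0, np.pi, 19)
    phi_edges = np.asarray(phi_edges, float)
    meso_times = np.asarray(meso_times, float)
    ecto_times = np.asarray(ecto_times, float)
    t_max = max(meso_times.max(), ecto_times.max())
    t_min = min(meso_times.min(), ecto_times.min())
    n_tb = max(int(np.ceil((t_max - t_min) / time_bin_min)), 1)
    time_edges = t_min + time_bin_min * np.arange(n_tb + 1)

    def binned(field: SphericalVelocityField, times: np.ndarray) -> np.ndarray:
        comp = getattr(field, component).ravel()
        ok = field.valid.ravel()
        pi_ = np.clip(np.digitize(field.phi.ravel(), phi_edges) - 1, 0, len(phi_edges) - 2)
        ti_ = np.clip(np.digitize(times.ravel(), time_edges) - 1, 0, n_tb - 1)
        sums = np.zeros((len(phi_edges) - 1, n_tb))
        cnt = np.zeros_like(sums)
        np.add.at(sums, (pi_[ok], ti_[ok]), comp[ok])
        np.add.at(cnt, (pi_[ok], ti_[ok]), 1.0)
        with np.errstate(invalid="ignore"):
            return sums / np.where(cnt == 0, np.nan, cnt)

    km = binned(ecto, ecto_times) - binned(meso, meso_times)
    return Kymograph(
        values=km,
        phi_edges=phi_edges,
        time_edges=time_edges,
        component=component,
    )


def transverse_extension_rate(
    field: SphericalVelocityField,
    phi_edges: np.ndarray | None = None,
    n_theta_bins: int = 24,
) -> tuple[np.ndarray, np.ndarray]:
    """Rate of change of the tissue's theta extent, profiled along phi.

    For each phi band the tissue's valid samples are binned in theta and the
    extension rate is the difference of the mean ``v_theta`` between the
    high-theta and low-theta edges of the tissue (the integral of
    d(v_theta)/d(theta) across the tissue width).  Positive values mean the
    tissue broadens perpendicular to the migration (meridian) axis, negative
    values mean it thins.

    Returns (phi bin centres, extension-rate profile).  Raises when the
    tissue is narrower than 3 theta bins everywhere.
    """
    if phi_edges is None:
        phi_edges = np.linspace(0.0, np.pi, 19)
    phi_edges = np.asarray(phi_edges, float)
    centres = 0.5 * (phi_edges[:-1] + phi_edges[1:])
    theta_edges = np.linspace(0.0, 2.0 * np.pi, n_theta_bins + 1)
    prof = np.full(len(centres), np.nan)
    any_wide = False
    phi = field.phi.ravel()
    theta = field.theta.ravel()
    v_t = field.v_theta.ravel()
    ok = field.valid.ravel()
    for i in range(len(centres)):
        sel = ok & (phi >= phi_edges[i]) & (phi < phi_edges[i + 1])
        if not sel.any():
            continue
        tb = np.digitize(theta[sel], theta_edges) - 1
        occupied = np.unique(tb)
        if len(occupied) < 3:
            continue
        any_wide = True
        lo, hi = occupied.min(), occupied.max()
        v_lo = v_t[sel][tb == lo].mean()
        v_hi = v_t[sel][tb == hi].mean()
        prof[i] = v_hi - v_lo
    if not any_wide:
        raise ValueError("tissue narrower than 3 theta bins in every phi band")
    return centres, prof


def mercator_project(
    theta: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mercator projection x = theta, y = ln tan(pi/4 + lat/2), lat = pi/2 - phi.

    Points beyond ±85° latitude are flagged (dropped by the map); the
    projection is conformal with local scale factor sec(lat).
    """
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    lat = np.pi / 2.0 - phi
    cutoff = np.deg2rad(MERCATOR_LATITUDE_CUTOFF_DEG)
    inside = np.abs(lat) <= cutoff
    y = np.where(inside, np.log(np.tan(np.pi / 4.0 + np.clip(lat, -cutoff, cutoff) / 2.0)), np.nan)
    return theta.copy(), y, inside


def mercator_unproject(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse Mercator: returns (theta, phi)."""
    lat = 2.0 * np.arctan(np.exp(np.asarray(y, float))) - np.pi / 2.0
    return np.asarray(x, float), np.pi / 2.0 - lat


def mercator_scale_factor(latitude: np.ndarray) -> np.ndarray:
    """Local Mercator scale factor sec(latitude)."""
    return 1.0 / np.cos(np.asarray(latitude, float))


def mercator_map(field: SphericalVelocityField, ax=None, **quiver_kw):
    """Quiver plot of the tangential flow on a 2D Mercator map.

    Returns (fig, ax, n_dropped) where ``n_dropped`` counts samples beyond
    the latitude cutoff.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x, y, inside = mercator_project(field.theta, field.phi)
    keep = inside & field.valid
    n_dropped = int((~inside & field.valid).sum())
    if ax is None:
        fig, ax = plt.subplots()
    else:
        fig = ax.figure
    ax.quiver(
        x[keep], y[keep], field.v_theta[keep], -field.v_phi[keep], **quiver_kw
    )
    ax.set_xlabel("theta (azimuth, rad)")
    ax.set_ylabel("Mercator y")
    return fig, ax, n_dropped
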