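"""Synthetic-data generators with recorded ground truth.

Every input class the analysis modules consume can be generated here with a
known answer, so the whole pipeline is testable without any microscopy data:
textured spherical-shell movies advected by prescribed velocity fields
(mimicking a two-channel mesoderm/ectoderm time-lapse), exponential FRAP
recovery traces sampled at 10 s intervals, rasterized label images of known
geometry, correlated two-channel voxel stacks with a target Pearson
coefficient, and runnable simulation configs.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Any

import numpy as np
from scipy import ndimage

from .cpm.types import CellType
from .frap import FrapTrace
from .morphometrics import LabelImage
from .optic_flow import SphereModel, VolumeMovie

__all__ = [
    "GroundTruth",
    "synth_flow_movie",
    "synth_frap_trace",
    "synth_label_shapes",
    "synth_coloc_pair",
    "synth_sim_config",
]


@dataclass
class GroundTruth:
    """What a generator actually put into its outputs."""

    generator: str
    parameters: dict[str, Any]
    seed: int
    truth: dict[str, Any]


def _smooth_texture(shape, rng, correlation_length=4.0):
    """Band-limited Gaussian random field: smooth, well-conditioned texture."""
    noise = rng.normal(size=shape)
    tex = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="wrap")
    tex -= tex.mean()
    s = tex.std()
    return tex / s if s > 0 else tex


def _velocity_at(spec: str, pts: np.ndarray, centre, params) -> np.ndarray:
    """Analytic velocity field (voxels/frame) at Cartesian points (x, y, z)."""
    if spec == "translation":
        v = np.asarray(params["velocity"], float)
        return np.broadcast_to(v, pts.shape).copy()
    if spec == "rotation":
        omega = np.asarray(params["omega"], float)  # rad/frame, axis*rate
        return np.cross(np.broadcast_to(omega, pts.shape), pts - centre)
    if spec == "phi_drift":
        # polar-angle drift about pole_axis with a leading/trailing speed
        # contrast: angular rate fast for phi < phi_step, slow beyond
        pole = np.asarray(params.get("pole_axis", (0.0, 0.0, 1.0)), float)
        pole = pole / np.linalg.norm(pole)
        d = pts - centre
        r = np.linalg.norm(d, axis=-1, keepdims=True)
        rhat = d / np.where(r == 0, 1.0, r)
        cosphi = np.clip(rhat @ pole, -1.0, 1.0)
        phi = np.arccos(cosphi)
        that = np.cross(np.broadcast_to(pole, rhat.shape), rhat)
        n = np.linalg.norm(that, axis=-1, keepdims=True)
        that = that / np.where(n < 1e-12, 1.0, n)
        phat = np.cross(that, rhat)
        rate = np.where(
            phi < params.get("phi_step", np.pi / 2),
            params.get("rate_leading", 0.01),
            params.get("rate_trailing", 0.005),
        )
        return rate[..., None] * r * phat
    raise ValueError(f"unknown field spec {spec!r}")


def synth_flow_movie(
    field_spec: str = "translation",
    shape: tuple[int, int, int] = (24, 64, 64),  # (z, y, x)
    shell_radius: float = 26.0,
    shell_thickness: float = 10.0,
    n_frames: int = 4,
    noise: float = 0.0,
    seed: int = 0,
    field_params: dict | None = None,
    ecto_field_params: dict | None = None,
    voxel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> tuple[VolumeMovie, VolumeMovie, dict[str, np.ndarray], GroundTruth]:
    """Two-channel textured movie advected by an analytic velocity field.

    A smooth random texture fills the volume and each frame ``t`` samples it
    at positions displaced backwards along the prescribed field, so the
    apparent motion equals the field.  The mesoderm and ectoderm channels
    carry independently specified fields (``field_params`` /
    ``ecto_field_params``; the latter defaults to the former) and disjoint
    spherical-shell masks (mesoderm inner shell, ectoderm outer shell).

    Returns (mesoderm movie, ectoderm movie, masks dict, ground truth).
    """
    rng = np.random.default_rng(seed)
    if field_params is None:
        field_params = {"velocity": (1.0, 0.0, 0.0)}
    if ecto_field_params is None:
        ecto_field_params = dict(field_params)
    nz, ny, nx = shape
    centre = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])

    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    pts = np.stack([xx, yy, zz], axis=-1).astype(float)  # (z, y, x, 3) as (x,y,z)
    rad = np.linalg.norm(pts - centre, axis=-1)
    meso_mask = (rad >= shell_radius - shell_thickness) & (rad < shell_radius)
    ecto_mask = (rad >= shell_radius) & (rad < shell_radius + shell_thickness)

    # per-frame displacement is approximated by the local field value at the
    # sample point (exact for uniform translation, first order otherwise)
    max_speed = 0.0
    movies = {}
    for name, fp in (("mesoderm", field_params), ("ectoderm", ecto_field_params)):
        tex = _smooth_texture(shape, rng)
        frames = np.empty((n_frames,) + shape)
        for t in range(n_frames):
            disp = t * _velocity_at(field_spec, pts.reshape(-1, 3), centre, fp)
            max_speed = max(max_speed, float(np.abs(disp).max() / max(t, 1)))
            back = pts.reshape(-1, 3) - disp
            # map_coordinates wants (z, y, x) index order
            coords = np.stack(
                [back[:, 2], back[:, 1], back[:, 0]], axis=0
            ).reshape(3, *shape)
            frames[t] = ndimage.map_coordinates(tex, coords, order=3, mode="wrap")
        if noise > 0:
            frames = frames + rng.normal(scale=noise, size=frames.shape)
        movies[name] = VolumeMovie(
            data=frames,
            voxel_size=voxel_size,
            frame_interval=frame_interval,
            channel=name,
        )
    if max_speed > 10.0:
        import warnings

        warnings.warn(
            "per-frame displacement exceeds half the default flow box; "
            "flow validity is violated by construction",
            stacklevel=2,
        )
    truth = GroundTruth(
        generator="synth_flow_movie",
        parameters={
            "field_spec": field_spec,
            "shape": shape,
            "shell_radius": shell_radius,
            "n_frames": n_frames,
            "noise": noise,
            "field_params": field_params,
            "ecto_field_params": ecto_field_params,
        },
        seed=seed,
        truth={
            "centre": centre,
            "field_spec": field_spec,
            "field_params": field_params,
            "ecto_field_params": ecto_field_params,
        },
    )
    masks = {"mesoderm": meso_mask, "ectoderm": ecto_mask}
    return movies["mesoderm"], movies["ectoderm"], masks, truth


def synth_frap_trace(
    k: float = 0.01,
    plateau: float = 0.8,
    noise_sigma: float = 0.0,
    n_pre: int = 5,
    n_post: int = 30,
    dt: float = 10.0,
    seed: int = 0,
) -> tuple[FrapTrace, GroundTruth]:
    """Normalized FRAP trace: pre-bleach at 1, bleach to 0, exponential
    recovery ``plateau (1 - e^{-k t})`` sampled every ``dt`` seconds (default
    10 s) with optional Gaussian noise."""
    if k <= 0:
        raise ValueError("recovery rate k must be > 0")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    times = dt * np.arange(n_pre + n_post)
    t_post = dt * np.arange(n_post)
    intensities = np.concatenate(
        [np.ones(n_pre), plateau * (1.0 - np.exp(-k * t_post))]
    )
    if noise_sigma > 0:
        noisy = intensities + rng.normal(scale=noise_sigma, size=intensities.shape)
        # keep the normalization anchors exact (they are set, not measured)
        noisy[n_pre] = 0.0
        intensities = noisy
    trace = FrapTrace(
        times=times, intensities=intensities, bleach_index=n_pre, normalized=True
    )
    gt = GroundTruth(
        generator="synth_frap_trace",
        parameters={
            "k": k,
            "plateau": plateau,
            "noise_sigma": noise_sigma,
            "n_pre": n_pre,
            "n_post": n_post,
            "dt": dt,
        },
        seed=seed,
        truth={"k": k, "plateau": plateau, "t90": float(-np.log(0.1) / k)},
    )
    return trace, gt


def synth_label_shapes(
    specs: list[dict],
    image_size: tuple[int, int] = (256, 256),
    pixel_size: float = 1.0,
    seed: int = 0,
) -> tuple[LabelImage, GroundTruth]:
    """Rasterize disks/rectangles/ellipses with analytic truth.

    Each spec is e.g. ``{"shape": "disk", "centre": (r, c), "radius": 50}``,
    ``{"shape": "rect", "top": r, "left": c, "height": h, "width": w}`` or
    ``{"shape": "ellipse", "centre": (r, c), "a": ra, "b": rb}``.
    Rasterization uses the centre-inclusion rule (a pixel belongs to the
    shape when its centre does).  Overlaps are allowed (later labels win)
    and recorded in the truth payload for merge tests.
    """
    labels = np.zeros(image_size, np.int32)
    shapes_truth = []
    rr, cc = np.meshgrid(
        np.arange(image_size[0]), np.arange(image_size[1]), indexing="ij"
    )
    overlapped = 0
    for i, spec in enumerate(specs, start=1):
        kind = spec["shape"]
        if kind == "disk":
            r0, c0 = spec["centre"]
            rad = float(spec["radius"])
            mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            analytic = {
                "area": np.pi * rad**2,
                "perimeter": 2 * np.pi * rad,
                "circularity": 1.0,
            }
        elif kind == "rect":
            t, l = spec["top"], spec["left"]
            h, w = spec["height"], spec["width"]
            mask = (rr >= t) & (rr < t + h) & (cc >= l) & (cc < l + w)
            analytic = {
                "area": float(h * w),
                "perimeter": 2.0 * (h + w),
                "circularity": 4 * np.pi * h * w / (2.0 * (h + w)) ** 2,
            }
        elif kind == "ellipse":
            r0, c0 = spec["centre"]
            a, b = float(spec["a"]), float(spec["b"])
            mask = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
            # Ramanujan approximation for the ellipse perimeter
            h = ((a - b) / (a + b)) ** 2
            perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
            analytic = {
                "area": np.pi * a * b,
                "perimeter": perim,
                "circularity": 4 * np.pi * (np.pi * a * b) / perim**2,
            }
        else:
            raise ValueError(f"unknown shape kind {kind!r}")
        if not mask.any():
            raise ValueError(f"shape {spec} does not cover any pixel centre")
        overlapped += int(np.count_nonzero(labels[mask]))
        labels[mask] = i
        shapes_truth.append(
            {
                "label": i,
                "spec": dict(spec),
                "analytic": analytic,
                "raster_area_px": int(mask.sum()),
            }
        )
    gt = GroundTruth(
        generator="synth_label_shapes",
        parameters={"image_size": image_size, "pixel_size": pixel_size},
        seed=seed,
        truth={"shapes": shapes_truth, "overlapping_pixels": overlapped},
    )
    return LabelImage(labels=labels, pixel_size=pixel_size), gt


def synth_coloc_pair(
    rho: float, n: int = 100_000, shape: tuple[int, ...] | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two standardized channels with population Pearson correlation ``rho``.

    Uses the correlated-mixing construction ``B = rho A + sqrt(1-rho^2) N``
    with independent standard-normal A and N.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    if shape is None:
        shape = (n,)
    a = rng.standard_normal(shape)
    b = rho * a + np.sqrt(1.0 - rho**2) * rng.standard_normal(shape)
    gt = GroundTruth(
        generator="synth_coloc_pair",
        parameters={"rho": rho, "n": int(np.prod(shape))},
        seed=seed,
        truth={"rho": rho},
    )
    return a, b, gt


def synth_sim_config(name: str, scale: str = "desk", seed: int = 0) -> dict:
    """Complete, runnable simulation config document for a named scenario.

    ``tiny`` completes in seconds (guard termination); ``desk`` is the
    replication scale.  The document round-trips through the config parser
    in :mod:`axmorph.io`.
    """
    from .scenarios import default_layout, scenario_preset

    config, J, params = scenario_preset(name, seed=seed, scale=scale)
    layout = default_layout(scale)
    mu = {CellType(t).name.lower(): float(v) for t, v in params.mu_by_type.items()}
    doc = {
        "scenario": {
            "name": config.name,
            "ppl_mobility_multiplier": config.ppl_mobility_multiplier,
            "ppl_adhesion_multiplier": config.ppl_adhesion_multiplier,
            "stop_threshold_um": config.stop_threshold_um,
            "max_mcs": config.max_mcs,
            "save_interval": config.save_interval,
            "ingression": {
                "interval": config.schedule.interval,
                "batch": config.schedule.batch,
                "enabled": config.schedule.enabled,
            },
        },
        "lattice": {
            "dims": list(layout.shape),
            "site_size_um": layout.site_size,
            "cell_side": layout.cell_side,
            "scale": scale,
        },
        "params": {
            "lambda_V": params.lambda_V,
            "lambda_S": params.lambda_S,
            "lambda_M": params.lambda_M,
            "T": params.T,
            "mu_by_type": mu,
            "neighbourhood": params.neighbourhood,
            "seed": seed,
        },
        "adhesion": {"J": J.J.tolist()},
        "potential": {"slope": 1.0, "anterior_favourable": True},
    }
    return doc
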