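"""Synthetic Lambertian scenes with exact ground truth.

The generator is the oracle for the whole pipeline: it builds height
fields with analytically known normals, instance labels and per-leaf
traits, and renders them under a directional-light rig with the same
Lambertian model the solver assumes.  Three scene families are provided:

* flat calibration targets (the tilted-plate validation protocol),
* spherical caps (closed-form oracle for curved-surface area and
  integration),
* parametric rosettes: elliptical leaf blades on narrow petioles, with
  exponential area growth and sinusoidal diel blade inclination, sampled
  every 30 minutes by default.

Only attached shadows (n . l <= 0) are modelled; no cast shadows, no
specularities.  Rasterization is centre-sampled with no anti-aliasing so
pixel counts are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .ps import PSImageSet
from .rig import CameraModel, LightModel


@dataclass
class Scene:
    """A single synthetic scene with exact ground truth.

    height (mm), normals (rows, cols, 3; unit where labels > 0), albedo
    on [0, 1], integer instance labels (0 = background), pixel scale in
    mm/px and a metadata dict of per-instance ground-truth traits.
    """

    height: np.ndarray
    normals: np.ndarray
    albedo: np.ndarray
    labels: np.ndarray
    pixel_scale: float
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.height.shape

    def foreground(self) -> np.ndarray:
        return self.labels > 0


def _pixel_grid_mm(camera: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates in mm, origin at the image centre."""
    rows, cols = camera.image_shape
    y = (np.arange(rows) - (rows - 1) / 2.0) * camera.pixel_scale
    x = (np.arange(cols) - (cols - 1) / 2.0) * camera.pixel_scale
    return np.meshgrid(x, y)


def _blank_scene(camera: CameraModel) -> Scene:
    rows, cols = camera.image_shape
    normals = np.zeros((rows, cols, 3))
    normals[..., 2] = 1.0
    return Scene(
        height=np.zeros((rows, cols)),
        normals=normals,
        albedo=np.zeros((rows, cols)),
        labels=np.zeros((rows, cols), dtype=np.int32),
        pixel_scale=camera.pixel_scale,
    )


def make_flat_target(
    area_mm2: float,
    inclination_deg: float,
    azimuth_deg: float = 0.0,
    camera: CameraModel | None = None,
    albedo: float = 0.8,
) -> Scene:
    """A square planar patch of true surface area ``area_mm2``, tilted by
    ``inclination_deg`` with its upslope direction at ``azimuth_deg``.

    The rendered footprint is foreshortened by cos(inclination); the
    constant ground-truth normal has nz = cos(inclination).
    """
    if area_mm2 <= 0:
        raise ConfigurationError("area must be positive")
    if not 0.0 <= inclination_deg < 90.0:
        raise ConfigurationError("inclination must lie in [0, 90)")
    camera = camera or CameraModel()
    theta = np.deg2rad(inclination_deg)
    phi = np.deg2rad(azimuth_deg)
    side = np.sqrt(area_mm2)
    half_u = side * np.cos(theta) / 2.0  # foreshortened along upslope
    half_v = side / 2.0
    extent = float(np.hypot(half_u, half_v))
    rows, cols = camera.image_shape
    if extent > (min(rows, cols) / 2.0 - 1.0) * camera.pixel_scale:
        raise ConfigurationError("target footprint exceeds image bounds")

    X, Y = _pixel_grid_mm(camera)
    u = X * np.cos(phi) + Y * np.sin(phi)
    v = -X * np.sin(phi) + Y * np.cos(phi)
    inside = (np.abs(u) <= half_u) & (np.abs(v) <= half_v)

    scene = _blank_scene(camera)
    scene.labels[inside] = 1
    scene.albedo[inside] = albedo
    scene.height[inside] = np.tan(theta) * u[inside]
    n = np.array([-np.sin(theta) * np.cos(phi), -np.sin(theta) * np.sin(phi), np.cos(theta)])
    scene.normals[inside] = n
    scene.meta = {
        "kind": "flat_target",
        "true_area_mm2": float(area_mm2),
        "projected_area_mm2": float(area_mm2 * np.cos(theta)),
        "inclination_deg": float(inclination_deg),
    }
    return scene


def make_sphere_cap(
    radius_mm: float,
    cap_height_mm: float,
    camera: CameraModel | None = None,
    albedo: float = 0.8,
) -> Scene:
    """Upper cap of a sphere of radius R, truncated at height h.

    Closed forms: projected footprint area pi*h*(2R - h); true cap
    surface area 2*pi*R*h.
    """
    if not 0.0 < cap_height_mm <= radius_mm:
        raise ConfigurationError("need 0 < cap_height <= radius")
    camera = camera or CameraModel()
    R, h = float(radius_mm), float(cap_height_mm)
    rc = np.sqrt(h * (2 * R - h))
    rows, cols = camera.image_shape
    if rc > (min(rows, cols) / 2.0 - 1.0) * camera.pixel_scale:
        raise ConfigurationError("cap footprint exceeds image bounds")

    X, Y = _pixel_grid_mm(camera)
    r2 = X**2 + Y**2
    inside = r2 <= rc**2
    scene = _blank_scene(camera)
    zs = np.sqrt(np.maximum(R**2 - r2, 0.0))
    scene.height[inside] = zs[inside] - (R - h)
    scene.labels[inside] = 1
    scene.albedo[inside] = albedo
    scene.normals[inside, 0] = X[inside] / R
    scene.normals[inside, 1] = Y[inside] / R
    scene.normals[inside, 2] = zs[inside] / R
    scene.meta = {
        "kind": "sphere_cap",
        "radius_mm": R,
        "cap_height_mm": h,
        "projected_area_mm2": float(np.pi * h * (2 * R - h)),
        "surface_area_mm2": float(2 * np.pi * R * h),
    }
    return scene


@dataclass
class RosetteSpec:
    """Parametric rosette: n equal-angle leaves, each an elliptic-
    paraboloid blade (convex from above) on a narrow flat petiole.

    Per-leaf blade planform area grows as A0 * exp(rate * t); blade
    nastic inclination follows baseline + amplitude * cos(2*pi*(t -
    phase)/period).  Defaults emulate a young rosette under a 12:12 h
    light:dark cycle sampled every 30 min: 24-h period, inclination
    peaking 5 h after dusk (dusk at t = 12 h), ~25% area growth per day.
    """

    n_leaves: int = 3
    leaf_azimuths_deg: Sequence[float] | None = None
    blade_semi_axes_mm: tuple[float, float] = (2.5, 1.5)
    petiole_length_mm: float = 2.5
    petiole_width_mm: float = 1.0
    inclination_baseline_deg: float = 25.0
    inclination_amplitude_deg: float = 10.0
    inclination_period_h: float = 24.0
    inclination_phase_h: float = 17.0
    area_growth_rate_per_h: float = 0.01
    dome_height_frac: float = 0.15
    albedo: float = 0.8
    sample_interval_h: float = 0.5

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ConfigurationError("n_leaves must be >= 1")
        if self.inclination_period_h <= 0:
            raise ConfigurationError("period must be positive")
        if self.inclination_amplitude_deg < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.sample_interval_h <= 0:
            raise ConfigurationError("sample_interval must be positive")
        self.blade_semi_axes_mm = tuple(self.blade_semi_axes_mm)
        if self.leaf_azimuths_deg is not None:
            self.leaf_azimuths_deg = tuple(self.leaf_azimuths_deg)
        if self.leaf_azimuths_deg is None:
            self.leaf_azimuths_deg = tuple(
                360.0 / self.n_leaves * k for k in range(self.n_leaves)
            )
        elif len(self.leaf_azimuths_deg) != self.n_leaves:
            raise ConfigurationError("one azimuth per leaf required")

    def nastic_angle_deg(self, t: float) -> float:
        """Ground-truth blade inclination (deg) at time t (hours)."""
        return self.inclination_baseline_deg + self.inclination_amplitude_deg * np.cos(
            2 * np.pi * (t - self.inclination_phase_h) / self.inclination_period_h
        )


def _render_leaf(
    scene: Scene,
    X: np.ndarray,
    Y: np.ndarray,
    label: int,
    azimuth_deg: float,
    a: float,
    b: float,
    petiole_len: float,
    petiole_width: float,
    beta_deg: float,
    dome_frac: float,
    albedo: float,
) -> None:
    """Rasterize one leaf into the scene buffers, keeping the higher
    surface where leaves overlap."""
    phi = np.deg2rad(azimuth_deg)
    beta = np.deg2rad(np.clip(beta_deg, 0.0, 85.0))
    cosb, sinb, tanb = np.cos(beta), np.sin(beta), np.tan(beta)
    u = X * np.cos(phi) + Y * np.sin(phi)
    v = -X * np.sin(phi) + Y * np.cos(phi)

    r_base = petiole_len
    # blade footprint: in-plane ellipse (semi-axes a along leaf, b across)
    # foreshortened along the leaf direction by cos(beta)
    uc = r_base + a * cosb
    blade = ((u - uc) / (a * cosb)) ** 2 + (v / b) ** 2 <= 1.0
    petiole = (np.abs(v) <= petiole_width / 2.0) & (u >= 0.0) & (u < r_base)

    # heights and analytic gradients on the blade
    up = np.where(blade, (u - r_base) / cosb, 0.0)  # in-plane coordinate
    h_d = dome_frac * b
    dome = h_d * (1.0 - ((up - a) / a) ** 2 - (v / b) ** 2)
    z_blade = (u - r_base) * tanb + np.maximum(dome, 0.0)
    ddome_dup = -2.0 * h_d * (up - a) / a**2
    ddome_dv = -2.0 * h_d * v / b**2
    dz_du = tanb + ddome_dup / cosb
    dz_dv = ddome_dv
    px = dz_du * np.cos(phi) - dz_dv * np.sin(phi)
    py = dz_du * np.sin(phi) + dz_dv * np.cos(phi)
    norm = np.sqrt(1.0 + px**2 + py**2)

    for region, z_new in ((petiole, np.zeros_like(u)), (blade, z_blade)):
        take = region & ((scene.labels == 0) | (z_new >= scene.height))
        scene.labels[take] = label
        scene.albedo[take] = albedo
        scene.height[take] = z_new[take]
        if region is blade:
            scene.normals[take, 0] = -px[take] / norm[take]
            scene.normals[take, 1] = -py[take] / norm[take]
            scene.normals[take, 2] = 1.0 / norm[take]
        else:
            scene.normals[take] = (0.0, 0.0, 1.0)


def make_rosette_series(
    spec: RosetteSpec,
    times: Sequence[float],
    camera: CameraModel | None = None,
) -> list[Scene]:
    """One ground-truth Scene per time point (hours).

    Leaf k carries the stable label k+1 in every frame.  Scene.meta
    records, per leaf: planform blade area (A0 * exp(rate*t) closed
    form), numerically exact 3D surface area from the analytic normals,
    the nastic inclination, and visibility; a fully occluded leaf adds a
    warning record.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ConfigurationError("times must be strictly increasing")
    camera = camera or CameraModel()
    X, Y = _pixel_grid_mm(camera)
    a0, b0 = spec.blade_semi_axes_mm
    scenes: list[Scene] = []
    for t in times:
        g = float(np.exp(spec.area_growth_rate_per_h * t / 2.0))
        beta = spec.nastic_angle_deg(t)
        scene = _blank_scene(camera)
        for k, az in enumerate(spec.leaf_azimuths_deg):
            _render_leaf(
                scene,
                X,
                Y,
                label=k + 1,
                azimuth_deg=az,
                a=a0 * g,
                b=b0 * g,
                petiole_len=spec.petiole_length_mm * g,
                petiole_width=spec.petiole_width_mm,
                beta_deg=beta,
                dome_frac=spec.dome_height_frac,
                albedo=spec.albedo,
            )
        leaves = []
        warnings_rec = []
        border = np.zeros(scene.labels.shape, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        if (scene.labels[border] > 0).any():
            warnings_rec.append(f"rosette touches the image border at t={t:g} h")
        px_area = camera.pixel_scale**2
        for k in range(spec.n_leaves):
            sel = scene.labels == k + 1
            visible = int(sel.sum())
            if visible == 0:
                warnings_rec.append(f"leaf {k + 1} fully occluded at t={t:g} h")
            nz = scene.normals[sel, 2]
            surf = float(np.sum(px_area / np.maximum(nz, 1e-6))) if visible else 0.0
            leaves.append(
                {
                    "label": k + 1,
                    "planform_area_mm2": float(np.pi * a0 * b0 * g**2),
                    "surface_area_mm2": surf,
                    "nastic_deg": float(np.clip(beta, 0.0, 85.0)),
                    "visible_px": visible,
                }
            )
        scene.meta = {
            "kind": "rosette",
            "time_h": float(t),
            "origin_px": ((camera.image_shape[0] - 1) / 2.0, (camera.image_shape[1] - 1) / 2.0),
            "leaves": leaves,
            "warnings": warnings_rec,
        }
        scenes.append(scene)
    return scenes


def render_ps(
    scene: Scene,
    rig: LightModel,
    noise_sd: float = 0.01,
    seed: int = 0,
    camera: CameraModel | None = None,
) -> PSImageSet:
    """Render a scene under each rig light with the Lambertian model.

    Per light j: I = g_j * rho * max(0, n . l_j), plus seeded Gaussian
    noise of standard deviation ``noise_sd`` (fraction of full scale)
    when nonzero.  Background and attached shadows render as 0; output is
    clipped to [0, 1 + 5 * noise_sd].
    """
    if not 0.0 <= noise_sd < 1.0:
        raise ConfigurationError("noise_sd must lie in [0, 1)")
    camera = camera or CameraModel(
        image_shape=scene.shape, pixel_scale=scene.pixel_scale
    )
    if camera.image_shape != scene.shape:
        raise ConfigurationError("camera.image_shape must match the scene")
    n = scene.normals.reshape(-1, 3)
    shading = np.maximum(n @ rig.matrix.T, 0.0)  # (P, n_lights)
    imgs = (
        rig.intensities[None, :] * scene.albedo.reshape(-1, 1) * shading
    ).T.reshape(rig.n_lights, *scene.shape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        imgs = imgs + rng.normal(0.0, noise_sd, imgs.shape)
    imgs = np.clip(imgs, 0.0, 1.0 + 5.0 * noise_sd)
    return PSImageSet(
        images=imgs, rig=rig, camera=camera, foreground_mask=scene.foreground()
    )
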