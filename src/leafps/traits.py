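"""Rosette- and leaf-level growth traits from masks and normal maps.

2D traits come straight from the binary mask (projected area, shape
descriptors).  3D traits rescale each pixel by 1/nz using the solved
surface normals, which corrects the cosine foreshortening of tilted
surfaces: a pixel viewed at surface inclination theta covers
pixel_scale^2 / cos(theta) of actual surface.  Inclination statistics use
the solved normals directly (never the integrated depth map).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import shapely
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPoint
from skimage import measure

from .exceptions import ConfigurationError
from .ps import NormalMap
from .rig import CameraModel
from .schedule import LightSchedule

NZ_MIN = 0.05  # clamp floor bounding the 1/nz correction near silhouettes


def projected_area_2d(mask: np.ndarray, camera: CameraModel) -> float:
    """Projected (top-down) area: foreground pixel count x pixel_scale^2, mm^2."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) * camera.pixel_scale**2


@dataclass
class Area3D:
    """3D-corrected area with bookkeeping of unsolved pixels."""

    area_mm2: float
    invalid_fraction: float
    warning: str | None = None

    def __float__(self) -> float:
        return self.area_mm2


def projected_area_3d(
    mask: np.ndarray,
    nm: NormalMap,
    camera: CameraModel,
    nz_min: float = NZ_MIN,
) -> Area3D:
    """Surface area over the mask: sum of pixel_scale^2 / max(nz, nz_min).

    Pixels without a valid normal fall back to the flat contribution
    (pixel_scale^2) and are counted in ``invalid_fraction``; above 50% a
    warning record is attached.
    """
    mask = np.asarray(mask, dtype=bool)
    px = camera.pixel_scale**2
    n_fg = int(mask.sum())
    if n_fg == 0:
        return Area3D(0.0, 0.0)
    ok = mask & nm.valid
    nz = np.maximum(nm.nz[ok], nz_min)
    area = float(np.sum(px / nz)) + px * (n_fg - int(ok.sum()))
    frac = 1.0 - int(ok.sum()) / n_fg
    warning = None
    if frac > 0.5:
        warning = f"{frac:.0%} of foreground pixels lack a valid normal"
        warnings.warn(warning)
    return Area3D(area, frac, warning)


def inclination_stats(
    mask: np.ndarray, nm: NormalMap
) -> tuple[np.ndarray, float]:
    """Per-pixel surface inclination arccos(nz) in degrees and its mean
    over the valid foreground.  The map is NaN outside mask & valid."""
    mask = np.asarray(mask, dtype=bool)
    ok = mask & nm.valid
    if not ok.any():
        raise ConfigurationError("no valid foreground pixels")
    inc = np.full(mask.shape, np.nan)
    inc[ok] = np.degrees(np.arccos(np.clip(nm.nz[ok], -1.0, 1.0)))
    return inc, float(np.nanmean(inc[ok]))


def convexity_map(nm: NormalMap, sigma: float = 2.0) -> np.ndarray:
    """Signed surface-curvature proxy from the projected normal field.

    Computed as the negated divergence of (nx, ny), optionally smoothed
    by a Gaussian of width ``sigma`` px: negative over convex (domed)
    surfaces, positive over concave ones, ~0 on planes.
    """
    nx, ny = nm.nx.astype(float), nm.ny.astype(float)
    if sigma > 0:
        nx = ndi.gaussian_filter(nx, sigma)
        ny = ndi.gaussian_filter(ny, sigma)
    div = np.gradient(nx, axis=1) + np.gradient(ny, axis=0)
    out = -div
    out[~nm.valid] = 0.0
    return out


@dataclass
class ShapeDescriptors:
    circularity: float
    compactness: float
    diameter_mm: float
    perimeter_mm: float


def shape_descriptors(mask: np.ndarray, camera: CameraModel) -> ShapeDescriptors:
    """2D rosette shape descriptors on the filled foreground union.

    circularity = 4*pi*A/P^2 (1 for a disc); compactness = A / convex
    hull area; diameter = minimum enclosing circle diameter; perimeter =
    marching-squares contour length.  Hull and enclosing circle are taken
    over pixel corners so square footprints measure their full extent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("empty mask")
    filled = ndi.binary_fill_holes(mask)
    scale = camera.pixel_scale
    area = float(filled.sum()) * scale**2

    # marching-squares outline, simplified to remove the half-pixel
    # staircase that would otherwise overestimate smooth boundaries
    contours = measure.find_contours(filled.astype(float), 0.5)
    perimeter = sum(
        float(
            np.sum(
                np.linalg.norm(
                    np.diff(measure.approximate_polygon(c, 1.0), axis=0), axis=1
                )
            )
        )
        for c in contours
    ) * scale

    boundary = filled & ~ndi.binary_erosion(filled)
    rr, cc = np.nonzero(boundary)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (np.column_stack([rr, cc])[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    hull = ConvexHull(corners)
    compactness = float(filled.sum()) / hull.volume  # 2D hull "volume" is area
    radius = shapely.minimum_bounding_radius(MultiPoint(corners[hull.vertices]))
    return ShapeDescriptors(
        circularity=float(4 * np.pi * area / perimeter**2),
        compactness=float(compactness),
        diameter_mm=float(2 * radius * scale),
        perimeter_mm=float(perimeter),
    )


@dataclass
class RERResult:
    """Relative expansion rate over sliding windows.

    ``table`` has one row per window start: t_start, t_end, rer (1/h) and
    phase ('light' / 'dark' / 'transition'); windows spanning a light
    transition are excluded from the per-phase means.
    """

    table: pd.DataFrame
    light_mean: float
    dark_mean: float


def relative_expansion_rate(
    times: np.ndarray,
    areas: np.ndarray,
    window_h: float = 4.0,
    schedule: LightSchedule | None = None,
) -> RERResult:
    """RER(t) = (ln A(t+w) - ln A(t)) / w over a sliding window.

    ``times`` must be uniformly sampled; the window must span an integer
    number of sampling steps.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(areas, dtype=float)
    if t.size != a.size or t.size < 2:
        raise ConfigurationError("times and areas must align, length >= 2")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt):
        raise ConfigurationError("times must be uniformly sampled")
    steps = int(round(window_h / dt))
    if steps < 1 or t.size <= steps:
        raise ConfigurationError("series shorter than the RER window")
    if np.any(a <= 0):
        raise ConfigurationError("areas must be positive for log growth rates")
    w = steps * dt
    rer = (np.log(a[steps:]) - np.log(a[:-steps])) / w
    t0 = t[:-steps]
    t1 = t[steps:]
    if schedule is None:
        phase = np.array(["unscheduled"] * rer.size)
    else:
        phase = np.array([schedule.phase_of_interval(x0, x1) for x0, x1 in zip(t0, t1)])
    table = pd.DataFrame({"t_start": t0, "t_end": t1, "rer": rer, "phase": phase})
    light = table.loc[table.phase == "light", "rer"]
    dark = table.loc[table.phase == "dark", "rer"]
    return RERResult(
        table=table,
        light_mean=float(light.mean()) if len(light) else float("nan"),
        dark_mean=float(dark.mean()) if len(dark) else float("nan"),
    )


def rosette_trait_record(
    time_h: float,
    mask: np.ndarray,
    nm: NormalMap,
    camera: CameraModel,
) -> dict:
    """One row of the rosette trait table at a single time point."""
    a2 = projected_area_2d(mask, camera)
    a3 = projected_area_3d(mask, nm, camera)
    _, mean_inc = inclination_stats(mask, nm)
    shapes = shape_descriptors(mask, camera)
    conv = convexity_map(nm)
    fg = np.asarray(mask, dtype=bool) & nm.valid
    return {
        "time_h": float(time_h),
        "pra_2d_mm2": a2,
        "pra_3d_mm2": a3.area_mm2,
        "invalid_fraction": a3.invalid_fraction,
        "pct_diff_3d_2d": 100.0 * (a3.area_mm2 - a2) / a3.area_mm2 if a3.area_mm2 else 0.0,
        "mean_inclination_deg": mean_inc,
        "convexity_mean": float(conv[fg].mean()) if fg.any() else 0.0,
        "circularity": shapes.circularity,
        "compactness": shapes.compactness,
        "diameter_mm": shapes.diameter_mm,
        "perimeter_mm": shapes.perimeter_mm,
    }
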