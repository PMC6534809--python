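"""Imaging-rig geometry: directional lights and camera scale.

The rig is a ring of near-infrared LEDs around a downward-looking camera.
Lights are modelled as distant directional sources: each one is a unit
vector pointing from the scene toward the light, expressed in the camera
frame (x right, y down along image rows, z toward the camera).  A surface
facing the camera has normal (0, 0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError

#: default field of view: 170 mm across 2048 pixels
DEFAULT_PIXEL_SCALE_MM = 170.0 / 2048.0


@dataclass(frozen=True)
class CameraModel:
    """Orthographic top-down camera described by its ground sampling distance.

    Parameters
    ----------
    pixel_scale : float
        Millimetres per pixel on the imaging plane (default ~0.083 mm/px,
        a 17 x 17 cm field of view at 2048 x 2048 pixels).
    image_shape : tuple of int
        (rows, cols) of the captured frames.
    """

    pixel_scale: float = DEFAULT_PIXEL_SCALE_MM
    image_shape: tuple[int, int] = (2048, 2048)

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be positive")
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise ConfigurationError("image_shape must be (rows, cols) >= 1")


@dataclass(frozen=True)
class LightModel:
    """A set of distant directional lights.

    ``directions`` is an (n, 3) array of unit vectors pointing from the
    scene toward each light; ``intensities`` holds per-light relative
    scalar gains (dimensionless, default 1).
    """

    directions: np.ndarray
    intensities: np.ndarray = None  # type: ignore[assignment]
    tilt_deg: float | None = None
    azimuths_deg: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ConfigurationError("directions must be an (n, 3) array")
        if d.shape[0] < 3:
            raise ConfigurationError(
                f"photometric stereo needs >= 3 lights, got {d.shape[0]}"
            )
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ConfigurationError("light directions must be unit vectors")
        if np.linalg.matrix_rank(d, tol=1e-9) < 3:
            raise ConfigurationError("light directions are coplanar (rank < 3)")
        object.__setattr__(self, "directions", d)
        ints = self.intensities
        if ints is None:
            ints = np.ones(d.shape[0])
        ints = np.asarray(ints, dtype=float)
        if ints.shape != (d.shape[0],) or np.any(ints <= 0):
            raise ConfigurationError("intensities must be positive, one per light")
        object.__setattr__(self, "intensities", ints)

    @property
    def n_lights(self) -> int:
        return self.directions.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """The (n, 3) light-direction matrix used by the solver."""
        return self.directions

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.directions))


def build_rig(
    n_lights: int,
    tilt_deg: float,
    azimuth_start_deg: float = 0.0,
    intensities=None,
) -> LightModel:
    """Build a symmetric ring of lights.

    Lights sit at equal azimuth spacing (360/n degrees) starting at
    ``azimuth_start_deg``, each inclined ``tilt_deg`` away from the optical
    axis.  The default hardware geometry is 8 lights at 45-degree azimuth
    increments, tilted 30 degrees.

    Returns a :class:`LightModel` whose vectors have z-component
    cos(tilt_deg).
    """
    if n_lights < 3:
        raise ConfigurationError("n_lights must be >= 3")
    if not 0.0 < tilt_deg < 90.0:
        raise ConfigurationError("tilt_deg must lie in (0, 90)")
    tilt = np.deg2rad(tilt_deg)
    az = azimuth_start_deg + 360.0 / n_lights * np.arange(n_lights)
    phi = np.deg2rad(az)
    directions = np.column_stack(
        [
            np.sin(tilt) * np.cos(phi),
            np.sin(tilt) * np.sin(phi),
            np.full(n_lights, np.cos(tilt)),
        ]
    )
    return LightModel(
        directions,
        intensities,
        tilt_deg=float(tilt_deg),
        azimuths_deg=tuple(float(a % 360.0) for a in az),
    )


def save_rig(path, rig: LightModel, camera: CameraModel) -> None:
    """Serialize the rig + camera geometry to a JSON description."""
    payload = {
        "n_lights": rig.n_lights,
        "tilt_deg": rig.tilt_deg,
        "azimuths_deg": list(rig.azimuths_deg) if rig.azimuths_deg else None,
        "directions": rig.directions.tolist(),
        "intensities": rig.intensities.tolist(),
        "pixel_scale_mm": camera.pixel_scale,
        "image_shape": list(camera.image_shape),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rig(path) -> tuple[LightModel, CameraModel]:
    payload = json.loads(Path(path).read_text())
    if payload.get("tilt_deg") is not None and payload.get("azimuths_deg"):
        tilt = np.deg2rad(payload["tilt_deg"])
        phi = np.deg2rad(np.asarray(payload["azimuths_deg"], dtype=float))
        directions = np.column_stack(
            [
                np.sin(tilt) * np.cos(phi),
                np.sin(tilt) * np.sin(phi),
                np.full(phi.size, np.cos(tilt)),
            ]
        )
        rig = LightModel(
            directions,
            payload.get("intensities"),
            tilt_deg=payload["tilt_deg"],
            azimuths_deg=tuple(payload["azimuths_deg"]),
        )
    else:
        rig = LightModel(
            np.asarray(payload["directions"], dtype=float),
            payload.get("intensities"),
        )
    camera = CameraModel(
        pixel_scale=payload["pixel_scale_mm"],
        image_shape=tuple(payload["image_shape"]),
    )
    return rig, camera
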