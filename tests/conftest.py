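import numpy as np
import pytest

import leafps as lp


@pytest.fixture(scope="session")
def rig8():
    """The standard 8-light ring tilted 30 degrees."""
    return lp.build_rig(8, 30)


@pytest.fixture(scope="session")
def validation_camera():
    """Camera used for flat-target validation: default mm/px on a frame
    large enough for the 600 mm^2 target, odd-sized so the target centres
    on a pixel."""
    return lp.CameraModel(pixel_scale=170.0 / 2048.0, image_shape=(449, 449))


@pytest.fixture(scope="session")
def unit_camera():
    """1 mm/px camera for closed-form geometry oracles."""
    return lp.CameraModel(pixel_scale=1.0, image_shape=(129, 129))


@pytest.fixture(scope="session")
def flat_sweep(rig8, validation_camera):
    """Render + solve the 0-45 degree flat-target sweep once (noise-free)."""
    out = []
    for deg in range(0, 50, 5):
        scene = lp.make_flat_target(600.0, deg, 0.0, validation_camera)
        imgs = lp.render_ps(scene, rig8, noise_sd=0.0, seed=0, camera=validation_camera)
        nm = lp.solve_normals(imgs)
        out.append((deg, scene, nm))
    return out


@pytest.fixture(scope="session")
def rosette_scene_nm(rig8):
    """One rendered + solved rosette frame with its ground-truth scene."""
    camera = lp.CameraModel(pixel_scale=0.2, image_shape=(161, 161))
    scene = lp.make_rosette_series(lp.RosetteSpec(), [24.0], camera)[0]
    imgs = lp.render_ps(scene, rig8, noise_sd=0.0, seed=0, camera=camera)
    return camera, scene, lp.solve_normals(imgs)


def angular_error_deg(nm, scene):
    """Per-pixel angle between solved and ground-truth normals, on the
    valid lit foreground."""
    sel = nm.valid & (scene.labels > 0)
    dots = np.clip(np.sum(nm.normals[sel] * scene.normals[sel], axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(dots))
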