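"""Blade/petiole separation, leaf landmarks and per-leaf traits.

A leaf mask is split by morphological opening with a disc: the opening
removes the narrow petiole, whose width is below twice the disc radius,
and keeps the blade.  Landmarks are the rosette origin P_O, the blade-
petiole intersection P_B and the leaf tip P_T; blade and petiole lengths
are the straight chords P_B-P_T and P_O-P_B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import draw, morphology

from .exceptions import ConfigurationError
from .ps import NormalMap
from .rig import CameraModel


def auto_opening_radius(leaf_area_px: int) -> int:
    """Disc radius for blade/petiole opening, scaled with leaf size and
    clipped to the working range 3-11 px."""
    return int(np.clip(round(0.3 * np.sqrt(leaf_area_px) / 2.0), 3, 11))


def split_blade_petiole(
    leaf_mask: np.ndarray, radius_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split a leaf mask into (blade, petiole) by opening with a disc.

    The blade is the largest connected component of the opening; the
    petiole is the remainder (possibly empty).  Blade and petiole
    partition the leaf mask exactly.
    """
    leaf_mask = np.asarray(leaf_mask, dtype=bool)
    if not leaf_mask.any():
        raise ConfigurationError("empty leaf mask")
    if not 3 <= radius_px <= 11:
        warnings.warn(f"opening radius {radius_px} outside the usual 3-11 px range")
    opened = morphology.opening(leaf_mask, morphology.disk(radius_px))
    if not opened.any():
        raise ConfigurationError("radius too large for leaf: opening is empty")
    lab, n = ndi.label(opened)
    if n > 1:
        sizes = ndi.sum_labels(opened, lab, index=np.arange(1, n + 1))
        blade = lab == (1 + int(np.argmax(sizes)))
    else:
        blade = opened
    petiole = leaf_mask & ~blade
    return blade, petiole


@dataclass
class LeafLandmarks:
    """(row, col) pixel coordinates of the three leaf landmarks."""

    P_O: tuple[float, float]  # rosette origin
    P_B: tuple[float, float]  # blade-petiole intersection
    P_T: tuple[float, float]  # leaf tip
    petiole_empty: bool = False


def leaf_landmarks(
    blade_mask: np.ndarray,
    petiole_mask: np.ndarray,
    P_O: tuple[float, float],
    min_petiole_px: int = 5,
) -> LeafLandmarks:
    """Locate P_B and P_T given the blade/petiole split and origin.

    P_B is the centroid of the contact band (blade and petiole pixels
    within 1 px of each other), computed against the petiole's largest
    connected component so that isolated rasterization specks left by
    the opening cannot bias it; when the petiole is empty it falls back
    to the blade boundary pixel nearest P_O.  P_T is the blade pixel
    farthest from P_O (deterministic tie-break: scan order).
    """
    blade_mask = np.asarray(blade_mask, dtype=bool)
    petiole_mask = np.asarray(petiole_mask, dtype=bool)
    if not blade_mask.any():
        raise ConfigurationError("empty blade mask")
    origin = np.asarray(P_O, dtype=float)

    pet_main = np.zeros_like(petiole_mask)
    if petiole_mask.any():
        lab, n = ndi.label(petiole_mask)
        sizes = ndi.sum_labels(petiole_mask, lab, index=np.arange(1, n + 1))
        pet_main = lab == (1 + int(np.argmax(sizes)))
    # a petiole whose largest connected piece is a few isolated pixels is
    # just opening residue, not an organ
    petiole_empty = int(pet_main.sum()) < min_petiole_px
    if petiole_empty:
        boundary = blade_mask & ~ndi.binary_erosion(blade_mask)
        pts = np.argwhere(boundary)
        d = np.linalg.norm(pts - origin, axis=1)
        pb = pts[int(np.argmin(d))].astype(float)
    else:
        near_blade = ndi.binary_dilation(blade_mask)
        near_pet = ndi.binary_dilation(pet_main)
        band = (blade_mask & near_pet) | (pet_main & near_blade)
        pts = np.argwhere(band)
        pb = pts.mean(axis=0)

    pts = np.argwhere(blade_mask)
    d = np.linalg.norm(pts - origin, axis=1)
    pt = pts[int(np.argmax(d))].astype(float)
    return LeafLandmarks(
        P_O=(float(origin[0]), float(origin[1])),
        P_B=(float(pb[0]), float(pb[1])),
        P_T=(float(pt[0]), float(pt[1])),
        petiole_empty=petiole_empty,
    )


def blade_inclination(
    nm: NormalMap,
    blade_mask: np.ndarray,
    landmarks: LeafLandmarks | None = None,
    method: str = "mean",
) -> float:
    """Blade inclination in degrees.

    ``method='mean'`` averages arccos(nz) over the valid blade;
    ``method='line'`` averages along the rasterized P_B -> P_T segment
    (falling back to 'mean' with a warning when the landmarks are
    degenerate or the segment has no valid pixels).
    """
    blade_mask = np.asarray(blade_mask, dtype=bool)
    inc = nm.inclination_deg()
    ok = blade_mask & nm.valid
    if not ok.any():
        raise ConfigurationError("no valid pixels on the blade")
    if method == "mean":
        return float(inc[ok].mean())
    if method != "line":
        raise ConfigurationError("method must be 'line' or 'mean'")
    if landmarks is None:
        raise ConfigurationError("line method requires landmarks")
    pb = np.round(landmarks.P_B).astype(int)
    pt = np.round(landmarks.P_T).astype(int)
    if np.all(pb == pt):
        warnings.warn("degenerate landmarks; falling back to blade mean")
        return float(inc[ok].mean())
    rr, cc = draw.line(pb[0], pb[1], pt[0], pt[1])
    keep = (
        (rr >= 0)
        & (rr < ok.shape[0])
        & (cc >= 0)
        & (cc < ok.shape[1])
    )
    rr, cc = rr[keep], cc[keep]
    on = ok[rr, cc]
    if not on.any():
        warnings.warn("P_B-P_T line misses the valid blade; falling back to mean")
        return float(inc[ok].mean())
    return float(inc[rr[on], cc[on]].mean())


@dataclass
class BladePetioleLengths:
    blade_length_mm: float
    petiole_length_mm: float
    ratio: float  # NaN when the petiole is empty / zero-length
    ratio_defined: bool


def blade_petiole_lengths(
    landmarks: LeafLandmarks, camera: CameraModel
) -> BladePetioleLengths:
    """Chord lengths |P_B - P_T| and |P_O - P_B| in mm and their ratio."""
    po = np.asarray(landmarks.P_O)
    pb = np.asarray(landmarks.P_B)
    pt = np.asarray(landmarks.P_T)
    blade = float(np.linalg.norm(pt - pb)) * camera.pixel_scale
    petiole = float(np.linalg.norm(pb - po)) * camera.pixel_scale
    if landmarks.petiole_empty or petiole == 0.0:
        return BladePetioleLengths(blade, 0.0 if landmarks.petiole_empty else petiole,
                                   float("nan"), False)
    return BladePetioleLengths(blade, petiole, blade / petiole, True)


def leaf_record(
    leaf_id: int,
    leaf_mask: np.ndarray,
    nm: NormalMap,
    camera: CameraModel,
    P_O: tuple[float, float],
    radius_px: int | None = None,
) -> dict:
    """Full per-leaf trait row: blade area/inclination, landmark chords."""
    leaf_mask = np.asarray(leaf_mask, dtype=bool)
    if radius_px is None:
        radius_px = auto_opening_radius(int(leaf_mask.sum()))
    blade, petiole = split_blade_petiole(leaf_mask, radius_px)
    lm = leaf_landmarks(blade, petiole, P_O)
    lengths = blade_petiole_lengths(lm, camera)
    from .traits import projected_area_3d

    area = projected_area_3d(blade, nm, camera)
    return {
        "leaf_id": leaf_id,
        "blade_area_mm2": area.area_mm2,
        "blade_mean_inclination_deg": blade_inclination(nm, blade, lm, "mean"),
        "blade_length_mm": lengths.blade_length_mm,
        "petiole_length_mm": lengths.petiole_length_mm,
        "blade_petiole_ratio": lengths.ratio,
        "ratio_defined": lengths.ratio_defined,
        "pb_row": lm.P_B[0],
        "pb_col": lm.P_B[1],
        "pt_row": lm.P_T[0],
        "pt_col": lm.P_T[1],
    }
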