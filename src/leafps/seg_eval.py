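"""Instance-segmentation scoring: symmetric best dice and
foreground-background dice.

SBD scores leaf-instance agreement: for each instance in one labelling,
take the best dice overlap with any instance of the other; average;
SBD is the minimum of the two directions.  FBD scores whole-rosette
segmentation: the dice of the two binarized foregrounds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|a&b| / (|a|+|b|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ConfigurationError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _dice_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise dice between all instances of two label maps."""
    xi = np.unique(x)
    xi = xi[xi > 0]
    yi = np.unique(y)
    yi = yi[yi > 0]
    # joint histogram of label pairs
    xmap = np.searchsorted(xi, x.ravel())
    ymap = np.searchsorted(yi, y.ravel())
    both = (x.ravel() > 0) & (y.ravel() > 0)
    inter = np.zeros((xi.size, yi.size))
    if both.any():
        flat = xmap[both] * yi.size + ymap[both]
        counts = np.bincount(flat, minlength=xi.size * yi.size)
        inter = counts.reshape(xi.size, yi.size).astype(float)
    sx = np.array([(x == v).sum() for v in xi], dtype=float)
    sy = np.array([(y == v).sum() for v in yi], dtype=float)
    dmat = 2.0 * inter / (sx[:, None] + sy[None, :])
    return dmat, xi, yi


def best_dice(x: np.ndarray, y: np.ndarray) -> float:
    """BD(x -> y): mean over instances of x of the best dice with any
    instance of y."""
    dmat, xi, _ = _dice_matrix(np.asarray(x), np.asarray(y))
    if xi.size == 0:
        raise ConfigurationError("label map has no instances")
    return float(dmat.max(axis=1).mean()) if dmat.size else 0.0


def sbd(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Symmetric best dice: min(BD(pred -> truth), BD(truth -> pred))."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ConfigurationError("mask shapes differ")
    if not (predicted > 0).any() or not (truth > 0).any():
        raise ConfigurationError("both label maps need at least one instance")
    return min(best_dice(predicted, truth), best_dice(truth, predicted))


def fbd(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Foreground-background dice of the binarized foregrounds."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    return dice(predicted > 0, truth > 0)


def evaluate_series(predicted_series, truth_series) -> pd.DataFrame:
    """Per-frame SBD/FBD table with an unweighted 'mean' summary row."""
    rows = []
    for i, (p, t) in enumerate(zip(predicted_series, truth_series)):
        rows.append({"frame": i, "sbd": sbd(p, t), "fbd": fbd(p, t)})
    df = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [{"frame": -1, "sbd": df.sbd.mean(), "fbd": df.fbd.mean()}]
    )
    return pd.concat([df, summary], ignore_index=True)
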