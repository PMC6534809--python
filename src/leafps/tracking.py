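"""Leaf-instance tracking across a labelled mask time series.

Per-frame instance labels are arbitrary; the tracker links them into
persistent identities using constant-velocity prediction of each
instance's centroid with nearest-neighbour gating.  Four parameters
control it, matching the scheme's field convention: ``span`` (number of
recent steps averaged into the velocity), ``search_radius`` (largest
allowed prediction-to-observation distance in pixels), ``frame_memory``
(frames an unseen track survives) and ``min_track_length`` (minimum
total frames a track must be seen to be kept).  Default values
10 / 30 / 3 / 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import linear_sum_assignment

from .exceptions import ConfigurationError


@dataclass
class TrackerConfig:
    span: int = 10
    search_radius: float = 30.0
    frame_memory: int = 3
    min_track_length: int = 100
    assignment: str = "greedy"  # or "optimal" (global assignment per frame)

    def __post_init__(self) -> None:
        if self.span < 0 or self.frame_memory < 0 or self.min_track_length < 0:
            raise ConfigurationError("tracker parameters must be >= 0")
        if self.search_radius <= 0:
            raise ConfigurationError("search_radius must be positive")
        if self.assignment not in ("greedy", "optimal"):
            raise ConfigurationError("assignment must be 'greedy' or 'optimal'")


@dataclass
class Track:
    """One persistent leaf identity.

    Parallel lists give, per observation: frame index, centroid (row,
    col) in px, the source label in that frame's mask, and the surface
    height at the centroid (mm, NaN when no depth supplied)."""

    leaf_id: int
    frames: list[int] = field(default_factory=list)
    rows: list[float] = field(default_factory=list)
    cols: list[float] = field(default_factory=list)
    source_labels: list[int] = field(default_factory=list)
    z_mm: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def last_position(self) -> np.ndarray:
        return np.array([self.rows[-1], self.cols[-1]])

    def predict(self, frame: int, span: int) -> np.ndarray:
        """Constant-velocity extrapolation to ``frame``: last centroid
        plus the mean per-frame velocity over up to ``span`` recent
        steps."""
        pos = self.last_position()
        if len(self.frames) < 2 or span == 0:
            return pos
        k = min(span, len(self.frames) - 1)
        f0, f1 = self.frames[-1 - k], self.frames[-1]
        p0 = np.array([self.rows[-1 - k], self.cols[-1 - k]])
        v = (pos - p0) / (f1 - f0)
        return pos + v * (frame - self.frames[-1])


def _frame_centroids(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return ids, np.empty((0, 2))
    cents = np.array(ndi.center_of_mass(labels > 0, labels, ids), dtype=float)
    return ids, cents


def track_instances(
    series: Sequence[np.ndarray],
    cfg: TrackerConfig | None = None,
    depths: Sequence | None = None,
) -> list[Track]:
    """Link per-frame instances into persistent tracks.

    Deterministic: candidate pairs are matched greedily by increasing
    distance (ties broken by smaller track id, then smaller label) within
    ``search_radius``; ``assignment='optimal'`` replaces the greedy pass
    with a globally optimal assignment under the same gate.  Unmatched
    observations open new tracks; tracks unseen for more than
    ``frame_memory`` frames are closed; tracks seen in fewer than
    ``min_track_length`` frames are discarded at the end.
    """
    cfg = cfg or TrackerConfig()
    if len(series) < 2:
        raise ConfigurationError("need at least 2 frames to track")
    live: list[Track] = []
    done: list[Track] = []
    next_id = 1
    for frame, labels in enumerate(series):
        ids, cents = _frame_centroids(np.asarray(labels))
        matches: list[tuple[int, int]] = []  # (track index in live, obs index)
        if live and ids.size:
            preds = np.array([trk.predict(frame, cfg.span) for trk in live])
            dist = np.linalg.norm(preds[:, None, :] - cents[None, :, :], axis=2)
            if cfg.assignment == "greedy":
                order = sorted(
                    (
                        (dist[i, j], live[i].leaf_id, int(ids[j]), i, j)
                        for i in range(len(live))
                        for j in range(ids.size)
                        if dist[i, j] <= cfg.search_radius
                    )
                )
                used_t: set[int] = set()
                used_o: set[int] = set()
                for d, _, _, i, j in order:
                    if i in used_t or j in used_o:
                        continue
                    used_t.add(i)
                    used_o.add(j)
                    matches.append((i, j))
            else:
                big = cfg.search_radius * 1e6
                cost = np.where(dist <= cfg.search_radius, dist, big)
                ri, ci = linear_sum_assignment(cost)
                matches = [
                    (int(i), int(j))
                    for i, j in zip(ri, ci)
                    if dist[i, j] <= cfg.search_radius
                ]
        matched_tracks = {i for i, _ in matches}
        matched_obs = {j for _, j in matches}
        for i, j in matches:
            trk = live[i]
            trk.frames.append(frame)
            trk.rows.append(float(cents[j, 0]))
            trk.cols.append(float(cents[j, 1]))
            trk.source_labels.append(int(ids[j]))
            trk.z_mm.append(_depth_at(depths, frame, cents[j]))
        for j in range(ids.size):
            if j in matched_obs:
                continue
            trk = Track(leaf_id=next_id)
            next_id += 1
            trk.frames.append(frame)
            trk.rows.append(float(cents[j, 0]))
            trk.cols.append(float(cents[j, 1]))
            trk.source_labels.append(int(ids[j]))
            trk.z_mm.append(_depth_at(depths, frame, cents[j]))
            live.append(trk)
        still_live = []
        for trk in live:
            if frame - trk.frames[-1] > cfg.frame_memory:
                done.append(trk)
            else:
                still_live.append(trk)
        live = still_live
    done.extend(live)
    kept = [t for t in done if len(t) >= cfg.min_track_length]
    kept.sort(key=lambda t: t.leaf_id)
    return kept


def _depth_at(depths, frame: int, centroid: np.ndarray) -> float:
    if depths is None:
        return float("nan")
    dm = depths[frame]
    if dm is None:
        return float("nan")
    z = dm.z if hasattr(dm, "z") else np.asarray(dm)
    r = int(round(centroid[0]))
    c = int(round(centroid[1]))
    r = min(max(r, 0), z.shape[0] - 1)
    c = min(max(c, 0), z.shape[1] - 1)
    return float(z[r, c])


def relabel_series(
    series: Sequence[np.ndarray], tracks: Sequence[Track]
) -> list[np.ndarray]:
    """Rewrite per-frame labels to persistent leaf ids.

    Pixels belonging to instances not covered by any kept track are set
    to background (0)."""
    lut: dict[tuple[int, int], int] = {}
    for trk in tracks:
        for frame, lab in zip(trk.frames, trk.source_labels):
            lut[(frame, lab)] = trk.leaf_id
    out = []
    for frame, labels in enumerate(series):
        labels = np.asarray(labels)
        new = np.zeros_like(labels)
        for lab in np.unique(labels):
            if lab <= 0:
                continue
            leaf = lut.get((frame, int(lab)))
            if leaf is not None:
                new[labels == lab] = leaf
        out.append(new)
    return out


def apply_corrections(
    series: Sequence[np.ndarray], edits: Sequence[tuple[int, int, int]]
) -> list[np.ndarray]:
    """Apply manual identity corrections to a relabelled series.

    ``edits`` rows are (frame, old_id, new_id); from ``frame`` onward,
    pixels carrying ``old_id`` are rewritten to ``new_id``.  This
    replaces interactive fixing of occasional identity swaps with a
    reproducible, machine-readable edit table.
    """
    out = [np.asarray(f).copy() for f in series]
    for frame, old_id, new_id in edits:
        if not 0 <= frame < len(out):
            raise ConfigurationError(f"edit frame {frame} out of range")
        for f in out[frame:]:
            f[f == old_id] = new_id
    return out


def tracks_to_table(tracks: Sequence[Track]):
    """Flatten tracks to a tidy table (frame, leaf_id, x_px, y_px, z_mm)."""
    import pandas as pd

    rows = []
    for trk in tracks:
        for f, r, c, z, lab in zip(
            trk.frames, trk.rows, trk.cols, trk.z_mm, trk.source_labels
        ):
            rows.append(
                {
                    "frame": f,
                    "leaf_id": trk.leaf_id,
                    "x_px": c,
                    "y_px": r,
                    "z_mm": z,
                    "source_label": lab,
                }
            )
    return pd.DataFrame(rows, columns=["frame", "leaf_id", "x_px", "y_px", "z_mm", "source_label"])
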