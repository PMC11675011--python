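"""Three-chamber sociability scoring from pose-tracking tables.

The apparatus is a rectangular maze (default 800 x 400 mm) split along its
long axis into three equal chambers: one lateral chamber holds a conspecific
(``social``), the other an inanimate object (``nonsocial``), and the middle
chamber (``center``) is empty.  The animal's snout position, tracked at a
fixed frame rate, determines which chamber it occupies on every frame.

From the per-frame labels we score:

* occupancy time per chamber (frame count / fps),
* debounced chamber entries,
* the social-preference index, in both published conventions:
  ``(S - N) / (S + N)`` (difference form, in [-1, 1]) and
  ``S / (S + N)`` (ratio form, in [0, 1]), where S and N are the social and
  nonsocial occupancy times.  The two are related by ``ratio = (diff+1)/2``,
* locomotion (path length of the snout trajectory), and
* a smoothed occupancy heatmap (seconds per voxel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

CHAMBERS = ("social", "center", "nonsocial")

__all__ = [
    "CHAMBERS",
    "ChamberGeometry",
    "BehaviorSummary",
    "filter_likelihood",
    "assign_chamber",
    "occupancy_and_entries",
    "social_preference",
    "locomotion",
    "occupancy_heatmap",
    "summarize_track",
]


@dataclass
class ChamberGeometry:
    """Axis-aligned three-chamber maze geometry.

    The maze spans ``[0, width_mm] x [0, height_mm]``; the three chambers
    are equal-width vertical slices.  ``social_side`` picks which lateral
    chamber holds the conspecific.  Points exactly on a divider belong to
    the center chamber (deterministic tie-break); points outside the maze
    are clamped to its bounds before labelling.
    """

    width_mm: float = 800.0
    height_mm: float = 400.0
    social_side: str = "right"

    def __post_init__(self):
        if self.social_side not in ("left", "right"):
            raise ValueError("social_side must be 'left' or 'right'")
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("maze dimensions must be positive")

    @property
    def dividers(self) -> tuple:
        w = self.width_mm / 3.0
        return (w, 2.0 * w)

    def chamber_bounds(self, chamber: str) -> tuple:
        """(x_lo, x_hi, y_lo, y_hi) of a chamber's rectangle."""
        d0, d1 = self.dividers
        xr = {"left": (0.0, d0), "center": (d0, d1),
              "right": (d1, self.width_mm)}
        side = {"social": self.social_side,
                "nonsocial": "left" if self.social_side == "right" else "right",
                "center": "center"}[chamber]
        x_lo, x_hi = xr[side]
        return (x_lo, x_hi, 0.0, self.height_mm)

    def label_points(self, x, y) -> np.ndarray:
        """Vectorised chamber membership for clamped (x, y) points.

        Strictly left of the first divider is one lateral chamber, strictly
        right of the second divider the other; everything else (including
        divider lines) is the center.
        """
        x = np.clip(np.asarray(x, dtype=float), 0.0, self.width_mm)
        d0, d1 = self.dividers
        left_lab = "nonsocial" if self.social_side == "right" else "social"
        right_lab = "social" if self.social_side == "right" else "nonsocial"
        labels = np.full(x.shape, "center", dtype="<U9")
        labels[x < d0] = left_lab
        labels[x > d1] = right_lab
        return labels


@dataclass
class BehaviorSummary:
    """Session-level behavioural outcome measures."""

    animal_id: str
    time_s: dict
    entries: dict
    preference_diff: float
    preference_ratio: float
    distance_cm: float
    heatmap: np.ndarray = field(default=None, repr=False)
    n_frames: int = 0
    fps: float = 20.0

    def as_row(self) -> dict:
        row = {"animal_id": self.animal_id, "n_frames": self.n_frames,
               "fps": self.fps, "distance_cm": self.distance_cm,
               "preference_diff": self.preference_diff,
               "preference_ratio": self.preference_ratio}
        for ch in CHAMBERS:
            row[f"time_{ch}_s"] = self.time_s[ch]
            row[f"entries_{ch}"] = self.entries[ch]
        return row


def filter_likelihood(track: pd.DataFrame, min_likelihood: float = 0.9) -> pd.DataFrame:
    """Replace low-confidence detections with the last valid position.

    Frames whose tracking likelihood falls below ``min_likelihood`` inherit
    the previous valid frame's coordinates (leading invalid frames inherit
    the first valid one).  Likelihood values themselves are left untouched.
    """
    out = track.copy()
    ok = out["likelihood"].to_numpy() >= min_likelihood
    if not ok.any():
        raise ValueError("no frame passes the likelihood filter")
    idx = np.where(ok, np.arange(len(ok)), -1)
    idx = np.maximum.accumulate(idx)
    first_ok = np.argmax(ok)
    idx[idx < 0] = first_ok
    for col in ("x_mm", "y_mm"):
        out[col] = out[col].to_numpy()[idx]
    return out


def assign_chamber(track: pd.DataFrame, geom: ChamberGeometry) -> np.ndarray:
    """Label every frame with the chamber containing the snout."""
    if len(track) == 0:
        raise ValueError("empty track")
    return geom.label_points(track["x_mm"].to_numpy(), track["y_mm"].to_numpy())


def occupancy_and_entries(labels: np.ndarray, fps: float,
                          debounce_s: float = 0.25) -> tuple:
    """Occupancy seconds and debounced entry counts per chamber.

    Occupancy is raw frame count / fps.  An *entry* is a transition into a
    chamber whose visit persists for at least ``debounce_s`` (this guards
    against boundary chatter when the snout hovers over a divider); the
    session's first chamber always counts as one entry.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    time_s = {ch: float(np.count_nonzero(labels == ch)) / fps for ch in CHAMBERS}

    debounce_frames = max(1, int(round(debounce_s * fps)))
    entries = {ch: 0 for ch in CHAMBERS}
    # run-length encode
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [labels.size])))
    run_labels = labels[starts]

    current = run_labels[0]
    entries[current] = 1
    for lab, ln in zip(run_labels[1:], lengths[1:]):
        if ln >= debounce_frames and lab != current:
            entries[lab] += 1
            current = lab
    return time_s, entries


def social_preference(time_s: dict, include_center: bool = False) -> tuple:
    """Social-preference indices from per-chamber occupancy seconds.

    Returns ``(preference_diff, preference_ratio)`` where
    ``diff = (S - N) / T`` and ``ratio = S / (S + N)``; by default the
    exploration time T excludes the center chamber (T = S + N), which makes
    ``ratio == (diff + 1) / 2`` an exact identity.  With
    ``include_center=True`` the difference form uses T = S + N + C instead.
    """
    s, n = time_s["social"], time_s["nonsocial"]
    if s == 0 and n == 0:
        raise ValueError("undefined social preference: no lateral-chamber time")
    total = s + n + (time_s["center"] if include_center else 0.0)
    return (s - n) / total, s / (s + n)


def locomotion(track: pd.DataFrame) -> float:
    """Snout path length in cm (sum of per-frame Euclidean steps)."""
    x = track["x_mm"].to_numpy(float)
    y = track["y_mm"].to_numpy(float)
    steps = np.hypot(np.diff(x), np.diff(y))
    return float(steps.sum() / 10.0)


def occupancy_heatmap(track: pd.DataFrame, geom: ChamberGeometry, fps: float,
                      voxel_mm: float = 10.0, sigma_voxels: float = 1.0) -> np.ndarray:
    """Seconds-per-voxel occupancy grid, Gaussian smoothed.

    The grid covers the maze bounds with square voxels of ``voxel_mm``.
    Smoothing uses a mass-preserving Gaussian kernel (``sigma_voxels`` of 0
    disables it); apart from truncation at the maze edge, the grid total
    equals the session duration.
    """
    nx = int(np.ceil(geom.width_mm / voxel_mm))
    ny = int(np.ceil(geom.height_mm / voxel_mm))
    x = np.clip(track["x_mm"].to_numpy(float), 0, geom.width_mm - 1e-9)
    y = np.clip(track["y_mm"].to_numpy(float), 0, geom.height_mm - 1e-9)
    grid, _, _ = np.histogram2d(
        x, y, bins=[nx, ny], range=[[0, nx * voxel_mm], [0, ny * voxel_mm]]
    )
    grid /= fps  # frames -> seconds
    if sigma_voxels > 0:
        grid = ndimage.gaussian_filter(grid, sigma=sigma_voxels,
                                       mode="constant", truncate=4.0)
    return grid


def summarize_track(track: pd.DataFrame, geom: ChamberGeometry, fps: float,
                    animal_id: str = "", min_likelihood: float = 0.9,
                    debounce_s: float = 0.25, include_center: bool = False,
                    voxel_mm: float = 10.0, sigma_voxels: float = 1.0,
                    with_heatmap: bool = True) -> BehaviorSummary:
    """Full behavioural scoring of one session."""
    filt = filter_likelihood(track, min_likelihood)
    labels = assign_chamber(filt, geom)
    time_s, entries = occupancy_and_entries(labels, fps, debounce_s)
    pref_diff, pref_ratio = social_preference(time_s, include_center)
    heat = occupancy_heatmap(filt, geom, fps, voxel_mm, sigma_voxels) \
        if with_heatmap else None
    return BehaviorSummary(
        animal_id=animal_id, time_s=time_s, entries=entries,
        preference_diff=pref_diff, preference_ratio=pref_ratio,
        distance_cm=locomotion(filt), heatmap=heat,
        n_frames=len(track), fps=fps,
    )
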