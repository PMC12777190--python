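"""Vertebral corner landmarks and center-heatmap decoding.

A lateral lumbar radiograph is annotated with four corner landmarks per
vertebra (upper-left, upper-right, lower-left, lower-right) for L1-L5,
20 landmarks in total.  A landmark-detection network emits three dense maps
at 1/stride resolution: a center heatmap (one Gaussian peak per vertebral
centroid), a 2-channel center offset (sub-stride residual of the centroid)
and an 8-channel corner offset (displacement of each corner from the center,
in input-image pixels).  ``decode_landmarks`` turns these maps back into a
:class:`VertebraSet`.

Decoding convention (fixed here, since only the output contract is
specified upstream): 3x3-neighborhood local-maximum non-maximum suppression,
score floor 0.1, top-k peaks by score, ties broken by smaller row then
smaller column.  Coordinates are 0-based pixels, x rightward, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import maximum_filter

VERTEBRA_LEVELS = ("L1", "L2", "L3", "L4", "L5")
CORNER_KEYS = ("upper_left", "upper_right", "lower_left", "lower_right")

SCORE_FLOOR = 0.1


@dataclass(frozen=True)
class Landmark:
    x: float  # column, rightward
    y: float  # row, downward

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Vertebra:
    level: str
    corners: Mapping[str, Landmark]

    def __post_init__(self) -> None:
        if self.level not in VERTEBRA_LEVELS:
            raise ValueError(f"unknown vertebral level {self.level!r}")
        missing = [k for k in CORNER_KEYS if k not in self.corners]
        if missing:
            raise ValueError(
                f"{self.level}: missing corner(s) {', '.join(missing)}")

    @property
    def centroid(self) -> Landmark:
        pts = np.array([self.corners[k].as_array() for k in CORNER_KEYS])
        cx, cy = pts.mean(axis=0)
        return Landmark(float(cx), float(cy))

    def corner_array(self) -> np.ndarray:
        """(4, 2) array of (x, y) in the canonical corner order."""
        return np.array([self.corners[k].as_array() for k in CORNER_KEYS])


@dataclass(frozen=True)
class VertebraSet:
    """Ordered L1..L5, superior to inferior (centroid y increasing).

    A full set holds all five levels; decoding with k < 5 may yield a
    leading subset (L1..Lk), which downstream geometry rejects.
    """

    vertebrae: Sequence[Vertebra]

    def __post_init__(self) -> None:
        levels = [v.level for v in self.vertebrae]
        if levels != list(VERTEBRA_LEVELS[:len(levels)]):
            raise ValueError(f"expected a leading run of L1..L5, got {levels}")
        ys = [v.centroid.y for v in self.vertebrae]
        if not all(a < b for a, b in zip(ys, ys[1:])):
            raise ValueError("vertebral centroids are not strictly "
                             "descending the image (y must increase L1->L5)")

    def __iter__(self):
        return iter(self.vertebrae)

    def __getitem__(self, level: str) -> Vertebra:
        for v in self.vertebrae:
            if v.level == level:
                return v
        raise KeyError(level)

    def landmark_array(self) -> np.ndarray:
        """(5, 4, 2) array of corner coordinates, L1..L5 x canonical order."""
        return np.stack([v.corner_array() for v in self.vertebrae])


class DetectionError(RuntimeError):
    """Raised when fewer vertebral peaks than requested are decodable."""


def _nms_peaks(heatmap: np.ndarray, floor: float) -> np.ndarray:
    """Indices of 3x3 local maxima above the score floor.

    A cell survives if it equals the 3x3 neighborhood maximum; among equal
    neighbors the lexicographically smallest (row, col) cell is kept.
    """
    hm = np.asarray(heatmap, dtype=float)
    local_max = maximum_filter(hm, size=3, mode="constant", cval=-np.inf)
    candidates = np.argwhere((hm >= local_max) & (hm >= floor))
    keep = []
    for r, c in candidates:
        # tie-break: drop a cell if an equal-valued neighbor precedes it
        r0, r1 = max(r - 1, 0), min(r + 2, hm.shape[0])
        c0, c1 = max(c - 1, 0), min(c + 2, hm.shape[1])
        first = None
        for rr in range(r0, r1):
            for cc in range(c0, c1):
                if hm[rr, cc] == hm[r, c]:
                    first = (rr, cc)
                    break
            if first is not None:
                break
        if first == (r, c):
            keep.append((r, c))
    return np.array(keep, dtype=int).reshape(-1, 2)


def decode_landmarks(center_heatmap: np.ndarray,
                     center_offset: np.ndarray,
                     corner_offset: np.ndarray,
                     k: int = 5,
                     stride: int = 4) -> VertebraSet:
    """Decode vertebral corners from center heatmap + offset maps.

    The k highest NMS peaks are taken as vertebral centers; each center is
    ``(peak_cell + center_offset) * stride`` and each corner is
    ``center + corner_offset`` (corner offsets already in image pixels).
    Decoded vertebrae are sorted by center y and labeled L1..L5 top-down.
    """
    hm = np.asarray(center_heatmap, dtype=float)
    c_off = np.asarray(center_offset, dtype=float)
    k_off = np.asarray(corner_offset, dtype=float)
    if c_off.shape != (2,) + hm.shape or k_off.shape != (8,) + hm.shape:
        raise ValueError("offset maps must share the heatmap's spatial shape "
                         "with 2 and 8 leading channels")

    peaks = _nms_peaks(hm, SCORE_FLOOR)
    if len(peaks) < k:
        raise DetectionError(
            f"found {len(peaks)} peak(s) above {SCORE_FLOOR}, need {k}")
    scores = hm[peaks[:, 0], peaks[:, 1]]
    # top-k by score, ties by (row, col)
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -scores))
    peaks = peaks[order[:k]]

    centers = []
    for r, c in peaks:
        cy = (r + c_off[0, r, c]) * stride
        cx = (c + c_off[1, r, c]) * stride
        corners = k_off[:, r, c].reshape(4, 2)  # (dy, dx) per corner
        pts = {
            key: Landmark(x=cx + corners[i, 1], y=cy + corners[i, 0])
            for i, key in enumerate(CORNER_KEYS)
        }
        centers.append((cy, cx, pts))
    centers.sort(key=lambda t: (t[0], t[1]))
    vertebrae = [
        Vertebra(level=VERTEBRA_LEVELS[i], corners=pts)
        for i, (_, _, pts) in enumerate(centers)
    ]
    return VertebraSet(vertebrae)


@dataclass(frozen=True)
class LocalizationReport:
    """Landmark localization error summary (20 keypoints)."""

    mae_px: float
    mae_mm: float
    per_level_px: Mapping[str, float]
    pixel_spacing: float


def landmark_mae(pred: VertebraSet, gt: VertebraSet,
                 pixel_spacing: float = 0.1343) -> LocalizationReport:
    """Mean Euclidean keypoint error in pixels and millimetres.

    Averages the per-landmark Euclidean distances over all 20 corners;
    per-level means are also reported.  pixel_spacing converts px -> mm.
    """
    pred_levels = [v.level for v in pred]
    gt_levels = [v.level for v in gt]
    if pred_levels != gt_levels:
        raise ValueError(
            f"level mismatch: {pred_levels} vs {gt_levels}")
    d = np.linalg.norm(pred.landmark_array() - gt.landmark_array(), axis=2)
    per_level = {lv: float(d[i].mean()) for i, lv in enumerate(gt_levels)}
    mae_px = float(d.mean())
    return LocalizationReport(mae_px=mae_px,
                              mae_mm=mae_px * pixel_spacing,
                              per_level_px=per_level,
                              pixel_spacing=pixel_spacing)


def relative_error(mae_px: float, reference_px: float) -> float:
    """Localization error as a percentage of a reference length, 1 decimal."""
    if reference_px <= 0:
        raise ValueError("reference length must be positive")
    return round(100.0 * mae_px / reference_px, 1)
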