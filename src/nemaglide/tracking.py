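"""Rod detection, nearest-neighbour track linking and block-matching optical
flow for gliding-filament movies.

Detection binarizes each frame, fits every connected contour with an ellipse
(inertia-tensor equivalents) and keeps elongated objects only (aspect ratio
> 2). Linking joins detections in consecutive frames when they are closer
than 5 µm, are mutual nearest neighbours, and change area and length by less
than 20%; matched contours leave the pool (greedy, by increasing distance).
Optical flow finds, for each grid node, the displacement inside a 3.6 µm box
that maximizes the normalized cross-correlation between consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from skimage import measure
from skimage.feature import match_template
from skimage.filters import threshold_otsu

__all__ = [
    "Detection",
    "Track",
    "detect_rods",
    "link",
    "build_tracks",
    "track_speed",
    "block_flow",
    "flow_mask_from_stack",
]


@dataclass
class Detection:
    """One segmented rod: centroid (µm), line orientation mod π, ellipse
    length/area (µm, µm²) and aspect ratio (major/minor, ≥ 1)."""

    centroid: np.ndarray
    orientation: float
    length: float
    area: float
    aspect_ratio: float

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.orientation = float(np.mod(self.orientation, np.pi))


@dataclass
class Track:
    """Time-ordered sequence of (frame, Detection) with strictly consecutive
    frame numbers."""

    frames: list[int] = _dc_field(default_factory=list)
    detections: list[Detection] = _dc_field(default_factory=list)

    def append(self, frame: int, det: Detection):
        if self.frames and frame != self.frames[-1] + 1:
            raise ValueError("track frames must increase by exactly 1")
        self.frames.append(frame)
        self.detections.append(det)

    def positions(self) -> np.ndarray:
        return np.array([d.centroid for d in self.detections]).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.frames)


def detect_rods(
    frame: np.ndarray,
    pixel_size: float,
    threshold: float | None = None,
    min_aspect: float = 2.0,
    min_area_px: int = 3,
) -> list[Detection]:
    """Segment rod-like objects in one grayscale frame.

    The frame is binarized (Otsu by default), connected components are
    labelled, and each component's equivalent ellipse (from its second
    moments) provides centroid, orientation, major-axis length and area.
    Only contours with aspect ratio above ``min_aspect`` survive — circular
    blobs and debris are rejected. Empty or featureless frames give [].
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a 2D grayscale frame")
    if frame.max() <= frame.min():
        return []
    thr = threshold_otsu(frame) if threshold is None else threshold
    binary = frame > thr
    if not binary.any():
        return []
    labels = measure.label(binary, connectivity=2)
    out: list[Detection] = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        aspect = major / minor if minor > 0 else np.inf
        if aspect <= min_aspect:
            continue
        # skimage orientation is measured from the row (y) axis toward the
        # column axis; convert to our CCW-from-+x convention.
        phi = np.mod(np.pi / 2 - rp.orientation, np.pi)
        cy, cx = rp.centroid
        out.append(
            Detection(
                centroid=np.array([cx, cy]) * pixel_size,
                orientation=phi,
                length=major * pixel_size,
                area=rp.area * pixel_size**2,
                aspect_ratio=float(aspect),
            )
        )
    return out


def _rule3_ok(a: Detection, b: Detection, max_rel_change: float) -> bool:
    """Area AND length change below ``max_rel_change``, relative to the
    earlier detection."""
    if a.area <= 0 or a.length <= 0:
        return False
    return (
        abs(b.area - a.area) / a.area < max_rel_change
        and abs(b.length - a.length) / a.length < max_rel_change
    )


def link(
    dets_t: list[Detection],
    dets_t1: list[Detection],
    max_dist: float = 5.0,
    max_rel_change: float = 0.2,
) -> list[tuple[int, int]]:
    """Match detections of two consecutive frames.

    A pair (i, j) links iff (1) their centroids are closer than ``max_dist``
    µm, (2) they are mutual nearest neighbours among the still-unmatched
    detections, and (3) area and length each change by less than
    ``max_rel_change`` relative to the earlier contour. Matching is greedy in
    order of increasing distance (the globally closest remaining pair is
    always mutual-nearest), and matched contours are removed from the pool.
    """
    if not dets_t or not dets_t1:
        return []
    p0 = np.array([d.centroid for d in dets_t])
    p1 = np.array([d.centroid for d in dets_t1])
    dist = np.linalg.norm(p0[:, None, :] - p1[None, :, :], axis=-1)
    dist = np.where(dist < max_dist, dist, np.inf)
    pairs: list[tuple[int, int]] = []
    work = dist.copy()
    while np.isfinite(work).any():
        i, j = np.unravel_index(np.argmin(work), work.shape)
        if _rule3_ok(dets_t[i], dets_t1[j], max_rel_change):
            pairs.append((int(i), int(j)))
            work[i, :] = np.inf
            work[:, j] = np.inf
        else:
            work[i, j] = np.inf
    return pairs


def build_tracks(detections_per_frame: list[list[Detection]], **link_kwargs) -> list[Track]:
    """Chain frame-to-frame links into tracks (no gap closing)."""
    tracks: list[Track] = []
    open_by_det: dict[int, Track] = {}
    for f, dets in enumerate(detections_per_frame):
        if f == 0:
            for k, det in enumerate(dets):
                tr = Track()
                tr.append(0, det)
                tracks.append(tr)
                open_by_det[k] = tr
            continue
        pairs = link(detections_per_frame[f - 1], dets, **link_kwargs)
        new_open: dict[int, Track] = {}
        for i, j in pairs:
            tr = open_by_det.get(i)
            if tr is None:
                tr = Track()
                tr.append(f - 1, detections_per_frame[f - 1][i])
                tracks.append(tr)
            tr.append(f, dets[j])
            new_open[j] = tr
        for j, det in enumerate(dets):
            if j not in new_open:
                tr = Track()
                tr.append(f, det)
                tracks.append(tr)
                new_open[j] = tr
        open_by_det = new_open
    return tracks


def track_speed(track: Track, frame_interval: float) -> np.ndarray:
    """Per-step speeds (µm/s): consecutive centroid distance / interval.

    Single-detection tracks give an empty array.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    pos = track.positions()
    if len(pos) < 2:
        return np.empty(0)
    return np.linalg.norm(np.diff(pos, axis=0), axis=1) / frame_interval


def block_flow(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    pixel_size: float,
    box: float = 3.6,
    stride: int | None = None,
    template_px: int | None = None,
    mask: np.ndarray | None = None,
    subpixel: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block-matching optical flow between two frames.

    For each node of a ``stride``-spaced grid, the local template from
    ``frame_t`` is correlated (normalized cross-correlation) against all
    positions of ``frame_t1`` inside a ``box`` × ``box`` µm search window;
    the best match gives the displacement. Returns (dx, dy, valid) grids in
    *pixels per frame*, full-frame sized, NaN where invalid. Featureless
    templates (zero variance) and masked-out nodes are invalid. Optional
    ``subpixel`` refines the peak with a parabolic fit (integer best match by
    default). ``mask`` (e.g. thresholded maximum-intensity projection of the
    stack) restricts where flow is computed.
    """
    a = np.asarray(frame_t, dtype=float)
    b = np.asarray(frame_t1, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    box_px = max(3, int(round(box / pixel_size)))
    if box_px % 2 == 0:
        box_px += 1
    if template_px is None:
        template_px = max(3, box_px // 2)
        if template_px % 2 == 0:
            template_px += 1
    if stride is None:
        stride = max(1, template_px // 2)
    th = template_px // 2
    sh = box_px // 2
    rows, cols = a.shape
    dx = np.full(a.shape, np.nan)
    dy = np.full(a.shape, np.nan)
    for i in range(sh + th, rows - sh - th, stride):
        for j in range(sh + th, cols - sh - th, stride):
            if mask is not None and not mask[i, j]:
                continue
            tmpl = a[i - th : i + th + 1, j - th : j + th + 1]
            if tmpl.std() < 1e-12:
                continue
            win = b[i - sh - th : i + sh + th + 1, j - sh - th : j + sh + th + 1]
            cc = match_template(win, tmpl)
            pk = np.unravel_index(np.argmax(cc), cc.shape)
            dyy = pk[0] - sh
            dxx = pk[1] - sh
            if subpixel:
                dyy += _parabolic_offset(cc, pk, axis=0)
                dxx += _parabolic_offset(cc, pk, axis=1)
            dy[i, j] = dyy
            dx[i, j] = dxx
    valid = np.isfinite(dx)
    return dx, dy, valid


def _parabolic_offset(cc: np.ndarray, peak, axis: int) -> float:
    """Sub-pixel peak offset along one axis by 3-point parabola fit."""
    idx = list(peak)
    if idx[axis] <= 0 or idx[axis] >= cc.shape[axis] - 1:
        return 0.0
    lo, hi = list(idx), list(idx)
    lo[axis] -= 1
    hi[axis] += 1
    y0, y1, y2 = cc[tuple(lo)], cc[tuple(idx)], cc[tuple(hi)]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-12:
        return 0.0
    return float(0.5 * (y0 - y2) / denom)


def flow_mask_from_stack(stack: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Mask where enough moving material is present: the maximum-intensity
    projection of the stack thresholded (Otsu by default)."""
    proj = np.max(np.asarray(stack, dtype=float), axis=0)
    if proj.max() <= proj.min():
        return np.zeros(proj.shape, dtype=bool)
    thr = threshold_otsu(proj) if threshold is None else threshold
    return proj > thr
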