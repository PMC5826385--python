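"""Segment ink dots in grayscale video frames and link them into tracks.

The physical experiments film dark ink dots on a light brain/skull surface.
Per frame, dots are isolated by a global Otsu threshold on the contrast-
normalised image, connected components (8-connectivity) are filtered by
area, and each component's position is taken as its intensity-weighted
(darkness-weighted) centroid for sub-pixel accuracy.  Across frames,
centroids are linked by greedy mutual-nearest assignment with a hard link
radius (10 px by convention): a candidate farther than the radius is never
linked, an unmatched centroid starts a new track, and a track that misses a
frame terminates rather than being re-identified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage import filters, measure

from .synth import FrameStack

__all__ = [
    "CentroidSet",
    "MarkerTrack",
    "preprocess",
    "segment_dots",
    "link_tracks",
    "filter_tracks",
    "track_stack",
    "DEFAULT_LINK_RADIUS",
]

logger = logging.getLogger(__name__)

DEFAULT_LINK_RADIUS = 10.0  # px


@dataclass(frozen=True)
class CentroidSet:
    """Sub-pixel dot centroids detected in one frame."""

    frame_index: int
    centroids: np.ndarray   # (n, 2) as (x_px, y_px) = (col, row)
    areas: np.ndarray       # (n,) px^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroids", np.asarray(self.centroids, float).reshape(-1, 2))
        object.__setattr__(self, "areas", np.asarray(self.areas, float).reshape(-1))


@dataclass
class MarkerTrack:
    """One labelled dot followed across consecutive frames."""

    marker_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    label: str | None = None    # 'brain' or 'rigid', assigned downstream

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions_array(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float).reshape(-1, 2)

    @property
    def first_position(self) -> np.ndarray:
        return np.asarray(self.positions[0], dtype=float)


def preprocess(
    frame: np.ndarray,
    low_percentile: float = 0.0,
    high_percentile: float = 100.0,
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Contrast-normalise one grayscale frame (monotone intensity mapping).

    A linear stretch maps the given intensity percentiles (default the
    full min/max range - the dots occupy far less than 1% of the frame,
    so inner percentiles would collapse onto the background) onto [0, 1],
    which also cancels frame-to-frame illumination flicker; an optional
    Gaussian blur suppresses pixel noise.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    lo = np.percentile(img, low_percentile)
    hi = np.percentile(img, high_percentile)
    if hi <= lo:  # constant image: nothing to stretch
        out = np.zeros_like(img)
    else:
        out = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    if smooth_sigma > 0:
        out = filters.gaussian(out, sigma=smooth_sigma, preserve_range=True)
    return out


def segment_dots(
    frame: np.ndarray,
    min_area: float = 4.0,
    max_area: float = 400.0,
) -> CentroidSet | np.ndarray:
    """Detect dark dots in one preprocessed frame.

    Thresholds with Otsu's method (dots darker than background), labels
    8-connected components, filters by area, and returns darkness-weighted
    centroids.  Components touching the border are kept.  Zero detections
    yield an empty, valid set.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if img.max() == img.min():
        logger.info("segment_dots: constant frame, no detections")
        return CentroidSet(0, np.empty((0, 2)), np.empty(0))
    thresh = filters.threshold_otsu(img)
    mask = img < thresh
    labels = measure.label(mask, connectivity=2)
    weight = img.max() - img  # darkness weight for sub-pixel centroids
    cents, areas = [], []
    nrows, ncols = img.shape
    for region in measure.regionprops(labels):
        if region.area < min_area or region.area > max_area:
            continue
        # include a 1 px halo around the component so the anti-aliased
        # dot edge contributes to the weighted centroid (sub-pixel bias
        # otherwise drifts with the dot's phase on the pixel grid)
        r0, c0, r1, c1 = region.bbox
        r0, c0 = max(r0 - 1, 0), max(c0 - 1, 0)
        r1, c1 = min(r1 + 1, nrows), min(c1 + 1, ncols)
        w = weight[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        tot = w.sum()
        cents.append(((w * xx).sum() / tot, (w * yy).sum() / tot))
        areas.append(region.area)
    if not cents:
        logger.info("segment_dots: no components within area bounds")
        return CentroidSet(0, np.empty((0, 2)), np.empty(0))
    return CentroidSet(0, np.asarray(cents), np.asarray(areas, float))


def _mutual_nearest_pairs(prev: np.ndarray, cur: np.ndarray, radius: float):
    """Greedy mutual-nearest matching within ``radius``; ties -> lowest index.

    Returns list of (prev_index, cur_index).
    """
    if len(prev) == 0 or len(cur) == 0:
        return []
    d = cdist(prev, cur)
    d[d > radius] = np.inf
    pairs = []
    avail_p = np.ones(len(prev), bool)
    avail_c = np.ones(len(cur), bool)
    while True:
        sub = d.copy()
        sub[~avail_p, :] = np.inf
        sub[:, ~avail_c] = np.inf
        if not np.isfinite(sub).any():
            break
        found = False
        # np.argmin scans row-major, so equidistant candidates resolve to the
        # lowest (prev, cur) index pair automatically.
        for i in np.flatnonzero(avail_p):
            j = int(np.argmin(sub[i]))
            if not np.isfinite(sub[i, j]):
                continue
            if int(np.argmin(sub[:, j])) == i:  # mutual preference
                pairs.append((i, j))
                avail_p[i] = False
                avail_c[j] = False
                found = True
        if not found:
            break
    return pairs


def link_tracks(
    centroid_sets: list[CentroidSet],
    radius: float = DEFAULT_LINK_RADIUS,
) -> list[MarkerTrack]:
    """Link per-frame centroids into tracks by greedy mutual-nearest assignment.

    Candidates farther than ``radius`` are never linked; unmatched centroids
    start new tracks; a track with a gap terminates.
    """
    tracks: list[MarkerTrack] = []
    active: list[MarkerTrack] = []
    next_id = 0
    for cs in centroid_sets:
        cur = cs.centroids
        heads = np.asarray([tr.positions[-1] for tr in active]).reshape(-1, 2)
        pairs = _mutual_nearest_pairs(heads, cur, radius)
        matched_c = set()
        survivors = []
        for i, j in pairs:
            active[i].frames.append(cs.frame_index)
            active[i].positions.append(cur[j])
            survivors.append(active[i])
            matched_c.add(j)
        for j in range(len(cur)):
            if j not in matched_c:
                tr = MarkerTrack(marker_id=next_id, frames=[cs.frame_index], positions=[cur[j]])
                next_id += 1
                tracks.append(tr)
                survivors.append(tr)
        active = survivors
    return tracks


def filter_tracks(
    tracks: list[MarkerTrack],
    n_frames: int,
    min_fraction: float = 0.9,
) -> list[MarkerTrack]:
    """Keep only tracks covering at least ``min_fraction`` of the frames."""
    return [t for t in tracks if len(t) >= min_fraction * n_frames]


def track_stack(
    stack: FrameStack,
    radius: float = DEFAULT_LINK_RADIUS,
    min_area: float = 4.0,
    max_area: float = 400.0,
    min_track_fraction: float = 0.9,
    smooth_sigma: float = 0.0,
) -> list[MarkerTrack]:
    """Full per-stack pipeline: preprocess, segment and link every frame."""
    sets = []
    for f, frame in enumerate(stack.frames):
        img = preprocess(frame, smooth_sigma=smooth_sigma)
        cs = segment_dots(img, min_area=min_area, max_area=max_area)
        sets.append(CentroidSet(f, cs.centroids, cs.areas))
    tracks = link_tracks(sets, radius=radius)
    return filter_tracks(tracks, len(stack.frames), min_track_fraction)
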