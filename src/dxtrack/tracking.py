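"""Diffraction-spot detection and frame-to-frame linking.

Implements the Crocker–Grier-style subset of single-particle tracking the
pipeline needs: rolling-median background subtraction, local-maximum
detection with intensity-weighted sub-pixel centroid refinement, and linking
by minimum-total-squared-displacement assignment between consecutive frames
(optimal per frame pair, gated by a maximum search radius).

Linking is deliberately conservative: the default allows no gap bridging
(``memory = 0``), because a trajectory's lifetime is defined by continuous
visibility of its spot — bridging gaps would silently lengthen lifetimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters.rank import median as rank_median


@dataclass
class SpotObservation:
    """One detected spot in one frame (sub-pixel centroid, summed counts)."""

    frame: int
    x: float
    y: float
    intensity: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass
class TrackingParams:
    """Detection and linking parameters.

    detection_threshold : counts a background-corrected pixel must exceed to
        seed a spot.
    min_spot_diameter : pixels; sets the centroid window and the background
        median window (3× this value).
    search_radius : max frame-to-frame displacement, pixels.
    memory : frames a track may go undetected and still be continued
        (default 0: lifetime = continuous visibility).
    min_track_length : shortest track kept, frames.
    """

    detection_threshold: float = 50.0
    min_spot_diameter: int = 5
    search_radius: float = 5.0
    memory: int = 0
    min_track_length: int = 2

    def __post_init__(self) -> None:
        if self.search_radius <= 0:
            raise ValueError("search_radius must be positive")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.min_spot_diameter < 1:
            raise ValueError("min_spot_diameter must be >= 1")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def subtract_background(image: np.ndarray, min_spot_diameter: int = 5) -> np.ndarray:
    """Remove a rolling-median background; clip negative residuals to zero.

    The median window is 3 × min_spot_diameter so that a spot occupies well
    under half the window and does not bias its own background estimate.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    window = 3 * min_spot_diameter
    if min(image.shape) < window:
        raise ValueError(
            f"image {image.shape} smaller than median window {window}"
        )
    if (np.issubdtype(image.dtype, np.integer)
            and image.min() >= 0 and image.max() <= np.iinfo(np.uint16).max):
        # photon-counting frames are small non-negative integers: the
        # histogram-based rank filter computes the exact window median far
        # faster than sorting
        footprint = np.ones((window, window), dtype=bool)
        with warnings.catch_warnings():
            # the rank filter warns about >8-bit data; it stays exact and
            # is still far faster than a sorting median here
            warnings.filterwarnings("ignore", message=".*rank filter.*")
            background = rank_median(
                image.astype(np.uint16), footprint=footprint
            ).astype(float)
    else:
        background = ndimage.median_filter(
            image.astype(float), size=window, mode="nearest"
        )
    corrected = image.astype(float) - background
    np.clip(corrected, 0.0, None, out=corrected)
    return corrected


def detect_spots(image: np.ndarray, params: TrackingParams,
                 frame: int = 0) -> list[SpotObservation]:
    """Find local maxima above threshold and refine each to its centroid.

    The centroid is intensity-weighted over a square window of half-width
    ``min_spot_diameter`` around the maximum — wide enough that the PSF
    tails are not truncated, which would bias the centroid toward the pixel
    grid.  Maxima within ``min_spot_diameter`` of a brighter one collapse
    into that observation.
    """
    image = np.asarray(image, dtype=float)
    d = params.min_spot_diameter
    # local maxima over a (2·half+1)² neighbourhood
    half = max(d // 2, 1)
    c_half = d
    footprint = np.ones((2 * half + 1, 2 * half + 1), dtype=bool)
    local_max = ndimage.maximum_filter(image, footprint=footprint,
                                       mode="constant")
    peaks = (image == local_max) & (image > params.detection_threshold)
    ys, xs = np.nonzero(peaks)
    if len(xs) == 0:
        return []
    order = np.argsort(image[ys, xs])[::-1]
    taken = np.zeros(image.shape, dtype=bool)
    obs: list[SpotObservation] = []
    for i in order:
        yc, xc = ys[i], xs[i]
        if taken[yc, xc]:
            continue
        taken[max(yc - half, 0):yc + half + 1,
              max(xc - half, 0):xc + half + 1] = True
        y0, y1 = max(yc - c_half, 0), min(yc + c_half + 1, image.shape[0])
        x0, x1 = max(xc - c_half, 0), min(xc + c_half + 1, image.shape[1])
        patch = image[y0:y1, x0:x1]
        total = patch.sum()
        if total <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        obs.append(SpotObservation(
            frame=frame,
            x=float((patch * xx).sum() / total),
            y=float((patch * yy).sum() / total),
            intensity=float(total),
        ))
    # stable order: by x then y, for deterministic downstream linking
    obs.sort(key=lambda o: (o.x, o.y))
    return obs


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_spots(observations: list[list[SpotObservation]],
               params: TrackingParams) -> list[list[SpotObservation]]:
    """Link per-frame observations into tracks.

    For each new frame, open track ends (last seen within ``memory`` frames)
    are matched to new observations by minimising the total squared
    displacement over the frame pair (Hungarian assignment); candidate pairs
    farther apart than ``search_radius`` are forbidden.  Unmatched
    observations start new tracks; tracks shorter than ``min_track_length``
    are discarded at the end.

    Returns a list of tracks, each a list of SpotObservation, ordered by the
    frame at which the track started (ties: detection order).
    """
    frames_seen = [obs[0].frame for obs in observations if obs]
    if any(np.diff(frames_seen) < 0):
        raise ValueError("observation groups must be ordered by frame")
    for group in observations:
        if len({o.frame for o in group}) > 1:
            raise ValueError("each observation group must hold a single frame")

    tracks: list[list[SpotObservation]] = []
    open_tracks: list[int] = []          # indices into tracks
    r2_max = params.search_radius ** 2

    for group in observations:
        if not group:
            continue
        frame = group[0].frame
        # drop track ends that are now too stale to continue
        open_tracks = [
            ti for ti in open_tracks
            if frame - tracks[ti][-1].frame <= params.memory + 1
        ]
        assigned_obs = set()
        if open_tracks:
            cost = np.full((len(open_tracks), len(group)), np.inf)
            for i, ti in enumerate(open_tracks):
                last = tracks[ti][-1]
                for j, o in enumerate(group):
                    d2 = (o.x - last.x) ** 2 + (o.y - last.y) ** 2
                    if d2 <= r2_max:
                        cost[i, j] = d2
            # linear_sum_assignment cannot take inf rows/cols: make forbidden
            # pairs finitely expensive but never preferable to leaving both
            # unmatched (big-M), then strip them afterwards
            big_m = r2_max * (cost.size + 1) + 1.0
            finite = np.where(np.isfinite(cost), cost, big_m)
            rows, cols = linear_sum_assignment(finite)
            for i, j in zip(rows, cols):
                if np.isfinite(cost[i, j]):
                    tracks[open_tracks[i]].append(group[j])
                    assigned_obs.add(j)
        next_open = [
            ti for ti in open_tracks if tracks[ti][-1].frame == frame
        ]
        # stale-but-alive ends stay open only if memory allows
        if params.memory > 0:
            next_open += [
                ti for ti in open_tracks if tracks[ti][-1].frame < frame
            ]
        for j, o in enumerate(group):
            if j not in assigned_obs:
                tracks.append([o])
                next_open.append(len(tracks) - 1)
        open_tracks = next_open

    return [t for t in tracks if len(t) >= params.min_track_length]


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_image_stack(path) -> np.ndarray:
    """Load a (multi-page) TIFF stack as an array of shape (frames, y, x)."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def track_movie(stack: np.ndarray,
                params: TrackingParams) -> list[list[SpotObservation]]:
    """Detect spots in every frame of a stack and link them into tracks."""
    per_frame = [
        detect_spots(subtract_background(frame, params.min_spot_diameter),
                     params, frame=i)
        for i, frame in enumerate(stack)
    ]
    return link_spots(per_frame, params)


def tracks_to_table(tracks: list[list[SpotObservation]]) -> pd.DataFrame:
    """Flatten tracks into a table (frame, x, y, intensity, track_id)."""
    rows = [
        (o.frame, o.x, o.y, o.intensity, tid)
        for tid, track in enumerate(tracks)
        for o in track
    ]
    return pd.DataFrame(
        rows, columns=["frame", "x", "y", "intensity", "track_id"]
    )
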