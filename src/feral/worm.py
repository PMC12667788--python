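"""Rule-based C. elegans locomotory-state classification.

Worm tracking yields a per-frame binary mask and centroid.  From these, each
frame is assigned one of four locomotor states — forward, reverse, turn,
pause — by a deterministic cascade of geometric and kinematic rules:

* a frame is *self-intersecting* (coiled) when the outermost contour's
  area : perimeter ratio exceeds a threshold (default 3.3, in the tracker's
  calibrated length units);
* non-intersecting masks are skeletonized to a midline, midlines are
  oriented consistently across frames by minimizing point-to-point distance
  to the previous frame, and the head is the end the animal moves toward
  more often;
* velocity is a centroid difference across ``offset`` frames (default 4, at
  6 fps: dt = 0.67 s), signed by its dot product with the tail-to-head axis;
* the cascade (first match wins): **turn** if self-intersecting, or if the
  midpoint-to-tail vector is longer than the midpoint-to-head vector and the
  angle between them is below 45 degrees (sharply bent posture); **pause**
  if |speed| < 50 um/s sustained for at least 0.5 s; **forward** / **reverse**
  by the sign of the speed.

Frames in the initial window where velocity is incomputable are *undefined*
(unless their posture already marks them as turning).
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.measure import label as cc_label, perimeter as sk_perimeter
from skimage.morphology import skeletonize

from feral.labels import ClassCatalog, FrameLabelTrack

__all__ = [
    "WormTrack",
    "WormStateTrack",
    "WORM_STATES",
    "self_intersecting",
    "contour_stats",
    "extract_midline",
    "align_midlines",
    "assign_head",
    "signed_speed",
    "classify_states",
    "states_to_labeltrack",
]

WORM_STATES = ("forward", "reverse", "turn", "pause")
UNDEFINED = "undefined"

DEFAULT_FPS = 6.0
DEFAULT_OFFSET = 4  # frames between centroids for the velocity difference
DEFAULT_SPEED_THRESHOLD = 50.0  # um/s
DEFAULT_PAUSE_MIN_S = 0.5
DEFAULT_TURN_ANGLE_DEG = 45.0
DEFAULT_INTERSECT_RATIO = 3.3


@dataclass
class WormTrack:
    """Per-frame tracking output for one worm.

    ``centroids`` are (n, 2) positions in um; ``areas``/``perimeters`` are
    contour statistics in um^2 / um (or the tracker's native units, matching
    the intersect threshold); ``midlines`` holds an ordered (M, 2) point
    array per frame, or None where the posture is self-intersecting.
    """

    centroids: np.ndarray
    areas: np.ndarray
    perimeters: np.ndarray
    midlines: list[np.ndarray | None]
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        n = len(self.centroids)
        if not (len(self.areas) == len(self.perimeters) == len(self.midlines) == n):
            raise ValueError("all per-frame sequences must have equal length")


@dataclass
class WormStateTrack:
    """One locomotor state per frame."""

    states: np.ndarray  # (n,) of {forward, reverse, turn, pause, undefined}
    fps: float = DEFAULT_FPS
    signed_speed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.states)) - set(WORM_STATES) - {UNDEFINED}
        if bad:
            raise ValueError(f"unknown states {sorted(bad)}")


# ---------------------------------------------------------------------------
# Geometry


def self_intersecting(
    contour_area: float,
    contour_perimeter: float,
    threshold: float = DEFAULT_INTERSECT_RATIO,
) -> bool:
    """True iff area / perimeter strictly exceeds the threshold.

    A thin tube has ratio ~ width / 2; a coiled worm closes into a compact
    blob whose ratio grows with its radius, so crossing the threshold flags
    self-intersection.  Strict inequality: a ratio exactly at the threshold
    is not intersecting.
    """
    if contour_area <= 0 or contour_perimeter <= 0:
        raise ValueError("contour area and perimeter must be positive")
    return contour_area / contour_perimeter > threshold


def contour_stats(mask: np.ndarray, um_per_px: float = 1.0) -> tuple[float, float]:
    """(area, perimeter) of a binary mask, scaled to um^2 / um."""
    mask = np.asarray(mask).astype(bool)
    area = float(mask.sum()) * um_per_px**2
    perim = float(sk_perimeter(mask)) * um_per_px
    return area, perim


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_adjacency(coords: np.ndarray) -> list[list[int]]:
    index = {tuple(c): i for i, c in enumerate(coords)}
    adj: list[list[int]] = [[] for _ in coords]
    for i, (r, c) in enumerate(coords):
        for dr, dc in _NEIGHBORS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)
    return adj


def _bfs_farthest(adj: list[list[int]], start: int) -> tuple[int, dict[int, int]]:
    parent = {start: -1}
    queue = deque([start])
    last = start
    while queue:
        node = queue.popleft()
        last = node
        for nxt in adj[node]:
            if nxt not in parent:
                parent[nxt] = node
                queue.append(nxt)
    return last, parent


def extract_midline(mask: np.ndarray, um_per_px: float = 1.0) -> np.ndarray:
    """Skeletonize a non-self-intersecting mask into an ordered midline.

    The midline is the longest geodesic path through the skeleton (a
    double-BFS on the pixel graph), which inherently prunes short spur
    branches left by skeletonization.  Points are (x, y) in um, ordered from
    one end to the other.
    """
    mask = np.asarray(mask).astype(bool)
    area, perim = contour_stats(mask)
    if self_intersecting(area, perim):
        raise ValueError("mask is self-intersecting; midline undefined")
    skel = skeletonize(mask)
    labels = cc_label(skel, connectivity=2)
    if labels.max() == 0:
        raise ValueError("empty skeleton")
    if labels.max() > 1:
        # keep the largest component; fragments are segmentation noise
        sizes = np.bincount(labels.ravel())[1:]
        skel = labels == (1 + sizes.argmax())
    coords = np.argwhere(skel)
    adj = _skeleton_adjacency(coords)
    end_a, _ = _bfs_farthest(adj, 0)
    end_b, parent = _bfs_farthest(adj, end_a)
    path = []
    node = end_b
    while node != -1:
        path.append(node)
        node = parent[node]
    if len(path) < 3:
        raise ValueError("skeleton too short for a midline (< 3 points)")
    pts = coords[path].astype(np.float64)
    return np.column_stack([pts[:, 1], pts[:, 0]]) * um_per_px  # (x, y)


def _resample(midline: np.ndarray, k: int = 50) -> np.ndarray:
    seg = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(midline[:1], k, axis=0)
    t = np.linspace(0.0, s[-1], k)
    return np.column_stack([np.interp(t, s, midline[:, i]) for i in range(2)])


def arc_midpoint(midline: np.ndarray) -> np.ndarray:
    """Midline point at half arc length ("midpoint of the worm")."""
    return _resample(midline, 51)[25]


def align_midlines(midlines: Sequence[np.ndarray | None]) -> list[np.ndarray | None]:
    """Orient each midline consistently with the previous available frame.

    For every frame the stored point order is kept or reversed, whichever
    minimizes the summed point-to-point distance to the previous oriented
    midline (both resampled to a common length).  The first available
    midline keeps its stored orientation.
    """
    oriented: list[np.ndarray | None] = []
    prev_resampled: np.ndarray | None = None
    for m in midlines:
        if m is None:
            oriented.append(None)
            continue
        if prev_resampled is None:
            oriented.append(m.copy())
            prev_resampled = _resample(m)
            continue
        fwd = _resample(m)
        cost_fwd = np.linalg.norm(fwd - prev_resampled, axis=1).sum()
        cost_rev = np.linalg.norm(fwd[::-1] - prev_resampled, axis=1).sum()
        if cost_rev < cost_fwd:
            oriented.append(m[::-1].copy())
            prev_resampled = fwd[::-1]
        else:
            oriented.append(m.copy())
            prev_resampled = fwd
    return oriented


# ---------------------------------------------------------------------------
# Kinematics


def _velocities(
    centroids: np.ndarray, fps: float, offset: int
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 2) velocity in um/s, NaN where incomputable, plus dt."""
    n = len(centroids)
    dt = offset / fps
    vel = np.full((n, 2), np.nan)
    if n > offset:
        diff = centroids[offset:] - centroids[:-offset]
        vel[offset:] = diff / dt
    # missing centroids (NaN) propagate into the affected velocity frames
    return vel, dt


def assign_head(
    oriented_midlines: Sequence[np.ndarray | None],
    centroids: np.ndarray,
    fps: float = DEFAULT_FPS,
    offset: int = DEFAULT_OFFSET,
) -> str:
    """Decide which midline end is the head: 'first' or 'last'.

    Worms move toward their head more often than toward their tail, so the
    head is the end the per-frame velocity points at in the majority of
    frames.  An exact tie falls back to 'first' with a warning.
    """
    vel, _ = _velocities(np.asarray(centroids, dtype=np.float64), fps, offset)
    toward_last = toward_first = 0
    for t, m in enumerate(oriented_midlines):
        if m is None or np.isnan(vel[t]).any():
            continue
        end_to_end = m[-1] - m[0]
        d = float(np.dot(vel[t], end_to_end))
        if d > 0:
            toward_last += 1
        elif d < 0:
            toward_first += 1
    if toward_last == toward_first:
        warnings.warn("head/tail assignment tied; defaulting to 'first'", stacklevel=2)
        return "first"
    return "last" if toward_last > toward_first else "first"


def _head_tail_vectors(
    oriented_midlines: Sequence[np.ndarray | None], head: str
) -> np.ndarray:
    """Per-frame unit tail-to-head vectors; gaps filled from neighbors."""
    n = len(oriented_midlines)
    vecs = np.full((n, 2), np.nan)
    for t, m in enumerate(oriented_midlines):
        if m is None:
            continue
        v = (m[-1] - m[0]) if head == "last" else (m[0] - m[-1])
        norm = np.linalg.norm(v)
        if norm > 0:
            vecs[t] = v / norm
    # forward/backward fill so self-intersecting gaps inherit the nearest axis
    last = None
    for t in range(n):
        if np.isnan(vecs[t]).any():
            if last is not None:
                vecs[t] = last
        else:
            last = vecs[t]
    nxt = None
    for t in range(n - 1, -1, -1):
        if np.isnan(vecs[t]).any():
            if nxt is not None:
                vecs[t] = nxt
        else:
            nxt = vecs[t]
    return vecs


def signed_speed(
    centroids: np.ndarray,
    head_tail: np.ndarray,
    fps: float = DEFAULT_FPS,
    offset: int = DEFAULT_OFFSET,
) -> np.ndarray:
    """Per-frame signed speed in um/s.

    velocity_t = (centroid_t - centroid_{t-offset}) / dt; the magnitude is
    signed positive iff the velocity points along the tail-to-head axis
    (zero dot product with nonzero speed counts as forward).  The first
    ``offset`` frames are NaN.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    head_tail = np.asarray(head_tail, dtype=np.float64)
    vel, _ = _velocities(centroids, fps, offset)
    speed = np.linalg.norm(vel, axis=1)
    dots = np.einsum("ij,ij->i", vel, head_tail)
    sign = np.where(dots < 0, -1.0, 1.0)
    return sign * speed


# ---------------------------------------------------------------------------
# State cascade


def bent_posture(
    midline: np.ndarray, head: str, angle_deg: float = DEFAULT_TURN_ANGLE_DEG
) -> bool:
    """Turn-geometry branch: sharply folded but not yet self-intersecting.

    True iff the midpoint-to-tail vector is longer than the midpoint-to-head
    vector and the angle between the two vectors is below ``angle_deg`` —
    i.e. head and tail point the same way from the body's arc midpoint.
    """
    mid = arc_midpoint(midline)
    head_pt = midline[-1] if head == "last" else midline[0]
    tail_pt = midline[0] if head == "last" else midline[-1]
    to_head = head_pt - mid
    to_tail = tail_pt - mid
    nh, nt = np.linalg.norm(to_head), np.linalg.norm(to_tail)
    if nt <= nh or nh == 0 or nt == 0:
        return False
    cosang = float(np.dot(to_head, to_tail)) / (nh * nt)
    return cosang > math.cos(math.radians(angle_deg))


def _pause_mask(signed: np.ndarray, fps: float, threshold: float, min_s: float) -> np.ndarray:
    """Frames inside a maximal sub-threshold run lasting >= min_s."""
    slow = np.abs(signed) < threshold
    slow &= ~np.isnan(signed)
    min_frames = math.ceil(min_s * fps)
    out = np.zeros(len(signed), dtype=bool)
    i = 0
    n = len(signed)
    while i < n:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j < n and slow[j]:
            j += 1
        if j - i >= min_frames:
            out[i:j] = True
        i = j
    return out


def classify_states(
    track: WormTrack,
    offset: int = DEFAULT_OFFSET,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    pause_min_s: float = DEFAULT_PAUSE_MIN_S,
    turn_angle_deg: float = DEFAULT_TURN_ANGLE_DEG,
    intersect_ratio: float = DEFAULT_INTERSECT_RATIO,
) -> WormStateTrack:
    """Run the full rule cascade on a worm track.

    Precedence: turn > pause > forward/reverse, with *turn* from
    self-intersection or sharply bent posture, *pause* from sustained
    sub-threshold speed, and forward/reverse from the speed sign.
    """
    n = len(track.centroids)
    self_int = np.array(
        [
            self_intersecting(track.areas[t], track.perimeters[t], intersect_ratio)
            for t in range(n)
        ]
    )
    oriented = align_midlines(track.midlines)
    head = assign_head(oriented, track.centroids, track.fps, offset)
    ht = _head_tail_vectors(oriented, head)
    signed = signed_speed(track.centroids, ht, track.fps, offset)

    turn = self_int.copy()
    for t, m in enumerate(oriented):
        if m is None or turn[t]:
            continue
        if bent_posture(m, head, turn_angle_deg):
            turn[t] = True

    pause = _pause_mask(signed, track.fps, speed_threshold, pause_min_s) & ~turn
    states = np.full(n, UNDEFINED, dtype=object)
    defined = ~np.isnan(signed)
    states[turn] = "turn"
    rest = defined & ~turn & ~pause
    states[pause] = "pause"
    states[rest & (signed > 0)] = "forward"
    states[rest & (signed < 0)] = "reverse"
    states[rest & (signed == 0)] = "forward"  # zero-speed tie outside a pause run
    return WormStateTrack(states=states.astype(str), fps=track.fps, signed_speed=signed)


def track_from_masks(
    masks: np.ndarray,
    centroids_um: np.ndarray,
    fps: float = DEFAULT_FPS,
    um_per_px: float = 1.0,
    intersect_ratio: float = DEFAULT_INTERSECT_RATIO,
    stats_um_per_px: float = 1.0,
) -> WormTrack:
    """Build a :class:`WormTrack` from per-frame masks and centroids.

    Midlines are extracted (in um, via ``um_per_px``) wherever the posture
    is not self-intersecting and set to None elsewhere.  Contour statistics
    are scaled by ``stats_um_per_px``, which defaults to 1 (pixel units)
    because the default intersection threshold is calibrated for pixel
    geometry at the original tracking magnification; pass the real scale if
    the threshold has been recalibrated to physical units.
    """
    n = len(masks)
    if len(centroids_um) != n:
        raise ValueError("masks and centroids disagree in length")
    areas = np.empty(n)
    perims = np.empty(n)
    midlines: list[np.ndarray | None] = []
    for t in range(n):
        areas[t], perims[t] = contour_stats(masks[t], stats_um_per_px)
        if self_intersecting(areas[t], perims[t], intersect_ratio):
            midlines.append(None)
        else:
            try:
                midlines.append(extract_midline(masks[t], um_per_px))
            except ValueError as err:
                warnings.warn(f"frame {t}: midline extraction failed ({err})", stacklevel=2)
                midlines.append(None)
    return WormTrack(
        centroids=np.asarray(centroids_um, dtype=np.float64),
        areas=areas,
        perimeters=perims,
        midlines=midlines,
        fps=fps,
    )


def states_to_labeltrack(
    wst: WormStateTrack, catalog: ClassCatalog, video_id: str = "worm"
) -> FrameLabelTrack:
    """Bridge heuristic states into the standard frame-label representation.

    The catalog must contain the four locomotor states; undefined frames map
    to the background class.
    """
    for s in WORM_STATES:
        catalog.index(s)
    targets = np.array(
        [
            catalog.background_index if s == UNDEFINED else catalog.index(s)
            for s in wst.states
        ],
        dtype=np.int64,
    )
    return FrameLabelTrack(video_id, wst.fps, len(targets), targets)
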