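"""Seeded synthetic fixtures with known ground truth.

Real behavioral recordings cannot ship with the package, so every pipeline
stage is exercised against generated data whose labels are exact by
construction:

* *classification fixtures* — short clips whose per-frame class is visually
  separable by both appearance (color-coded patterns) and motion: a static
  noise background for "other", a single moving blob, an orbiting blob
  pair, a drifting stripe.  The generator emits the video, the exact
  frame-label track, and an equivalent timestamped event table;
* *multi-label fixtures* — several entities with independent behavior
  schedules rendered in one scene, pooled into per-frame label sets;
* *worm fixtures* — centroid + mask sequences integrating scripted
  locomotor states (forward/reverse/turn/pause) with geometry that respects
  the rule thresholds by a stated margin (crawl speeds 150 um/s vs the
  50 um/s pause threshold; tube masks with area:perimeter ~ 2.3 vs coiled
  discs at ~ 6 against the 3.3 intersection threshold).

Noise model: per-frame Gaussian pixel noise plus a slow illumination drift —
enough to exercise augmentation robustness without defeating separability.
All fixtures are bit-reproducible under their seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from feral.labels import (
    MULTI_LABEL,
    AnnotationEvent,
    ClassCatalog,
    FrameLabelTrack,
    pool_entity_labels,
    write_events_csv,
    write_label_json,
)
from feral.video import write_video

__all__ = [
    "FixtureScript",
    "ClassificationFixture",
    "make_classification_fixture",
    "make_multilabel_fixture",
    "make_worm_fixture",
    "default_worm_script",
    "WormFixture",
]

#: foreground rendering styles, assigned to foreground classes in catalog order
_STYLES = ("moving_blob", "orbiting_pair", "stripe")

# color channel emphasised by each style (appearance separability)
_STYLE_COLOR = {"moving_blob": 0, "orbiting_pair": 1, "stripe": 2}


@dataclass(frozen=True)
class FixtureScript:
    """Class schedule for one synthetic clip.

    ``schedule`` is a list of (class_name, start_frame, end_frame) with
    half-open frame intervals; for a single-label script the segments must
    tile [0, n_frames) without overlap.
    """

    schedule: tuple[tuple[str, int, int], ...]
    fps: float = 10.0
    size: int = 32
    seed: int = 0
    video_id: str = "fixture"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "schedule", tuple((str(c), int(a), int(b)) for c, a, b in self.schedule)
        )
        for c, a, b in self.schedule:
            if b <= a or a < 0:
                raise ValueError(f"bad segment {c}: [{a}, {b})")

    @property
    def n_frames(self) -> int:
        return max(b for _, _, b in self.schedule)

    def validate_tiling(self) -> None:
        segs = sorted((a, b) for _, a, b in self.schedule)
        cursor = 0
        for a, b in segs:
            if a != cursor:
                raise ValueError(f"schedule gap/overlap at frame {cursor} (next segment {a})")
            cursor = b
        if cursor != self.n_frames:
            raise ValueError("schedule does not tile the clip")


def _gaussian_blob(size: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * radius**2)))


def _render_style(style: str, f_rel: int, size: int) -> np.ndarray:
    """One foreground pattern frame (H, W, 3) in [0, 1]; motion is phase f_rel."""
    frame = np.zeros((size, size, 3))
    ch = _STYLE_COLOR[style]
    if style == "moving_blob":
        cx = (0.15 + 0.7 * ((f_rel % 24) / 24.0)) * size
        frame[..., ch] = _gaussian_blob(size, cx, size / 2, size / 10)
    elif style == "orbiting_pair":
        angle = 2 * math.pi * (f_rel % 20) / 20.0
        r = size * 0.25
        for sgn in (1, -1):
            cx = size / 2 + sgn * r * math.cos(angle)
            cy = size / 2 + sgn * r * math.sin(angle)
            frame[..., ch] += _gaussian_blob(size, cx, cy, size / 12)
    elif style == "stripe":
        y0 = (f_rel % 16) / 16.0 * size
        yy = np.arange(size)
        band = np.exp(-((yy - y0) ** 2) / (2 * (size / 12) ** 2))
        frame[..., ch] = band[:, None]
    else:
        raise ValueError(f"unknown style {style!r}")
    return np.clip(frame, 0.0, 1.0)


def _style_map(catalog: ClassCatalog) -> dict[str, str]:
    fg = [catalog.names[i] for i in catalog.foreground_indices()]
    return {name: _STYLES[i % len(_STYLES)] for i, name in enumerate(fg)}


@dataclass
class ClassificationFixture:
    frames: np.ndarray  # (n, S, S, 3) uint8
    track: FrameLabelTrack
    catalog: ClassCatalog
    events: list[AnnotationEvent]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vid = self.track.video_id
        paths = {
            "video": out_dir / f"{vid}.tiff",
            "labels": out_dir / f"{vid}.labels.json",
            "events": out_dir / f"{vid}.events.csv",
        }
        write_video(paths["video"], self.frames, fps=self.track.fps, video_id=vid)
        write_label_json(self.track, self.catalog, paths["labels"])
        write_events_csv(self.events, paths["events"])
        return paths


def make_classification_fixture(script: FixtureScript) -> ClassificationFixture:
    """Render a single-label clip whose classes are separable by design.

    The background class renders as static noise; each foreground class gets
    a distinct color-coded motion pattern.  Labels match the script exactly,
    and an equivalent timestamped event list is returned for round-trip
    tests of the annotation parser.
    """
    script.validate_tiling()
    class_names = []
    for c, _, _ in script.schedule:
        if c not in class_names:
            class_names.append(c)
    catalog = ClassCatalog(names=tuple(class_names), mode="single_label")
    styles = _style_map(catalog)
    rng = np.random.default_rng(script.seed)
    n, S = script.n_frames, script.size

    base_noise = rng.normal(0.5, 0.04, size=(S, S, 3))
    drift = 1.0 + 0.05 * np.sin(2 * math.pi * np.arange(n) / max(n, 1))
    frames = np.empty((n, S, S, 3))
    targets = np.empty(n, dtype=np.int64)
    for name, a, b in script.schedule:
        idx = catalog.index(name)
        targets[a:b] = idx
        for f in range(a, b):
            canvas = base_noise + rng.normal(0.0, 0.02, size=(S, S, 3))
            if name != catalog.background_name:
                canvas = canvas * 0.4 + _render_style(styles[name], f - a, S)
            frames[f] = np.clip(canvas * drift[f], 0.0, 1.0)
    frames_u8 = np.rint(frames * 255).astype(np.uint8)
    track = FrameLabelTrack(script.video_id, script.fps, n, targets)
    events = [
        AnnotationEvent(script.video_id, name, a / script.fps, b / script.fps)
        for name, a, b in script.schedule
        if name != catalog.background_name
    ]
    events.sort(key=lambda e: e.start_s)
    return ClassificationFixture(frames=frames_u8, track=track, catalog=catalog, events=events)


def make_multilabel_fixture(
    entity_schedules: list[tuple[tuple[str, int, int], ...]],
    n_frames: int,
    class_names: tuple[str, ...],
    fps: float = 10.0,
    size: int = 32,
    seed: int = 0,
    video_id: str = "multilabel-fixture",
) -> tuple[np.ndarray, FrameLabelTrack, ClassCatalog, list[FrameLabelTrack]]:
    """Render several entities with independent schedules in one scene.

    Each entity occupies its own image quadrant and shows its scheduled
    behavior's pattern there; frame targets are the pooled union of all
    entities' behaviors.  Returns (frames, pooled track, catalog,
    per-entity tracks).
    """
    catalog = ClassCatalog(names=class_names, mode=MULTI_LABEL)
    styles = _style_map(catalog)
    rng = np.random.default_rng(seed)
    frames = np.clip(rng.normal(0.5, 0.04, size=(n_frames, size, size, 3)), 0, 1)
    half = size // 2
    offsets = [(0, 0), (0, half), (half, 0), (half, half)]
    entity_tracks = []
    for ei, schedule in enumerate(entity_schedules):
        oy, ox = offsets[ei % len(offsets)]
        targets = np.zeros((n_frames, catalog.n_classes), dtype=np.uint8)
        for name, a, b in schedule:
            idx = catalog.index(name)
            targets[a:b, idx] = 1
            for f in range(a, b):
                tile = _render_style(styles[name], f - a, half)
                region = frames[f, oy : oy + half, ox : ox + half]
                frames[f, oy : oy + half, ox : ox + half] = np.clip(region * 0.4 + tile, 0, 1)
        entity_tracks.append(FrameLabelTrack(video_id, fps, n_frames, targets))
    pooled = pool_entity_labels(entity_tracks, catalog)
    frames_u8 = np.rint(frames * 255).astype(np.uint8)
    return frames_u8, pooled, catalog, entity_tracks


# ---------------------------------------------------------------------------
# Worm fixtures


#: scripted centroid speeds per state, um/s (signed along the head direction);
#: margins vs the 50 um/s pause threshold are deliberate
_WORM_SPEEDS = {"forward": 150.0, "reverse": -150.0, "pause": 8.0, "turn": 8.0}

_WORM_LEN_PX = 60
_WORM_WIDTH_PX = 5  # tube ratio ~ w/2 = 2.5 < 3.3 (not self-intersecting)
_COIL_RADIUS_PX = 12  # disc ratio ~ r/2 = 6 > 3.3 (self-intersecting)
_MASK_SIZE = 96


def default_worm_script() -> list[tuple[str, int]]:
    """A forward-dominated state script (the animal crawls forward most often)."""
    return [
        ("forward", 60),
        ("reverse", 12),
        ("forward", 30),
        ("pause", 12),
        ("forward", 30),
        ("turn", 12),
        ("forward", 30),
    ]


def _tube_mask(size: int, length: int, width: int, heading: np.ndarray) -> np.ndarray:
    """Worm-centered straight tube mask along ``heading``."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    dx, dy = xx - c, yy - c
    along = dx * heading[0] + dy * heading[1]
    across = -dx * heading[1] + dy * heading[0]
    return (np.abs(along) <= length / 2) & (np.abs(across) <= width / 2)


def _disc_mask(size: int, radius: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


@dataclass
class WormFixture:
    masks: np.ndarray  # (n, H, W) bool, worm-centered windows
    centroids_um: np.ndarray  # (n, 2) absolute positions
    truth_states: np.ndarray  # (n,) scripted state per frame
    fps: float
    um_per_px: float
    heading: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))


def make_worm_fixture(
    script: list[tuple[str, int]] | None = None,
    noise_um: float = 0.0,
    seed: int = 0,
    fps: float = 6.0,
    um_per_px: float = 5.0,
) -> WormFixture:
    """Integrate scripted locomotor states into a centroid + mask sequence.

    Centroids integrate the scripted signed speed along a fixed heading at
    ``fps``; masks are worm-centered tubes (bent into self-intersecting
    discs during scripted turns).  ``noise_um`` adds Gaussian jitter to the
    centroids.  Segments shorter than the pause-duration rule trigger a
    warning since the classifier cannot recover them as pauses.
    """
    script = script or default_worm_script()
    rng = np.random.default_rng(seed)
    min_pause = math.ceil(0.5 * fps)
    for state, length in script:
        if state not in _WORM_SPEEDS:
            raise ValueError(f"unknown state {state!r}")
        if state == "pause" and length < min_pause:
            warnings.warn(
                f"pause segment of {length} frames is shorter than the "
                f"{min_pause}-frame duration rule and will not be recovered",
                stacklevel=2,
            )
    heading = np.array([1.0, 0.0])
    states: list[str] = []
    for state, length in script:
        states.extend([state] * length)
    n = len(states)
    centroids = np.zeros((n, 2))
    pos = np.zeros(2)
    dt = 1.0 / fps
    for t, state in enumerate(states):
        centroids[t] = pos
        pos = pos + _WORM_SPEEDS[state] * dt * heading
    if noise_um > 0:
        centroids = centroids + rng.normal(0.0, noise_um, size=centroids.shape)

    tube = _tube_mask(_MASK_SIZE, _WORM_LEN_PX, _WORM_WIDTH_PX, heading)
    disc = _disc_mask(_MASK_SIZE, _COIL_RADIUS_PX)
    masks = np.stack([disc if s == "turn" else tube for s in states])
    return WormFixture(
        masks=masks,
        centroids_um=centroids,
        truth_states=np.array(states),
        fps=fps,
        um_per_px=um_per_px,
        heading=heading,
    )
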