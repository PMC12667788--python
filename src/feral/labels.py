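"""Frame-aligned behavioral labels.

Behavioral annotations usually arrive as timestamped bout tables exported from
annotation software (BORIS, ELAN, or plain spreadsheets): one row per bout of
behavior with a start and end time in seconds.  Training and evaluation both
need something else entirely — one categorical target per video frame.  This
module converts between the two representations and defines the on-disk JSON
schema ("feral-labels/1") used by the rest of the pipeline.

Conventions (applied everywhere):

* frames are 0-based and frame ``f`` represents the instant ``f / fps``;
* bout intervals are half-open ``[start_s, end_s)``, so boundary frames are
  never double-labeled;
* in single-label mode every frame gets exactly one class, with uncovered
  frames assigned the background ("other") class;
* in multi-label mode a frame's target is the set of all covering behaviors
  (possibly empty).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LABEL_SCHEMA = "feral-labels/1"

SINGLE_LABEL = "single_label"
MULTI_LABEL = "multi_label"

#: column layouts for supported event-table dialects, modeled on the common
#: export defaults of each tool (video id, behavior, start s, end s)
_DIALECTS = {
    "generic_csv": {
        "sep": ",",
        "video_id": ("video_id", "video"),
        "behavior": ("behavior", "label"),
        "start_s": ("start_s", "start"),
        "end_s": ("end_s", "end", "stop"),
    },
    "boris_csv": {
        "sep": ",",
        "video_id": ("Observation id", "Media file path"),
        "behavior": ("Behavior",),
        "start_s": ("Start (s)",),
        "end_s": ("Stop (s)",),
    },
    "elan_tsv": {
        "sep": "\t",
        "video_id": ("File", "video_id"),
        "behavior": ("Annotation", "Tier"),
        "start_s": ("Begin Time (s)", "Begin Time - ss.msec"),
        "end_s": ("End Time (s)", "End Time - ss.msec"),
    },
}


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered behavior classes plus the labeling mode.

    In single-label mode one class is the designated background
    ("other"/no-label) class that absorbs uncovered frames; multi-label mode
    has no background class (an uncovered frame is simply the empty set).
    """

    names: tuple[str, ...]
    mode: str = SINGLE_LABEL
    background_name: str | None = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        if any(not n for n in self.names):
            raise ValueError("class names must be non-empty")
        if self.mode == SINGLE_LABEL:
            if self.background_name is None:
                raise ValueError("single_label mode requires a background class")
            if self.background_name not in self.names:
                # background is appended if absent: every single-label catalog
                # needs an "other" class for uncovered frames
                object.__setattr__(self, "names", self.names + (self.background_name,))
        elif self.mode == MULTI_LABEL:
            object.__setattr__(self, "background_name", None)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    @property
    def background_index(self) -> int:
        if self.background_name is None:
            raise ValueError("multi_label catalog has no background class")
        return self.names.index(self.background_name)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"behavior {name!r} not in catalog {self.names}") from None

    def foreground_indices(self) -> list[int]:
        """Indices of all classes except the background (all, in multi-label)."""
        if self.mode == MULTI_LABEL:
            return list(range(self.n_classes))
        bg = self.background_index
        return [i for i in range(self.n_classes) if i != bg]


@dataclass(frozen=True)
class AnnotationEvent:
    """One annotated bout: a behavior on a half-open time interval."""

    video_id: str
    behavior: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"negative start {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValueError(f"inverted/empty interval [{self.start_s}, {self.end_s})")


@dataclass
class FrameLabelTrack:
    """Per-frame targets for one video at a stated frame rate.

    ``targets`` is an int array of class indices, shape ``(n_frames,)``, in
    single-label mode, or a {0,1} uint8 array of shape ``(n_frames, C)`` in
    multi-label mode.
    """

    video_id: str
    fps: float
    n_frames: int
    targets: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self.targets = np.asarray(self.targets)
        if len(self.targets) != self.n_frames:
            raise ValueError(
                f"targets has {len(self.targets)} entries, declared n_frames={self.n_frames}"
            )
        if self.targets.ndim == 2:
            bad = ~np.isin(self.targets, (0, 1))
            if bad.any():
                raise ValueError("multi_label targets must be {0,1}-valued")
            self.targets = self.targets.astype(np.uint8)
        elif self.targets.ndim == 1:
            self.targets = self.targets.astype(np.int64)
        else:
            raise ValueError("targets must be 1-D (single) or 2-D (multi)")

    @property
    def mode(self) -> str:
        return SINGLE_LABEL if self.targets.ndim == 1 else MULTI_LABEL

    def validate_against(self, catalog: ClassCatalog) -> None:
        if self.mode != catalog.mode:
            raise ValueError(f"track mode {self.mode} != catalog mode {catalog.mode}")
        if self.mode == SINGLE_LABEL:
            if self.targets.min() < 0 or self.targets.max() >= catalog.n_classes:
                raise ValueError("class index out of catalog range")
        elif self.targets.shape[1] != catalog.n_classes:
            raise ValueError("target width != number of classes")

    def class_counts(self, catalog: ClassCatalog) -> np.ndarray:
        """Frames per class (single-label: a partition of n_frames)."""
        self.validate_against(catalog)
        if self.mode == SINGLE_LABEL:
            return np.bincount(self.targets, minlength=catalog.n_classes)
        return self.targets.sum(axis=0).astype(np.int64)


def _resolve_column(df: pd.DataFrame, candidates: Sequence[str], what: str) -> str:
    for cand in candidates:
        if cand in df.columns:
            return cand
    raise ValueError(f"no column for {what}: tried {candidates}, file has {list(df.columns)}")


def parse_events(path: str | Path, dialect: str = "generic_csv") -> list[AnnotationEvent]:
    """Parse a timestamped event table into a sorted list of events.

    Rows with negative or inverted intervals are rejected with a diagnostic
    naming the offending row number (1-based, excluding the header).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    spec = _DIALECTS[dialect]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=spec["sep"])
    if df.empty:
        return []
    cols = {
        key: _resolve_column(df, spec[key], key)
        for key in ("video_id", "behavior", "start_s", "end_s")
    }
    events = []
    for row_num, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        start = float(rec[cols["start_s"]])
        end = float(rec[cols["end_s"]])
        try:
            events.append(
                AnnotationEvent(
                    video_id=str(rec[cols["video_id"]]),
                    behavior=str(rec[cols["behavior"]]),
                    start_s=start,
                    end_s=end,
                )
            )
        except ValueError as err:
            raise ValueError(f"row {row_num} of {path.name}: {err}") from None
    events.sort(key=lambda e: (e.video_id, e.start_s, e.end_s))
    return events


def _frame_span(start_s: float, end_s: float, fps: float, n_frames: int) -> tuple[int, int]:
    """Frames f with f/fps in [start_s, end_s), clipped to [0, n_frames)."""
    # tiny epsilon guards against float noise in start_s * fps landing just
    # above an integer frame instant
    first = int(np.ceil(start_s * fps - 1e-9))
    stop = int(np.ceil(end_s * fps - 1e-9))
    return max(first, 0), min(stop, n_frames)


def events_to_frames(
    events: Iterable[AnnotationEvent],
    fps: float,
    n_frames: int,
    catalog: ClassCatalog,
    video_id: str | None = None,
) -> FrameLabelTrack:
    """Rasterize timestamped events onto the frame grid.

    Frame ``f`` receives behavior ``b`` iff ``f/fps`` lies in one of ``b``'s
    intervals.  Single-label conflicts (two behaviors covering one frame) are
    resolved deterministically: the event with the later start wins, ties
    broken toward the earlier catalog position; a warning reports how many
    frames were contested.
    """
    if fps <= 0 or n_frames <= 0:
        raise ValueError("fps and n_frames must be positive")
    events = list(events)
    if video_id is None:
        ids = {e.video_id for e in events}
        if len(ids) > 1:
            raise ValueError(f"events span multiple videos {sorted(ids)}; pass video_id")
        video_id = ids.pop() if ids else "video"
    for e in events:
        catalog.index(e.behavior)  # unknown behaviors are an error, not a drop

    if catalog.mode == MULTI_LABEL:
        targets = np.zeros((n_frames, catalog.n_classes), dtype=np.uint8)
        for e in events:
            lo, hi = _frame_span(e.start_s, e.end_s, fps, n_frames)
            targets[lo:hi, catalog.index(e.behavior)] = 1
        return FrameLabelTrack(video_id, fps, n_frames, targets)

    targets = np.full(n_frames, catalog.background_index, dtype=np.int64)
    # later-start-wins: apply in start order; equal starts applied in reverse
    # catalog order so the earlier catalog position overwrites last
    ordered = sorted(events, key=lambda e: (e.start_s, -catalog.index(e.behavior)))
    contested = np.zeros(n_frames, dtype=bool)
    covered = np.zeros(n_frames, dtype=np.int64)
    for e in ordered:
        lo, hi = _frame_span(e.start_s, e.end_s, fps, n_frames)
        idx = catalog.index(e.behavior)
        seg = targets[lo:hi]
        contested[lo:hi] |= (covered[lo:hi] > 0) & (seg != idx)
        seg[:] = idx
        covered[lo:hi] += 1
    n_contested = int(contested.sum())
    if n_contested:
        warnings.warn(
            f"{video_id}: {n_contested} frame(s) covered by simultaneous events; "
            "resolved by later-start-wins",
            stacklevel=2,
        )
    return FrameLabelTrack(video_id, fps, n_frames, targets)


def pool_entity_labels(
    per_entity_tracks: Sequence[FrameLabelTrack], catalog: ClassCatalog
) -> FrameLabelTrack:
    """Union per-entity multi-label tracks into one frame-level target.

    Used when several animals are annotated independently in the same frame
    (e.g. one ape sitting while another climbs): the pooled frame target is
    the set of all behaviors shown by any entity.
    """
    if catalog.mode != MULTI_LABEL:
        raise ValueError("pooling entity labels requires a multi_label catalog")
    if not per_entity_tracks:
        raise ValueError("no tracks to pool")
    first = per_entity_tracks[0]
    for t in per_entity_tracks:
        t.validate_against(catalog)
        if (t.video_id, t.fps, t.n_frames) != (first.video_id, first.fps, first.n_frames):
            raise ValueError("entity tracks disagree on video_id/fps/n_frames")
    pooled = np.zeros_like(first.targets)
    for t in per_entity_tracks:
        pooled |= t.targets
    return FrameLabelTrack(first.video_id, first.fps, first.n_frames, pooled)


def track_to_events(track: FrameLabelTrack, catalog: ClassCatalog) -> list[AnnotationEvent]:
    """Maximal-run decomposition of a track back into timestamped events.

    Background frames (single-label) and empty sets (multi-label) produce no
    events.  Rasterizing the result with :func:`events_to_frames` reproduces
    the track exactly (round-trip identity).
    """
    track.validate_against(catalog)
    events: list[AnnotationEvent] = []
    fps = track.fps

    def runs(binary: np.ndarray) -> list[tuple[int, int]]:
        padded = np.concatenate(([0], binary.astype(np.int8), [0]))
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        return list(zip(starts, ends))

    if track.mode == SINGLE_LABEL:
        for c in range(catalog.n_classes):
            if c == catalog.background_index:
                continue
            for lo, hi in runs(track.targets == c):
                events.append(AnnotationEvent(track.video_id, catalog.names[c], lo / fps, hi / fps))
    else:
        for c in range(catalog.n_classes):
            for lo, hi in runs(track.targets[:, c] == 1):
                events.append(AnnotationEvent(track.video_id, catalog.names[c], lo / fps, hi / fps))
    events.sort(key=lambda e: (e.start_s, e.behavior))
    return events


def write_events_csv(events: Sequence[AnnotationEvent], path: str | Path) -> None:
    """Write events as a generic_csv dialect table."""
    df = pd.DataFrame(
        {
            "video_id": [e.video_id for e in events],
            "behavior": [e.behavior for e in events],
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
        }
    )
    df.to_csv(path, index=False)


def write_label_json(
    tracks: FrameLabelTrack | Sequence[FrameLabelTrack],
    catalog: ClassCatalog,
    path: str | Path,
) -> None:
    """Serialize tracks + catalog to the versioned frame-label JSON schema."""
    if isinstance(tracks, FrameLabelTrack):
        tracks = [tracks]
    videos = {}
    for t in tracks:
        t.validate_against(catalog)
        if catalog.mode == SINGLE_LABEL:
            labels = t.targets.tolist()
        else:
            labels = [np.flatnonzero(row).tolist() for row in t.targets]
        videos[t.video_id] = {"fps": t.fps, "n_frames": t.n_frames, "labels": labels}
    doc = {
        "schema": LABEL_SCHEMA,
        "mode": catalog.mode,
        "class_names": list(catalog.names),
        "background": catalog.background_name,
        "videos": videos,
    }
    Path(path).write_text(json.dumps(doc))


def read_label_json(path: str | Path) -> tuple[list[FrameLabelTrack], ClassCatalog]:
    """Read the frame-label JSON schema back into tracks + catalog.

    Behavior *names*, not positions, are authoritative: the catalog is rebuilt
    from the file's class_names so permuting the stored order (with
    consistently permuted indices) yields a semantically identical labeling.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != LABEL_SCHEMA:
        raise ValueError(f"schema mismatch: expected {LABEL_SCHEMA!r}, got {doc.get('schema')!r}")
    catalog = ClassCatalog(
        names=tuple(doc["class_names"]),
        mode=doc["mode"],
        background_name=doc.get("background"),
    )
    tracks = []
    for vid, rec in doc["videos"].items():
        n_frames = int(rec["n_frames"])
        labels = rec["labels"]
        if len(labels) != n_frames:
            raise ValueError(
                f"{vid}: file has {len(labels)} labels but declares n_frames={n_frames}"
            )
        if catalog.mode == SINGLE_LABEL:
            targets = np.asarray(labels, dtype=np.int64)
        else:
            targets = np.zeros((n_frames, catalog.n_classes), dtype=np.uint8)
            for f, active in enumerate(labels):
                targets[f, active] = 1
        tracks.append(FrameLabelTrack(vid, float(rec["fps"]), n_frames, targets))
    return tracks, catalog


def remap_track(
    track: FrameLabelTrack, src: ClassCatalog, dst: ClassCatalog
) -> FrameLabelTrack:
    """Re-index a track from one catalog's class order to another's by name."""
    track.validate_against(src)
    if set(src.names) != set(dst.names) or src.mode != dst.mode:
        raise ValueError("catalogs must contain the same class names and mode")
    perm = np.array([dst.index(name) for name in src.names])
    if track.mode == SINGLE_LABEL:
        targets = perm[track.targets]
    else:
        targets = np.zeros_like(track.targets)
        targets[:, perm] = track.targets
    return FrameLabelTrack(track.video_id, track.fps, track.n_frames, targets)
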