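"""Seekable frame access and video standardization.

Training needs fast random access to arbitrary frames, which many
distribution codecs cannot provide (they only support sequential decoding).
The pipeline therefore standardizes recordings once, up front, into a
seekable container resized to a fixed square resolution, and all downstream
stages read frames by absolute index through :func:`read_frames`.

Supported seekable containers (all lossless, all frame-indexable):

* multipage TIFF (``.tif``/``.tiff``) — the preferred interchange format;
* a directory of numbered PNG frames;
* a ``.npy`` stack of shape (n_frames, H, W, 3), dtype uint8.

Frame rate does not fit in these containers, so each video carries a JSON
sidecar (``<name>.meta.json``) recording fps.  Compressed distribution
formats (MP4/AVI/MOV) must be transcoded to one of the above with an
external tool (e.g. ffmpeg); :func:`preprocess_video` raises a clear error
with that hint when handed one.

Pixel contract: frames are stored as 8-bit RGB and converted to [0, 1]
floats only at the model boundary (:meth:`FrameBlock.as_float`); resizing is
plain bilinear squash to ``size x size`` without aspect-ratio preservation.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from skimage.transform import resize as _sk_resize

__all__ = [
    "VideoMeta",
    "FrameBlock",
    "VideoFormatError",
    "probe",
    "read_frames",
    "write_video",
    "preprocess_video",
]

DEFAULT_SIZE = 256
_SEEKABLE_SUFFIXES = {".tif", ".tiff", ".npy"}
_UNSEEKABLE_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv", ".webm"}
_FRAME_SUFFIXES = {".png", ".bmp", ".jpg", ".jpeg"}


class VideoFormatError(RuntimeError):
    """Raised for unreadable, unsupported, or non-video inputs."""


@dataclass(frozen=True)
class VideoMeta:
    video_id: str
    path: Path
    fps: float
    n_frames: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class FrameBlock:
    """A stack of decoded frames plus the absolute indices they came from."""

    indices: tuple[int, ...]
    pixels: np.ndarray = field(repr=False)  # (n, H, W, 3) uint8

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.pixels):
            raise ValueError("indices and pixels disagree in length")

    def as_float(self) -> np.ndarray:
        """Pixels as float64 in [0, 1] (the model-boundary representation)."""
        return self.pixels.astype(np.float64) / 255.0


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json") if path.is_dir() else path.with_suffix(
        path.suffix + ".meta.json"
    )


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _write_sidecar(path: Path, fps: float, video_id: str) -> None:
    _sidecar_path(path).write_text(json.dumps({"fps": fps, "video_id": video_id}))


def _frame_files(directory: Path) -> list[Path]:
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
    if not files:
        raise VideoFormatError(f"{directory} contains no frame images")
    return files


def _to_rgb_uint8(frame: np.ndarray) -> np.ndarray:
    if frame.dtype != np.uint8:
        raise VideoFormatError(f"expected 8-bit frames, got dtype {frame.dtype}")
    if frame.ndim == 2:
        frame = np.stack([frame] * 3, axis=-1)
    if frame.shape[-1] == 4:  # drop alpha
        frame = frame[..., :3]
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise VideoFormatError(f"cannot interpret frame of shape {frame.shape} as RGB")
    return frame


def probe(path: str | Path) -> VideoMeta:
    """Read exact metadata for a seekable video (full page scan for TIFF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _read_sidecar(path)
    fps = float(sidecar.get("fps", 30.0))
    video_id = sidecar.get("video_id", path.stem)

    if path.is_dir():
        files = _frame_files(path)
        first = _to_rgb_uint8(iio.imread(files[0]))
        n, h, w = len(files), first.shape[0], first.shape[1]
    elif path.suffix.lower() in {".tif", ".tiff"}:
        try:
            with tifffile.TiffFile(path) as tf:
                n = len(tf.pages)
                first = _to_rgb_uint8(tf.pages[0].asarray())
        except Exception as err:  # corrupt container
            raise VideoFormatError(f"cannot read TIFF {path}: {err}") from err
        h, w = first.shape[0], first.shape[1]
        if n < 2:
            raise VideoFormatError(f"{path} has a single page: a still image, not a video")
    elif path.suffix.lower() == ".npy":
        arr = np.load(path, mmap_mode="r")
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise VideoFormatError(f"{path}: expected (n, H, W, 3) stack, got {arr.shape}")
        n, h, w = arr.shape[0], arr.shape[1], arr.shape[2]
    elif path.suffix.lower() in _UNSEEKABLE_SUFFIXES:
        raise VideoFormatError(
            f"{path.suffix} containers are not seekable here; transcode to multipage TIFF "
            "first (e.g. `ffmpeg -i in.mp4 out%06d.png` then `feral preprocess`)"
        )
    elif path.suffix.lower() in _FRAME_SUFFIXES:
        raise VideoFormatError(f"{path} is a still image, not a video")
    else:
        raise VideoFormatError(f"unsupported container {path.suffix!r}")
    return VideoMeta(video_id=video_id, path=path, fps=fps, n_frames=n, width=w, height=h)


def _decode(meta: VideoMeta, unique_sorted: np.ndarray) -> np.ndarray:
    path = meta.path
    if path.is_dir():
        files = _frame_files(path)
        return np.stack([_to_rgb_uint8(iio.imread(files[i])) for i in unique_sorted])
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            return np.stack([_to_rgb_uint8(tf.pages[i].asarray()) for i in unique_sorted])
    if path.suffix.lower() == ".npy":
        arr = np.load(path, mmap_mode="r")
        return np.array(arr[unique_sorted])
    raise VideoFormatError(f"unsupported container {path.suffix!r}")


def resize_frame(frame: np.ndarray, size: int) -> np.ndarray:
    """Bilinear squash of one RGB frame to size x size, back to uint8."""
    if frame.shape[0] == size and frame.shape[1] == size:
        return frame
    out = _sk_resize(
        frame.astype(np.float64),
        (size, size),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def read_frames(meta: VideoMeta, indices, size: int | None = None) -> FrameBlock:
    """Decode the frames at ``indices`` (sorted, repeats honored), optionally resized.

    A pure function of (file, indices): repeated calls return identical pixel
    content.
    """
    idx = np.asarray(list(indices), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("no indices requested")
    if (np.diff(idx) < 0).any():
        raise ValueError("indices must be sorted ascending")
    if idx[0] < 0 or idx[-1] >= meta.n_frames:
        raise IndexError(f"index out of range [0, {meta.n_frames}) in {idx[[0, -1]]}")
    unique = np.unique(idx)
    frames = _decode(meta, unique)
    if size is not None:
        frames = np.stack([resize_frame(f, size) for f in frames])
    pos = np.searchsorted(unique, idx)
    return FrameBlock(indices=tuple(int(i) for i in idx), pixels=frames[pos])


def write_video(
    path: str | Path, frames: np.ndarray, fps: float, video_id: str | None = None
) -> VideoMeta:
    """Write an (n, H, W, 3) uint8 stack as a multipage TIFF + fps sidecar."""
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.dtype != np.uint8:
        raise ValueError(f"expected (n, H, W, 3) uint8 stack, got {frames.shape} {frames.dtype}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, frames, photometric="rgb")
    _write_sidecar(path, fps, video_id or path.stem)
    return probe(path)


def preprocess_video(
    in_path: str | Path,
    out_path: str | Path,
    size: int = DEFAULT_SIZE,
    skip_if_ok: bool = False,
) -> VideoMeta:
    """Standardize a recording: seekable container, size x size, fps preserved.

    Frame count preservation is verified after writing; any drift is a hard
    error.  With ``skip_if_ok`` an already-compliant TIFF is copied verbatim.
    """
    in_path, out_path = Path(in_path), Path(out_path)
    src = probe(in_path)
    compliant = (
        in_path.suffix.lower() in {".tif", ".tiff"} and src.width == size and src.height == size
    )
    if skip_if_ok and compliant:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(in_path, out_path)
        _write_sidecar(out_path, src.fps, src.video_id)
        return probe(out_path)
    block = read_frames(src, range(src.n_frames), size=size)
    out = write_video(out_path, block.pixels, fps=src.fps, video_id=src.video_id)
    if out.n_frames != src.n_frames:
        raise VideoFormatError(
            f"frame-count drift during preprocess: {src.n_frames} -> {out.n_frames}"
        )
    return out
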