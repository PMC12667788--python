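"""Overlapping temporal chunk geometry.

Transformer video encoders cannot process whole recordings at once, so videos
are cut into fixed-length chunks of sampled frames before encoding.  A chunk
is defined by its start frame, the intra-chunk frame stride (sampling
interval), and the chunk length in sampled frames; consecutive chunks overlap
by a configurable fraction of their raw span.  At 0% overlap each frame
appears in at most one chunk, at 50% in two, at 66% in three, and so on —
overlap multiplies training samples and gives inference several predictions
per frame to ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChunkConfig", "ChunkSpec", "plan_chunks", "coverage_counts", "subsample_chunks"]


@dataclass(frozen=True)
class ChunkConfig:
    """Chunk geometry: length in sampled frames, stride, and overlap fraction.

    Defaults follow the pipeline's standard regime: 64-frame chunks sampling
    every frame, 50% overlap (hop of 32 raw frames).
    """

    chunk_len: int = 64
    frame_stride: int = 1
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.chunk_len < 2:
            raise ValueError("chunk_len must be >= 2")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def span(self) -> int:
        """Raw frames covered by one chunk: (chunk_len-1)*stride + 1."""
        return (self.chunk_len - 1) * self.frame_stride + 1

    @property
    def hop(self) -> int:
        """Raw-frame distance between consecutive chunk starts."""
        return max(1, round(self.chunk_len * self.frame_stride * (1.0 - self.overlap)))


@dataclass(frozen=True)
class ChunkSpec:
    """One concrete chunk: chunk_len absolute frame indices of one video."""

    video_id: str
    start: int
    indices: tuple[int, ...] = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))


def _make_chunk(video_id: str, start: int, cfg: ChunkConfig) -> ChunkSpec:
    idx = range(start, start + cfg.span, cfg.frame_stride)
    return ChunkSpec(video_id=video_id, start=start, indices=tuple(idx))


def plan_chunks(
    n_frames: int,
    cfg: ChunkConfig = ChunkConfig(),
    mode: str = "train",
    video_id: str = "video",
) -> list[ChunkSpec]:
    """Enumerate chunk windows over a video of ``n_frames`` frames.

    Starts lie on the regular grid 0, hop, 2*hop, ...  In ``infer`` mode a
    final chunk anchored so its last index is ``n_frames - 1`` is appended
    when the grid leaves trailing frames uncovered, so every stride-reachable
    frame gets a genuine prediction.  In ``train`` mode videos shorter than
    one chunk span yield an empty plan (short clips are skipped rather than
    padded with fabricated context); ``infer`` on such videos is an error.
    """
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    span = cfg.span
    if n_frames < span:
        if mode == "train":
            return []
        raise ValueError(
            f"video of {n_frames} frames is shorter than one chunk span ({span}); "
            "reduce chunk_len/frame_stride to run inference"
        )
    starts = list(range(0, n_frames - span + 1, cfg.hop))
    chunks = [_make_chunk(video_id, s, cfg) for s in starts]
    if mode == "infer":
        tail_start = n_frames - span
        if chunks[-1].indices[-1] < n_frames - 1:
            chunks.append(_make_chunk(video_id, tail_start, cfg))
    return chunks


def coverage_counts(chunks: list[ChunkSpec], n_frames: int) -> np.ndarray:
    """Per-frame count of chunks whose sampled index set contains the frame."""
    counts = np.zeros(n_frames, dtype=np.int64)
    for c in chunks:
        counts[list(c.indices)] += 1
    return counts


def subsample_chunks(chunks: list[ChunkSpec], fraction: float, seed: int) -> list[ChunkSpec]:
    """Uniform without-replacement subsample of a chunk plan.

    Size is ``round(fraction * len(chunks))``; the selection is reproducible
    under ``seed`` and returned in the original plan order.  Used to probe
    data efficiency by training on a fraction of the available chunks.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return list(chunks)
    size = round(fraction * len(chunks))
    if size == 0:
        raise ValueError(
            f"fraction {fraction} of {len(chunks)} chunks rounds to zero; use a larger fraction"
        )
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(chunks), size=size, replace=False))
    return [chunks[i] for i in keep]
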