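"""Fine-tuning regime: losses, weighting, augmentation, schedule, EMA, fit.

Behavioral datasets are heavily imbalanced — a dominant "other" state plus
rare but biologically meaningful actions — so the single-label loss is a
label-smoothed cross-entropy with per-class weights proportional to the
square root of the inverse class frequency (amplifies rare classes without
overcompensating), and the multi-label loss is a binary cross-entropy whose
positive terms are weighted by n_negatives / n_positives per class.

Regularization follows the standard recipe: clip-consistent visual
augmentation (one transform and strength per clip, applied identically to
every frame), batch-level MixUp with element-wise label mixing across the
temporal dimension, strong weight decay, dropout, and an optional
exponential moving average of the weights.  The learning rate warms up
linearly over the first 20% of iterations and then follows cosine decay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from feral.chunking import ChunkConfig, ChunkSpec, plan_chunks
from feral.labels import MULTI_LABEL, SINGLE_LABEL, ClassCatalog, FrameLabelTrack
from feral.model import AttentionPoolHead, HeadConfig, VideoClassifier
from feral.nn import Adam, Tensor, log_softmax, relu

__all__ = [
    "ClassStats",
    "TrainConfig",
    "EmaState",
    "class_weights",
    "smoothed_weighted_ce",
    "weighted_bce",
    "mixup_batch",
    "clip_augment",
    "lr_at",
    "ema_update",
    "fit",
    "FitResult",
]


# ---------------------------------------------------------------------------
# Class statistics and weights


@dataclass(frozen=True)
class ClassStats:
    """Per-class frame statistics driving the loss weighting.

    Single-label: ``freq`` is the per-class fraction of labeled frames
    (sums to 1).  Multi-label: ``n_pos``/``n_neg`` count positive and
    negative frames per class (summing to the total frame count).
    """

    mode: str
    freq: np.ndarray | None = None
    n_pos: np.ndarray | None = None
    n_neg: np.ndarray | None = None

    @classmethod
    def from_tracks(
        cls, tracks: Sequence[FrameLabelTrack], catalog: ClassCatalog
    ) -> "ClassStats":
        counts = np.zeros(catalog.n_classes, dtype=np.int64)
        total = 0
        for t in tracks:
            counts += t.class_counts(catalog)
            total += t.n_frames
        if catalog.mode == SINGLE_LABEL:
            return cls(mode=SINGLE_LABEL, freq=counts / counts.sum())
        return cls(mode=MULTI_LABEL, n_pos=counts, n_neg=total - counts)


def class_weights(stats: ClassStats, catalog: ClassCatalog | None = None) -> np.ndarray:
    """Single-label weights: w_c proportional to sqrt(1 / freq_c), mean 1."""
    if stats.mode != SINGLE_LABEL or stats.freq is None:
        raise ValueError("class_weights requires single-label frequency stats")
    freq = np.asarray(stats.freq, dtype=np.float64)
    zero = np.flatnonzero(freq <= 0)
    if zero.size:
        names = [catalog.names[i] for i in zero] if catalog else zero.tolist()
        raise ValueError(f"class(es) with zero frequency: {names}")
    raw = np.sqrt(1.0 / freq)
    return raw / raw.mean()


def bce_pos_weights(stats: ClassStats, catalog: ClassCatalog | None = None) -> np.ndarray:
    """Multi-label positive-term weights: n_neg / n_pos per class."""
    if stats.mode != MULTI_LABEL or stats.n_pos is None:
        raise ValueError("bce_pos_weights requires multi-label counts")
    n_pos = np.asarray(stats.n_pos, dtype=np.float64)
    n_neg = np.asarray(stats.n_neg, dtype=np.float64)
    zero = np.flatnonzero(n_pos == 0)
    if zero.size:
        names = [catalog.names[i] for i in zero] if catalog else zero.tolist()
        raise ValueError(f"class(es) with no positive frames: {names}")
    return n_neg / n_pos


# ---------------------------------------------------------------------------
# Losses


def _target_rows(targets, n_classes: int) -> np.ndarray:
    """Int class indices -> one-hot rows; probability rows pass through."""
    targets = np.asarray(targets)
    if targets.ndim == 1:
        rows = np.zeros((len(targets), n_classes))
        rows[np.arange(len(targets)), targets.astype(int)] = 1.0
        return rows
    if not np.allclose(targets.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("mixed target rows must sum to 1")
    return targets.astype(np.float64)


def smoothed_weighted_ce(
    logits: Tensor | np.ndarray,
    targets,
    weights: np.ndarray | None = None,
    smoothing: float = 0.1,
    focal_gamma: float | None = None,
) -> Tensor:
    """Label-smoothed, class-weighted cross-entropy, averaged over frames.

    The per-frame target distribution is q = (1 - s) * y + s / C applied to
    hard or already-mixed rows y; the loss is -sum_c w_c q_c log softmax_c.
    ``focal_gamma`` optionally modulates each frame by (1 - p_true)^gamma
    (off by default; it brought no consistent benefit).
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    flat = logits if logits.ndim == 2 else logits.reshape(-1, logits.shape[-1])
    if not np.isfinite(flat.data).all():
        raise FloatingPointError("non-finite logits passed to cross-entropy")
    n, C = flat.shape
    y = _target_rows(targets, C).reshape(n, C)
    q = (1.0 - smoothing) * y + smoothing / C
    w = np.ones(C) if weights is None else np.asarray(weights, dtype=np.float64)
    logp = log_softmax(flat, axis=-1)
    frame_loss = -(logp * Tensor(q * w)).sum(axis=-1)  # (n,)
    if focal_gamma is not None:
        p_true = (np.exp(logp.data) * y).sum(axis=-1)  # detached modulation
        frame_loss = frame_loss * Tensor((1.0 - p_true) ** focal_gamma)
    return frame_loss.mean()


def _log_sigmoid(x: Tensor) -> Tensor:
    """Numerically stable log(sigmoid(x)) = -softplus(-x)."""
    # softplus(z) = max(z, 0) + log1p(exp(-|z|)); here z = -x
    abs_x = relu(x) + relu(-x)
    return -(relu(-x) + ((-abs_x).exp() + 1.0).log())


def weighted_bce(
    logits: Tensor | np.ndarray,
    targets,
    stats: ClassStats,
    catalog: ClassCatalog | None = None,
) -> Tensor:
    """Class-weighted binary cross-entropy on sigmoid(logits).

    Positive terms of class c are weighted by n_neg_c / n_pos_c, emphasizing
    rare classes; the loss is the mean over frames and classes.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    flat = logits if logits.ndim == 2 else logits.reshape(-1, logits.shape[-1])
    y = np.asarray(targets, dtype=np.float64).reshape(flat.shape)
    w_pos = bce_pos_weights(stats, catalog)
    # -[w_c * y * log sigma(x) + (1 - y) * log(1 - sigma(x))]
    term = Tensor(w_pos * y) * _log_sigmoid(flat) + Tensor(1.0 - y) * _log_sigmoid(-flat)
    return -(term.mean())


# ---------------------------------------------------------------------------
# Augmentation


@dataclass(frozen=True)
class MixupDraw:
    """One MixUp pairing: mixing coefficient and partner index."""

    alpha: float
    partner: int


def mixup_batch(
    videos: np.ndarray,
    label_rows: np.ndarray,
    lam: float,
    rng: np.random.Generator,
    alpha: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray, list[MixupDraw]]:
    """MixUp over a batch: convex combinations of clip pairs and their labels.

    X_new = a X + (1 - a) X~, y_new = a y + (1 - a) y~, with a ~ Beta(lam,
    lam) per sample (overridable for testing).  Partners come from reversing
    a seeded shuffle of the batch; the same coefficient is applied to pixels
    and, element-wise across the temporal dimension, to the label rows.
    """
    B = len(videos)
    if B < 2:
        raise ValueError("mixup requires a batch of at least 2 clips")
    if len(label_rows) != B:
        raise ValueError("videos and label_rows disagree in batch size")
    order = rng.permutation(B)
    partner = np.empty(B, dtype=int)
    partner[order] = order[::-1]
    if alpha is None:
        a = rng.beta(lam, lam, size=B)
    else:
        a = np.broadcast_to(np.asarray(alpha, dtype=np.float64), (B,)).copy()
    a_vid = a.reshape((B,) + (1,) * (videos.ndim - 1))
    a_lab = a.reshape((B,) + (1,) * (label_rows.ndim - 1))
    mixed_videos = a_vid * videos + (1.0 - a_vid) * videos[partner]
    mixed_labels = a_lab * label_rows + (1.0 - a_lab) * label_rows[partner]
    draws = [MixupDraw(alpha=float(a[i]), partner=int(partner[i])) for i in range(B)]
    return mixed_videos, mixed_labels, draws


#: transformations available to the per-clip augmenter (one is sampled per
#: clip together with a strength, then applied identically to every frame)
AUGMENT_OPS = ("identity", "brightness", "contrast", "rotation", "color_jitter", "translation")


def clip_augment(
    video: np.ndarray,
    rng: np.random.Generator,
    ops: Sequence[str] = AUGMENT_OPS,
) -> np.ndarray:
    """Apply one randomly chosen transform, at one strength, to a whole clip.

    ``video`` is (T, H, W, 3) float in [0, 1].  Sampling one op and one
    strength per clip (rather than per frame) preserves temporal coherence
    while diversifying across clips.
    """
    video = np.asarray(video, dtype=np.float64)
    op = ops[rng.integers(len(ops))]
    if op == "identity":
        return video
    strength = float(rng.uniform(0.0, 1.0))
    if op == "brightness":
        delta = (strength - 0.5) * 0.4
        return np.clip(video + delta, 0.0, 1.0)
    if op == "contrast":
        factor = 0.6 + 0.8 * strength
        mean = video.mean()
        return np.clip((video - mean) * factor + mean, 0.0, 1.0)
    if op == "color_jitter":
        gains = 1.0 + (rng.uniform(-1.0, 1.0, size=3) * 0.3 * strength)
        return np.clip(video * gains, 0.0, 1.0)
    if op == "rotation":
        angle = (strength - 0.5) * 30.0  # degrees, same for every frame
        return np.clip(
            np.stack(
                [
                    ndimage.rotate(f, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
                    for f in video
                ]
            ),
            0.0,
            1.0,
        )
    if op == "translation":
        h, w = video.shape[1:3]
        dy = (strength - 0.5) * 0.2 * h
        dx = float(rng.uniform(-0.1, 0.1)) * w
        return np.clip(
            np.stack(
                [ndimage.shift(f, (dy, dx, 0.0), order=1, mode="nearest") for f in video]
            ),
            0.0,
            1.0,
        )
    raise ValueError(f"unknown augmentation op {op!r}")


# ---------------------------------------------------------------------------
# Schedule and EMA


def lr_at(step: int, total_steps: int, peak_lr: float, warmup_frac: float = 0.2) -> float:
    """Linear warm-up to ``peak_lr`` then cosine decay to ~0 at the last step."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps})")
    warmup_steps = warmup_frac * total_steps
    if step < warmup_steps:
        return peak_lr * step / warmup_steps
    last = total_steps - 1
    if last <= warmup_steps:
        return peak_lr
    progress = (step - warmup_steps) / (last - warmup_steps)
    return peak_lr * 0.5 * (1.0 + math.cos(math.pi * progress))


@dataclass
class EmaState:
    """Exponential moving average of the trainable weights."""

    shadow: dict[str, np.ndarray]
    beta: float = 0.999
    t: int = 0

    @classmethod
    def init(cls, model, beta: float = 0.999) -> "EmaState":
        shadow = {
            name: p.data.copy() for name, p in model.named_parameters() if p.requires_grad
        }
        return cls(shadow=shadow, beta=beta)


def ema_update(state: EmaState, params: dict[str, np.ndarray]) -> EmaState:
    """One EMA step: theta_ema <- beta * theta_ema + (1 - beta) * theta."""
    for name, theta in params.items():
        if name not in state.shadow:
            continue
        if state.shadow[name].shape != np.shape(theta):
            raise ValueError(f"shape mismatch for {name}")
        state.shadow[name] = state.beta * state.shadow[name] + (1.0 - state.beta) * theta
    state.t += 1
    return state


# ---------------------------------------------------------------------------
# Fit loop


@dataclass(frozen=True)
class TrainConfig:
    """Every knob of the fine-tuning regime, with the standard defaults."""

    epochs: int = 10
    weight_decay: float = 0.1
    peak_lr: float = 1e-3  # tiny-backbone default; plug-in backbones use 1e-4
    warmup_frac: float = 0.2
    label_smoothing: float = 0.1
    mixup_lambda: float = 0.2
    dropout_p: float = 0.5
    ema_beta: float = 0.999
    freeze_frac: float = 0.5
    batch_size: int = 4
    seed: int = 0
    chunk: ChunkConfig = field(default_factory=ChunkConfig)
    use_mixup: bool = True
    use_augment: bool = True
    focal_gamma: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.warmup_frac < 1.0:
            raise ValueError("warmup_frac must lie in [0, 1)")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must lie in [0, 1)")
        if not 0.0 <= self.freeze_frac <= 1.0:
            raise ValueError("freeze_frac must lie in [0, 1]")


@dataclass
class FitResult:
    model: VideoClassifier
    ema: EmaState
    history: list[dict]
    n_frozen_groups: int


def apply_freezing(backbone, freeze_frac: float) -> int:
    """Freeze the first ceil(freeze_frac * n_layers) layer groups (input side)."""
    groups = backbone.layer_groups()
    n_freeze = math.ceil(freeze_frac * len(groups))
    for gi, group in enumerate(groups):
        for p in group:
            p.requires_grad = gi >= n_freeze
    return n_freeze


def _chunk_targets(track: FrameLabelTrack, chunk: ChunkSpec, n_classes: int) -> np.ndarray:
    idx = list(chunk.indices)
    if track.mode == SINGLE_LABEL:
        return _target_rows(track.targets[idx], n_classes)
    return track.targets[idx].astype(np.float64)


def fit(
    tracks: Sequence[FrameLabelTrack],
    videos: dict[str, np.ndarray],
    backbone,
    cfg: TrainConfig,
    catalog: ClassCatalog,
    log_path: str | Path | None = None,
) -> FitResult:
    """Fine-tune backbone + attention-pooling head on labeled videos.

    ``videos`` maps video_id to a (T, H, W, 3) uint8 frame stack whose
    spatial size matches the backbone's input size.  The model trains for
    ``epochs`` passes over the fixed chunk grid with no early stopping;
    losses, learning rates and EMA state are logged as JSON lines.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no labeled tracks")
    for t in tracks:
        t.validate_against(catalog)
        if t.video_id not in videos:
            raise KeyError(f"no video for track {t.video_id!r}")

    dataset: list[tuple[FrameLabelTrack, ChunkSpec]] = []
    for t in tracks:
        for chunk in plan_chunks(t.n_frames, cfg.chunk, mode="train", video_id=t.video_id):
            dataset.append((t, chunk))
    if not dataset:
        raise ValueError("no labeled chunks: all videos shorter than one chunk span")

    C = catalog.n_classes
    stats = ClassStats.from_tracks(tracks, catalog)
    if catalog.mode == SINGLE_LABEL:
        weights = class_weights(stats, catalog)
    else:
        bce_pos_weights(stats, catalog)  # fail early on classes with no positives

    head = AttentionPoolHead(
        HeadConfig(
            n_queries=cfg.chunk.chunk_len,
            n_classes=C,
            embed_dim=backbone.embed_dim,
            dropout_p=cfg.dropout_p,
        ),
        seed=cfg.seed,
    )
    model = VideoClassifier(backbone, head)
    n_frozen = apply_freezing(backbone, cfg.freeze_frac)
    model.train()

    optimizer = Adam(model.parameters(), lr=0.0, weight_decay=cfg.weight_decay)
    ema = EmaState.init(model, beta=cfg.ema_beta)
    rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(cfg.seed + 1)

    steps_per_epoch = math.ceil(len(dataset) / cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    history: list[dict] = []
    log_file = open(log_path, "w") if log_path else None
    step = 0
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(dataset))
            for b0 in range(0, len(dataset), cfg.batch_size):
                batch = [dataset[i] for i in order[b0 : b0 + cfg.batch_size]]
                clips, rows = [], []
                for track, chunk in batch:
                    pixels = videos[track.video_id][list(chunk.indices)]
                    clip = pixels.astype(np.float64) / 255.0
                    if cfg.use_augment:
                        clip = clip_augment(clip, aug_rng)
                    clips.append(clip)
                    rows.append(_chunk_targets(track, chunk, C))
                x = np.stack(clips)
                y = np.stack(rows)
                if cfg.use_mixup and len(batch) >= 2:
                    x, y, _ = mixup_batch(x, y, cfg.mixup_lambda, rng)

                logits = model(x)
                if catalog.mode == SINGLE_LABEL:
                    loss = smoothed_weighted_ce(
                        logits,
                        y.reshape(-1, C),
                        weights,
                        smoothing=cfg.label_smoothing,
                        focal_gamma=cfg.focal_gamma,
                    )
                else:
                    loss = weighted_bce(logits, y.reshape(-1, C), stats, catalog)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"NaN/inf loss at step {step} (epoch {epoch}); aborting. "
                        "Inspect the run log and consider lowering peak_lr."
                    )
                optimizer.zero_grad()
                model.zero_grad()
                loss.backward()
                optimizer.lr = lr_at(step, total_steps, cfg.peak_lr, cfg.warmup_frac)
                optimizer.step()
                ema_update(
                    ema,
                    {n: p.data for n, p in model.named_parameters() if p.requires_grad},
                )
                record = {
                    "step": step,
                    "epoch": epoch,
                    "loss": float(loss.data),
                    "lr": optimizer.lr,
                }
                history.append(record)
                if log_file:
                    log_file.write(json.dumps(record) + "\n")
                step += 1
    finally:
        if log_file:
            log_file.close()
    model.eval()
    return FitResult(model=model, ema=ema, history=history, n_frozen_groups=n_frozen)
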