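"""Video classification model: pluggable encoder + attention-pooling head.

The encoder ("backbone") turns a chunk of frames into a long sequence of
spatiotemporal tokens; any encoder satisfying :class:`BackboneContract` can
be plugged in.  The classification head maps that token sequence back onto
the temporal resolution of the chunk: a set of learnable query embeddings
(one per sampled frame) cross-attends to the tokens, and the pooled
per-query embeddings are batch-normalized, dropped out, and linearly
projected to class logits — row ``q`` of the output is the prediction for
the chunk's ``q``-th sampled frame.

A small trainable encoder (:class:`TinyVideoBackbone`) ships with the
package so the full pipeline runs end-to-end on a CPU; larger pretrained
encoders register behind the same contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from feral.chunking import ChunkSpec
from feral.nn import (
    Dropout,
    BatchNorm1d,
    LayerNorm,
    Linear,
    Module,
    MultiheadAttention,
    Parameter,
    Tensor,
    gelu,
)

__all__ = [
    "BackboneContract",
    "HeadConfig",
    "ChunkLogits",
    "TinyVideoBackbone",
    "tiny_backbone",
    "AttentionPoolHead",
    "VideoClassifier",
    "save_checkpoint",
    "load_checkpoint",
]


@runtime_checkable
class BackboneContract(Protocol):
    """What a plug-in video encoder must provide.

    ``encode`` maps a pixel block of shape (B, T, H, W, 3) in [0, 1] to a
    token tensor of shape (B, N_tokens, D); it must be deterministic in
    evaluation mode for fixed weights and input.  ``layer_groups`` exposes
    an input-to-output ordering of parameter groups so partial freezing can
    exclude the first fraction of them from fine-tuning.
    """

    descriptor: str
    embed_dim: int

    @property
    def n_layers(self) -> int: ...

    def encode(self, pixels: np.ndarray) -> Tensor: ...

    def layer_groups(self) -> list[list[Parameter]]: ...


@dataclass(frozen=True)
class HeadConfig:
    """Attention-pooling head hyperparameters.

    ``n_queries`` must equal the chunk length of the paired chunk config —
    query q is trained to represent sampled frame q.
    """

    n_queries: int = 64
    n_classes: int = 2
    embed_dim: int = 64
    dropout_p: float = 0.5
    n_heads: int = 8

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")


@dataclass(frozen=True)
class ChunkLogits:
    """Per-frame logits for one chunk: row q aligns to chunk.indices[q]."""

    chunk: ChunkSpec
    logits: np.ndarray  # (n_queries, C)

    def __post_init__(self) -> None:
        if len(self.logits) != len(self.chunk.indices):
            raise ValueError("one logit row per sampled frame required")


class _TransformerBlock(Module):
    """Pre-LN self-attention block with a GELU MLP."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, mlp_ratio: int = 2):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp_in = Linear(dim, mlp_ratio * dim, rng)
        self.mlp_out = Linear(mlp_ratio * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h)
        x = x + self.mlp_out(gelu(self.mlp_in(self.norm2(x))))
        return x


class TinyVideoBackbone(Module):
    """A small space-time patch transformer satisfying the backbone contract.

    Frames are cut into (t_patch x patch x patch) tubelets, linearly embedded
    with an added learned positional embedding, and passed through a stack of
    self-attention blocks.  Capacity is sized to fit the synthetic fixtures on
    one CPU, not to compete with pretrained encoders.
    """

    def __init__(
        self,
        seed: int = 0,
        input_size: int = 32,
        chunk_len: int = 16,
        patch: int = 8,
        t_patch: int = 2,
        embed_dim: int = 64,
        n_blocks: int = 2,
        n_heads: int = 4,
    ):
        super().__init__()
        if input_size % patch or chunk_len % t_patch:
            raise ValueError("input_size/chunk_len must be divisible by patch/t_patch")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.chunk_len = chunk_len
        self.patch = patch
        self.t_patch = t_patch
        self.embed_dim = embed_dim
        self.n_tokens = (chunk_len // t_patch) * (input_size // patch) ** 2
        patch_dim = t_patch * patch * patch * 3
        self.patch_embed = Linear(patch_dim, embed_dim, rng)
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, size=(1, self.n_tokens, embed_dim)))
        self.blocks = [_TransformerBlock(embed_dim, n_heads, rng) for _ in range(n_blocks)]
        self.final_norm = LayerNorm(embed_dim)
        self.descriptor = (
            f"tiny-vit3d/seed={seed}/size={input_size}/len={chunk_len}/"
            f"patch={patch}x{t_patch}/d={embed_dim}/blocks={n_blocks}"
        )

    @property
    def n_layers(self) -> int:
        # freezable groups, input side first: patch embed, each block, final norm
        return len(self.blocks) + 2

    def layer_groups(self) -> list[list[Parameter]]:
        groups: list[list[Parameter]] = [[self.patch_embed.weight, self.patch_embed.bias, self.pos_embed]]
        for blk in self.blocks:
            groups.append(blk.parameters())
        groups.append(self.final_norm.parameters())
        return groups

    def _tubelets(self, pixels: np.ndarray) -> np.ndarray:
        B, T, H, W, C = pixels.shape
        pt, ps = self.t_patch, self.patch
        x = pixels.reshape(B, T // pt, pt, H // ps, ps, W // ps, ps, C)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)  # (B, T/pt, H/ps, W/ps, pt, ps, ps, C)
        return x.reshape(B, self.n_tokens, pt * ps * ps * C)

    def encode(self, pixels: np.ndarray) -> Tensor:
        pixels = np.asarray(pixels, dtype=np.float64)
        if pixels.ndim == 4:
            pixels = pixels[None]
        B, T, H, W, _ = pixels.shape
        if T != self.chunk_len or H != self.input_size or W != self.input_size:
            raise ValueError(
                f"backbone expects ({self.chunk_len}, {self.input_size}, "
                f"{self.input_size}) chunks, got ({T}, {H}, {W})"
            )
        tokens = self.patch_embed(Tensor(self._tubelets(pixels))) + self.pos_embed
        for blk in self.blocks:
            tokens = blk(tokens)
        return self.final_norm(tokens)


def tiny_backbone(seed: int = 0, **kwargs) -> TinyVideoBackbone:
    """Construct the small trainable encoder (deterministic under seed)."""
    return TinyVideoBackbone(seed=seed, **kwargs)


class AttentionPoolHead(Module):
    """Learnable-query attention pooling plus the per-frame classifier.

    ``pool_frames`` compresses the token sequence into one embedding per
    query (frame); ``classify`` runs batch-norm -> dropout -> linear on the
    pooled rows.  Attention weights of the last pooling call are exposed for
    inspection via ``attn.last_weights``.
    """

    def __init__(self, config: HeadConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 1)
        self.config = config
        self.queries = Parameter(
            rng.normal(0.0, 0.02, size=(1, config.n_queries, config.embed_dim))
        )
        self.attn = MultiheadAttention(config.embed_dim, config.n_heads, rng)
        self.norm = BatchNorm1d(config.embed_dim)
        self.dropout = Dropout(config.dropout_p, rng=np.random.default_rng(seed + 2))
        self.proj = Linear(config.embed_dim, config.n_classes, rng)

    def pool_frames(self, tokens: Tensor, queries: Tensor | None = None) -> Tensor:
        """Cross-attend queries to tokens: (B, N, D) -> (B, Q, D)."""
        if queries is None:
            queries = self.queries
        B = tokens.shape[0]
        if queries.shape[0] == 1 and B > 1:
            queries = queries + Tensor(np.zeros((B, 1, 1)))  # broadcast over batch
        return self.attn(queries, tokens)

    def classify(self, pooled: Tensor) -> Tensor:
        """(B, Q, D) -> (B, Q, C) via normalize -> dropout -> affine."""
        B, Q, D = pooled.shape
        flat = pooled.reshape(B * Q, D)
        flat = self.norm(flat)
        flat = self.dropout(flat)
        logits = self.proj(flat)
        return logits.reshape(B, Q, self.config.n_classes)

    def __call__(self, tokens: Tensor) -> Tensor:
        return self.classify(self.pool_frames(tokens))


class VideoClassifier(Module):
    """Backbone + head; forward maps pixel chunks to per-frame logits."""

    def __init__(self, backbone: Module, head: AttentionPoolHead):
        super().__init__()
        if head.config.embed_dim != backbone.embed_dim:
            raise ValueError("head embed_dim must match backbone embed_dim")
        self.backbone = backbone
        self.head = head

    def __call__(self, pixels: np.ndarray) -> Tensor:
        return self.head(self.backbone.encode(pixels))

    def predict_logits(self, pixels: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode forward, returning plain arrays."""
        was_training = self.training
        self.eval()
        try:
            out = self(pixels).data.copy()
        finally:
            if was_training:
                self.train()
        return out


def save_checkpoint(
    path: str | Path,
    model: VideoClassifier,
    class_names: list[str],
    mode: str,
    extra: dict | None = None,
) -> None:
    """Save weights (npz) plus a JSON sidecar with head config and catalog."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "head_config": asdict(model.head.config),
        "class_names": class_names,
        "mode": mode,
        "backbone": model.backbone.descriptor,
        "bn_running_mean": model.head.norm.running_mean.tolist(),
        "bn_running_var": model.head.norm.running_var.tolist(),
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_checkpoint(path: str | Path, backbone: Module) -> tuple[VideoClassifier, dict]:
    """Rebuild a classifier from a checkpoint, pairing it with ``backbone``."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    head = AttentionPoolHead(HeadConfig(**sidecar["head_config"]))
    model = VideoClassifier(backbone, head)
    with np.load(path) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    model.head.norm.running_mean = np.asarray(sidecar["bn_running_mean"])
    model.head.norm.running_var = np.asarray(sidecar["bn_running_var"])
    model.eval()
    return model, sidecar
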