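"""Histology patch extraction and perceptual spot embeddings.

Per spot, square patches are cropped at several scales (default 150/100/50
px sides) centered on the spot coordinate, white-padded where they exit the
image, and resized to a common output size (default 224).  A pluggable
backend maps each patch to token embeddings: the default ``stub`` backend
downsamples the patch to a 16×16 grayscale grid and applies a frozen
seeded random projection, giving a deterministic, download-free encoder
whose tokens are still discriminative between differently tinted tissue
regions.  Tokens are self-attention-pooled per scale, the per-scale
vectors are concatenated and fused by a three-layer MLP into one
perceptual embedding f_perc per spot.  A cross-modal attention block
(queries from expression-derived latents, keys/values from f_perc) is
provided for decoder conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .data_io import SpotCoordinates

__all__ = [
    "PatchSet", "TokenEmbeddings", "PerceptualEmbedding",
    "CrossAttentionParams", "PerceptualPipeline", "extract_patches",
    "encode_patch", "attention_pool", "fuse_scales", "cross_modal_attend",
]

DEFAULT_SCALES = (150, 100, 50)
DEFAULT_OUT_SIZE = 224


@dataclass
class PatchSet:
    """One resized RGB patch per (spot, scale), with crop provenance."""

    patches: dict                  # (spot_id, scale) -> out_size² RGB float array
    provenance: dict               # (spot_id, scale) -> dict(crop_box, padded_fraction)
    spot_ids: list[str]
    scales: tuple[int, ...]
    out_size: int


@dataclass
class TokenEmbeddings:
    tokens: np.ndarray             # N_s × d
    backend_tag: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.tokens)):
            raise ValueError("token embeddings must be finite")


@dataclass
class PerceptualEmbedding:
    vector: np.ndarray             # length d
    pooled_per_scale: list


@dataclass
class CrossAttentionParams:
    """Projections for multi-head cross attention into dimension d_k per head."""

    w_q: np.ndarray                # d_q × (n_heads · d_k)
    w_k: np.ndarray                # d_kv × (n_heads · d_k)
    w_v: np.ndarray                # d_kv × (n_heads · d_k)
    n_heads: int = 4
    d_k: int = 64

    def __post_init__(self) -> None:
        want = self.n_heads * self.d_k
        for name, w in (("w_q", self.w_q), ("w_k", self.w_k), ("w_v", self.w_v)):
            if w.shape[1] != want:
                raise ValueError(
                    f"{name} output dim {w.shape[1]} != n_heads*d_k = {want}")


def extract_patches(image: np.ndarray, coords: SpotCoordinates,
                    scales: Sequence[int] = DEFAULT_SCALES,
                    out_size: int = DEFAULT_OUT_SIZE) -> PatchSet:
    """Crop scale×scale boxes centered on each spot; white-pad and resize."""
    if image.size == 0:
        raise ValueError("image is empty")
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    h, w = img.shape[:2]
    patches: dict = {}
    provenance: dict = {}
    for sid, (x, y) in zip(coords.spot_ids, coords.xy):
        for s in scales:
            half = s / 2.0
            x0, x1 = int(round(x - half)), int(round(x - half)) + s
            y0, y1 = int(round(y - half)), int(round(y - half)) + s
            patch = np.full((s, s, 3), 255.0)
            sx0, sx1 = max(0, x0), min(w, x1)
            sy0, sy1 = max(0, y0), min(h, y1)
            visible = 0
            if sx0 < sx1 and sy0 < sy1:
                patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = \
                    img[sy0:sy1, sx0:sx1, :3]
                visible = (sx1 - sx0) * (sy1 - sy0)
            padded_fraction = 1.0 - visible / (s * s)
            pil = Image.fromarray(np.clip(patch, 0, 255).astype(np.uint8))
            resized = np.asarray(
                pil.resize((out_size, out_size), Image.BILINEAR),
                dtype=float) / 255.0
            patches[(sid, s)] = resized
            provenance[(sid, s)] = dict(crop_box=(x0, y0, x1, y1),
                                        padded_fraction=padded_fraction)
    return PatchSet(patches, provenance, list(coords.spot_ids),
                    tuple(scales), out_size)


class _StubBackend:
    """Frozen affine patch encoder: 16×16 grayscale grid → random projection."""

    GRID = 16

    def __init__(self, n_tokens: int = 16, dim: int = 64, seed: int = 12345):
        rng = np.random.default_rng(seed)
        self.n_tokens = n_tokens
        self.dim = dim
        self.projection = rng.normal(0, 1.0 / np.sqrt(self.GRID ** 2),
                                     (n_tokens * dim, self.GRID ** 2))

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        gray = np.asarray(patch, dtype=float)
        if gray.ndim == 3:
            gray = gray.mean(axis=2)
        g = self.GRID
        h, w = gray.shape
        # block-mean downsample to a GRID×GRID summary (vectorized reduceat)
        ys = np.linspace(0, h, g + 1).astype(int)
        xs = np.linspace(0, w, g + 1).astype(int)
        rows = np.add.reduceat(gray, ys[:-1], axis=0)
        blocks = np.add.reduceat(rows, xs[:-1], axis=1)
        areas = np.outer(np.diff(ys), np.diff(xs))
        flat = (blocks / areas).ravel()
        return (self.projection @ flat).reshape(self.n_tokens, self.dim)


_STUB_CACHE: dict[tuple[int, int, int], _StubBackend] = {}


def encode_patch(patch: np.ndarray, backend: str = "stub",
                 n_tokens: int = 16, dim: int = 64,
                 seed: int = 12345) -> TokenEmbeddings:
    """Map one patch to N_s × d token embeddings via the named backend."""
    if backend == "stub":
        key = (n_tokens, dim, seed)
        if key not in _STUB_CACHE:
            _STUB_CACHE[key] = _StubBackend(n_tokens, dim, seed)
        return TokenEmbeddings(_STUB_CACHE[key](patch), "stub")
    if backend == "external-foundation":
        raise RuntimeError(
            "no pretrained pathology backend is available in this build; "
            "use backend='stub'")
    raise ValueError(f"unknown backend {backend!r}")


def attention_pool(tokens: TokenEmbeddings | np.ndarray,
                   pool_weights: np.ndarray) -> np.ndarray:
    """Self-attention pooling: softmax((w·tokensᵀ)/√d) · tokens."""
    t = tokens.tokens if isinstance(tokens, TokenEmbeddings) else np.asarray(tokens)
    if t.size == 0:
        raise ValueError("empty token matrix")
    d = t.shape[1]
    w = np.asarray(pool_weights, dtype=float)
    if w.shape != (d,):
        raise ValueError(f"pool_weights shape {w.shape} != ({d},)")
    scores = (t @ w) / np.sqrt(d)
    scores -= scores.max()
    weights = np.exp(scores)
    weights /= weights.sum()
    return weights @ t


@dataclass
class _FusionMlp:
    """Three-layer ReLU MLP fusing concatenated per-scale vectors."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @staticmethod
    def init(in_dim: int, hidden: int, out_dim: int,
             rng: np.random.Generator) -> "_FusionMlp":
        dims = [in_dim, hidden, hidden, out_dim]
        ws, bs = [], []
        for a, b in zip(dims[:-1], dims[1:]):
            lim = np.sqrt(6.0 / (a + b))
            ws.append(rng.uniform(-lim, lim, (a, b)))
            bs.append(np.zeros(b))
        return _FusionMlp(ws, bs)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0)
        return h


def fuse_scales(pooled: list[np.ndarray],
                mlp: Optional[_FusionMlp] = None,
                seed: int = 777) -> PerceptualEmbedding:
    """Concatenate per-scale pooled vectors and fuse with a three-layer MLP."""
    dims = {p.shape for p in pooled}
    if len(dims) != 1:
        raise ValueError(f"inconsistent pooled dims: {sorted(dims)}")
    d = pooled[0].shape[0]
    x = np.concatenate(pooled)
    if mlp is None:
        mlp = _FusionMlp.init(x.shape[0], 2 * d, d, np.random.default_rng(seed))
    return PerceptualEmbedding(mlp(x), list(pooled))


def cross_modal_attend(query_feats: np.ndarray, perceptual: np.ndarray,
                       params: CrossAttentionParams,
                       key_sets: Optional[list[np.ndarray]] = None) -> np.ndarray:
    """Multi-head cross attention; queries from spot latents, K/V from f_perc.

    By default each spot attends over its own single perceptual row;
    ``key_sets`` optionally gives, per spot, the indices of perceptual rows
    to use as keys/values (e.g. the spot plus its graph neighbors).
    """
    q_all = np.asarray(query_feats) @ params.w_q
    k_all = np.asarray(perceptual) @ params.w_k
    v_all = np.asarray(perceptual) @ params.w_v
    n, h, dk = q_all.shape[0], params.n_heads, params.d_k
    if key_sets is None:
        if perceptual.shape[0] != n:
            raise ValueError("one-key mode needs row-aligned query/perceptual")
        key_sets = [np.array([i]) for i in range(n)]
    out = np.empty((n, h * dk))
    for i in range(n):
        ks = k_all[key_sets[i]].reshape(-1, h, dk)
        vs = v_all[key_sets[i]].reshape(-1, h, dk)
        qi = q_all[i].reshape(h, dk)
        for head in range(h):
            scores = ks[:, head] @ qi[head] / np.sqrt(dk)
            scores -= scores.max()
            w = np.exp(scores)
            w /= w.sum()
            out[i, head * dk:(head + 1) * dk] = w @ vs[:, head]
    return out


class PerceptualPipeline:
    """Full SFE path: image + coords → per-spot f_perc matrix.

    All parameters (pooling weights, fusion MLP, stub projection) are
    frozen functions of their seeds, so the path is deterministic.
    """

    def __init__(self, scales: Sequence[int] = DEFAULT_SCALES,
                 out_size: int = DEFAULT_OUT_SIZE, backend: str = "stub",
                 n_tokens: int = 16, dim: int = 64, seed: int = 777):
        self.scales = tuple(scales)
        self.out_size = out_size
        self.backend = backend
        self.n_tokens = n_tokens
        self.dim = dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.pool_weights = {s: rng.normal(0, 1, dim) for s in self.scales}
        self.fusion = _FusionMlp.init(len(self.scales) * dim, 2 * dim, dim, rng)

    def embed(self, image: np.ndarray, coords: SpotCoordinates) -> np.ndarray:
        patches = extract_patches(image, coords, self.scales, self.out_size)
        out = np.empty((len(coords.spot_ids), self.dim))
        for i, sid in enumerate(coords.spot_ids):
            pooled = []
            for s in self.scales:
                toks = encode_patch(patches.patches[(sid, s)], self.backend,
                                    self.n_tokens, self.dim)
                pooled.append(attention_pool(toks, self.pool_weights[s]))
            out[i] = fuse_scales(pooled, mlp=self.fusion).vector
        return out
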