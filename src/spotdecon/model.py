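"""The multitask deconvolution autoencoder.

A shared encoder E maps normalized expression rows (simulated spots
directly; real spots after graph-convolutional spatial encoding) into a
latent space of width d_f.  From there:

* a conditional decoder D reconstructs expression, with a sinusoidal
  positional encoding of the spot coordinates and a cross-modal attention
  block over the histology perceptual embedding injected (additively, with
  residual connections) at every decoding layer — both are skipped
  identically for the simulated branch, which has no coordinates or images;
* a shared three-layer extractor F_shared feeds two softmax heads: C_prop
  (cell-type proportions, trained on simulated spots where composition is
  known) and C_hist (pathology class of real spots);
* a domain discriminator M, reached through a gradient-reversal layer,
  pushes E toward domain-invariant latents.

All parameters live in one :class:`ModelParams`; every forward pass is a
deterministic function of inputs and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor, grl, softmax_rows
from .data_io import SpotCoordinates
from .spatial_graph import GcnStack

__all__ = ["ModelParams", "positional_encode", "encode", "decode_conditional",
           "shared_extract", "predict_proportions", "predict_pathology",
           "grl_discriminate"]


def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (d_in + d_out))
    return Tensor.param(rng.uniform(-lim, lim, (d_in, d_out)))


def _zeros(d: int) -> Tensor:
    return Tensor.param(np.zeros((1, d)))


@dataclass
class ModelParams:
    """All trainable tensors, keyed by module path for checkpointing."""

    n_genes: int
    n_cell_types: int
    n_path_classes: int
    d_f: int = 256
    d_s: int = 128
    hidden: int = 512
    pos_dim: int = 64
    d_k: int = 64
    n_heads: int = 4
    perc_dim: int = 64
    grl_coeff: float = 1.0
    seed: int = 0
    params: dict = field(default_factory=dict)
    gcn: Optional[GcnStack] = None

    def __post_init__(self) -> None:
        if self.params:
            return
        rng = np.random.default_rng(self.seed)
        G, df, ds, hd = self.n_genes, self.d_f, self.d_s, self.hidden
        p = self.params
        # encoder E: G -> hidden -> d_f
        p["enc.w0"], p["enc.b0"] = _glorot(rng, G, hd), _zeros(hd)
        p["enc.w1"], p["enc.b1"] = _glorot(rng, hd, df), _zeros(df)
        # decoder D: d_f -> hidden -> G, two conditioned layers
        widths = [(df, hd), (hd, G)]
        for l, (a, b) in enumerate(widths):
            p[f"dec.{l}.w"], p[f"dec.{l}.b"] = _glorot(rng, a, b), _zeros(b)
            p[f"dec.{l}.pos"] = _glorot(rng, self.pos_dim, a)
            hdk = self.n_heads * self.d_k
            p[f"dec.{l}.wq"] = _glorot(rng, a, hdk)
            p[f"dec.{l}.wk"] = _glorot(rng, self.perc_dim, hdk)
            p[f"dec.{l}.wv"] = _glorot(rng, self.perc_dim, hdk)
            p[f"dec.{l}.wo"] = _glorot(rng, hdk, a)
        # shared extractor: d_f -> 256 -> d_s
        p["shared.w0"], p["shared.b0"] = _glorot(rng, df, 256), _zeros(256)
        p["shared.w1"], p["shared.b1"] = _glorot(rng, 256, ds), _zeros(ds)
        # heads
        p["prop.w"], p["prop.b"] = _glorot(rng, ds, self.n_cell_types), \
            _zeros(self.n_cell_types)
        p["hist.w"], p["hist.b"] = _glorot(rng, ds, self.n_path_classes), \
            _zeros(self.n_path_classes)
        # domain discriminator M: d_f -> 64 -> 1
        p["disc.w0"], p["disc.b0"] = _glorot(rng, df, 64), _zeros(64)
        p["disc.w1"], p["disc.b1"] = _glorot(rng, 64, 1), _zeros(1)
        # graph encoder: G -> hidden -> G (shared gene space with E's input).
        # Initialized near identity so the stack starts as pure two-hop
        # neighborhood smoothing of expression; training then departs from it.
        if hd >= G:
            w0 = 0.01 * _glorot(rng, G, hd).data
            w0[:, :G] += np.eye(G)
            w1 = 0.01 * _glorot(rng, hd, G).data
            w1[:G, :] += np.eye(G)
            self.gcn = GcnStack([Tensor.param(w0), Tensor.param(w1)])
        else:
            self.gcn = GcnStack.init([G, hd, G], rng)

    def parameters(self) -> list[Tensor]:
        ps = list(self.params.values())
        if self.gcn is not None:
            ps += self.gcn.weights
        return ps

    # -- checkpointing --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        for i, w in enumerate(self.gcn.weights):
            arrays[f"gcn.{i}"] = w.data
        cfg = dict(n_genes=self.n_genes, n_cell_types=self.n_cell_types,
                   n_path_classes=self.n_path_classes, d_f=self.d_f,
                   d_s=self.d_s, hidden=self.hidden, pos_dim=self.pos_dim,
                   d_k=self.d_k, n_heads=self.n_heads, perc_dim=self.perc_dim,
                   grl_coeff=self.grl_coeff, seed=self.seed)
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load(path: str | Path) -> "ModelParams":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            model = ModelParams(**cfg)
            for k in model.params:
                model.params[k].data = data[k].copy()
            for i, w in enumerate(model.gcn.weights):
                w.data = data[f"gcn.{i}"].copy()
        return model


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _maybe_data(out: Tensor, was_tensor: bool):
    return out if was_tensor else out.data


def encode(model: ModelParams, x):
    """Shared encoder E; accepts raw or graph-encoded rows (both width G)."""
    was = isinstance(x, Tensor)
    h = _as_tensor(x)
    if h.shape[1] != model.n_genes:
        raise ValueError(f"input width {h.shape[1]} != n_genes {model.n_genes}")
    p = model.params
    h = (h @ p["enc.w0"] + p["enc.b0"]).relu()
    h = h @ p["enc.w1"] + p["enc.b1"]
    return _maybe_data(h, was)


def positional_encode(coords: SpotCoordinates | np.ndarray,
                      dim: int) -> np.ndarray:
    """Sinusoidal encoding of min-max-normalized (x, y) at dim/4 frequencies.

    Band k of axis t contributes sin(t · f_k) and cos(t · f_k) with
    f_0 = 1 and geometric growth up to 100; every entry lies in [−1, 1].
    """
    if dim % 2 != 0:
        raise ValueError("positional encoding dim must be even")
    xy = coords.xy if isinstance(coords, SpotCoordinates) else np.asarray(coords)
    span = xy.max(axis=0) - xy.min(axis=0)
    span[span == 0] = 1.0
    norm = (xy - xy.min(axis=0)) / span
    n_freq = dim // 4
    if n_freq == 0:
        raise ValueError("dim must be at least 4")
    freqs = 100.0 ** (np.arange(n_freq) / max(1, n_freq - 1))
    out = np.empty((xy.shape[0], dim))
    for axis in range(2):
        angles = norm[:, axis:axis + 1] * freqs[None, :]
        base = axis * 2 * n_freq
        out[:, base:base + n_freq] = np.sin(angles)
        out[:, base + n_freq:base + 2 * n_freq] = np.cos(angles)
    return out


def decode_conditional(model: ModelParams, latent,
                       perceptual=None, pos: Optional[np.ndarray] = None):
    """Conditional decoder D.

    Each layer adds a projected positional encoding, applies one-key
    cross-modal attention over the spot's perceptual embedding with a
    residual connection, then the MLP sublayer.  With a single key per
    spot the attention weight is exactly 1, so the attended value is the
    projected perceptual row itself; the query/key projections are kept
    for the multi-key mode.  When ``perceptual`` is None (simulated
    branch) the attention block is skipped identically.
    """
    was = isinstance(latent, Tensor)
    h = _as_tensor(latent)
    p = model.params
    perc = _as_tensor(perceptual) if perceptual is not None else None
    if perc is not None and perc.shape[0] != h.shape[0]:
        raise ValueError("perceptual rows must align with latent rows")
    if pos is not None and np.asarray(pos).shape[0] != h.shape[0]:
        raise ValueError("positional rows must align with latent rows")
    n_layers = 2
    for l in range(n_layers):
        if pos is not None:
            h = h + Tensor(np.asarray(pos)) @ p[f"dec.{l}.pos"]
        if perc is not None:
            attended = (perc @ p[f"dec.{l}.wv"]) @ p[f"dec.{l}.wo"]
            h = h + attended
        h = h @ p[f"dec.{l}.w"] + p[f"dec.{l}.b"]
        if l < n_layers - 1:
            h = h.relu()
    return _maybe_data(h, was)


def shared_extract(model: ModelParams, latent):
    was = isinstance(latent, Tensor)
    h = _as_tensor(latent)
    p = model.params
    h = (h @ p["shared.w0"] + p["shared.b0"]).relu()
    h = h @ p["shared.w1"] + p["shared.b1"]
    return _maybe_data(h, was)


def predict_proportions(model: ModelParams, shared):
    """C_prop: linear head + row softmax onto the cell-type simplex."""
    was = isinstance(shared, Tensor)
    h = _as_tensor(shared)
    logits = h @ model.params["prop.w"] + model.params["prop.b"]
    return _maybe_data(softmax_rows(logits), was)


def predict_pathology(model: ModelParams, shared):
    """C_hist: linear head + row softmax over pathology classes."""
    was = isinstance(shared, Tensor)
    h = _as_tensor(shared)
    logits = h @ model.params["hist.w"] + model.params["hist.b"]
    return _maybe_data(softmax_rows(logits), was)


def grl_discriminate(model: ModelParams, latent, grl_coeff: Optional[float] = None):
    """Domain probability per spot, through the gradient-reversal layer.

    Forward pass is identical to running M directly; the backward pass
    scales the gradient reaching the latent by −grl_coeff.
    """
    coeff = model.grl_coeff if grl_coeff is None else grl_coeff
    if coeff < 0:
        raise ValueError("grl_coeff must be >= 0")
    was = isinstance(latent, Tensor)
    h = grl(_as_tensor(latent), coeff)
    p = model.params
    h = (h @ p["disc.w0"] + p["disc.b0"]).relu()
    h = (h @ p["disc.w1"] + p["disc.b1"]).sigmoid()
    return _maybe_data(h, was)
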