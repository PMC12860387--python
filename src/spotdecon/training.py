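"""Losses, joint training loop, K-fold protocol, and deconvolution inference.

The total objective is

    L_total = L_deconv + λ1·L_hist + λ2·L_recon + λ3·L_match

where L_deconv and L_hist are categorical cross-entropies (summed over
spots and classes), L_recon is the squared reconstruction error of real
expression (sum as printed, or mean for training stability — the default),
and L_match is the binary cross-entropy of the domain discriminator reached
through the gradient-reversal layer.  Each epoch alternates paired
simulated/real batches; the simulated batch carries the deconvolution
supervision (only pseudo-spots have composition labels), the real batch
carries reconstruction, optional pathology classification, and both feed
the domain matcher.  One Adam step is taken per paired batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor
from .data_io import (ProportionMatrix, SpotExpressionMatrix, StDataset,
                      normalize_expression)
from .image_features import PerceptualPipeline
from .model import (ModelParams, decode_conditional, encode, grl_discriminate,
                    positional_encode, predict_pathology, predict_proportions,
                    shared_extract)
from .spatial_graph import SpatialGraph, build_knn_adjacency, gcn_encode

__all__ = ["LossWeights", "TrainConfig", "loss_deconv", "loss_hist",
           "loss_recon", "loss_match", "total_loss", "kfold_split", "fit",
           "deconvolve", "cross_validate"]

_EPS = 1e-12


@dataclass
class LossWeights:
    """λ1 (pathology), λ2 (reconstruction), λ3 (domain matching)."""

    lambda1: float = 0.1
    lambda2: float = 0.1
    lambda3: float = 0.01

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 400
    k_folds: int = 10
    seed: int = 0
    optimizer: str = "adam"
    graph_k: int = 5
    recon_reduction: str = "mean"

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _cross_entropy(y, yhat):
    """−Σ_ij y_ij log(ŷ_ij), summed; ŷ clamped to [1e-12, 1]."""
    if _is_tensor(y, yhat):
        y_t = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=float))
        return -(y_t * yhat.clamp(_EPS, 1.0).log()).sum()
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("label and prediction shapes differ")
    if np.any(yhat <= 0):
        yhat = np.clip(yhat, _EPS, None)
    return float(-(y * np.log(yhat)).sum())


def loss_deconv(y, yhat):
    """Categorical cross-entropy of predicted vs known spot composition."""
    yv = y.values if isinstance(y, ProportionMatrix) else y
    yh = yhat.values if isinstance(yhat, ProportionMatrix) else yhat
    return _cross_entropy(yv, yh)


def loss_hist(y, yhat):
    """Categorical cross-entropy of predicted pathology classes."""
    yv = getattr(y, "values", y)
    return _cross_entropy(yv, yhat)


def loss_recon(target, recon, reduction: str = "sum"):
    """Squared reconstruction error, summed or averaged over entries."""
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    if _is_tensor(target, recon):
        t = target if isinstance(target, Tensor) else Tensor(np.asarray(target))
        diff = (t - recon) ** 2.0
        return diff.sum() if reduction == "sum" \
            else diff.sum() * (1.0 / diff.data.size)
    t = np.asarray(target, dtype=float)
    r = np.asarray(recon, dtype=float)
    if t.shape != r.shape:
        raise ValueError("target and reconstruction shapes differ")
    sq = (t - r) ** 2
    return float(sq.sum()) if reduction == "sum" else float(sq.mean())


def _loss_recon_tensor(target: np.ndarray, recon: Tensor,
                       reduction: str) -> Tensor:
    diff = (Tensor(np.asarray(target, dtype=float)) - recon) ** 2.0
    if reduction == "sum":
        return diff.sum()
    return diff.sum() * (1.0 / diff.data.size)


def loss_match(real_probs, simu_probs, c: Optional[np.ndarray] = None):
    """Domain-matching BCE: −(1/R)Σ[c log p_real + (1−c) log(1−p_simu)].

    R is the aggregate number of rows across both domains; ``c`` defaults
    to ones for real rows and zeros for simulated rows.
    """
    if _is_tensor(real_probs, simu_probs):
        pr = real_probs.clamp(_EPS, 1 - _EPS)
        ps = simu_probs.clamp(_EPS, 1 - _EPS)
        n = pr.data.size + ps.data.size
        return -(pr.log().sum() + (1.0 - ps).log().sum()) * (1.0 / n)
    pr = np.clip(np.asarray(real_probs, dtype=float).ravel(), _EPS, 1 - _EPS)
    ps = np.clip(np.asarray(simu_probs, dtype=float).ravel(), _EPS, 1 - _EPS)
    if np.any((pr <= 0) | (pr >= 1)) or np.any((ps <= 0) | (ps >= 1)):
        raise ValueError("probabilities must lie strictly in (0,1)")
    n = pr.size + ps.size
    return float(-(np.log(pr).sum() + np.log1p(-ps).sum()) / n)


def total_loss(components: Sequence[float], w: LossWeights):
    """L_deconv + λ1·L_hist + λ2·L_recon + λ3·L_match."""
    deconv, hist, recon, match = components
    return deconv + w.lambda1 * hist + w.lambda2 * recon + w.lambda3 * match


def kfold_split(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Random partition into K folds of near-equal size (differ by ≤ 1)."""
    if n < k:
        raise ValueError(f"cannot split {n} spots into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _prepare_expression(m: SpotExpressionMatrix) -> np.ndarray:
    if m.layer_tag == "counts":
        m = normalize_expression(m)
    return np.asarray(m.values, dtype=float)


def fit(simulated: StDataset, real: StDataset, model: ModelParams,
        cfg: TrainConfig, w: LossWeights,
        *, graph: Optional[SpatialGraph] = None,
        perceptual: Optional[np.ndarray] = None,
        train_real_idx: Optional[np.ndarray] = None,
        use_sce: bool = True, use_sfe: bool = True
        ) -> tuple[ModelParams, dict[str, list[float]]]:
    """Jointly train all components end-to-end; returns per-epoch loss curves.

    ``train_real_idx`` restricts the real-side losses to a subset of spots
    (used by cross-validation); the spatial graph still spans all real spots
    by default (transductive).  ``use_sce`` / ``use_sfe`` disable the graph
    encoder / perceptual conditioning for ablation runs.
    """
    if simulated.proportions is None:
        raise ValueError("simulated dataset must carry proportion labels")
    if w.lambda1 > 0 and real.pathology is None:
        raise ValueError("lambda1 > 0 requires real pathology labels")
    if w.lambda3 > 0 and (simulated is None or real is None):
        raise ValueError("lambda3 > 0 requires both domains")
    if simulated.expression.gene_ids != real.expression.gene_ids:
        raise ValueError("gene spaces not aligned; run align_genes first")

    x_sim = _prepare_expression(simulated.expression)
    x_real = _prepare_expression(real.expression)
    y_prop = simulated.proportions.values
    y_hist = real.pathology.values if real.pathology is not None else None

    if use_sce:
        if graph is None:
            if real.coords is None:
                raise ValueError("real dataset needs coordinates for the graph")
            graph = build_knn_adjacency(real.coords, k=cfg.graph_k)
    if perceptual is None and use_sfe and real.image is not None \
            and real.coords is not None:
        perceptual = PerceptualPipeline(dim=model.perc_dim).embed(
            real.image, real.coords)
    if not use_sfe:
        perceptual = None
    pos = positional_encode(real.coords, model.pos_dim) \
        if real.coords is not None else None

    curves: dict[str, list[float]] = {k: [] for k in
                                      ("deconv", "hist", "recon", "match", "total")}
    if cfg.epochs == 0:
        return model, curves

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n_sim = x_sim.shape[0]
    real_pool = np.arange(x_real.shape[0]) if train_real_idx is None \
        else np.asarray(train_real_idx)

    for _epoch in range(cfg.epochs):
        sim_order = rng.permutation(n_sim)
        real_order = rng.permutation(real_pool)
        epoch_losses = np.zeros(5)
        n_batches = 0
        real_cursor = 0
        for start in range(0, n_sim, cfg.batch_size):
            sim_idx = sim_order[start:start + cfg.batch_size]
            # cycle through real spots so each epoch covers all of them
            take = min(cfg.batch_size, real_pool.size)
            if real_cursor + take > real_order.size:
                real_order = rng.permutation(real_pool)
                real_cursor = 0
            real_idx = real_order[real_cursor:real_cursor + take]
            real_cursor += take
            opt.zero_grad()

            # simulated branch: raw rows -> E -> F_shared -> C_prop
            xb = Tensor(x_sim[sim_idx])
            lat_sim = encode(model, xb)
            prop_hat = predict_proportions(model, shared_extract(model, lat_sim))
            l_deconv = loss_deconv(y_prop[sim_idx], prop_hat)

            # real branch: (GCN ->) E -> decoder / C_hist
            x_real_t = Tensor(x_real)
            x_real_g = gcn_encode(x_real_t, graph, model.gcn) if use_sce \
                else x_real_t
            lat_real_all = encode(model, x_real_g)
            lat_real = lat_real_all.take_rows(real_idx)
            perc_b = Tensor(perceptual[real_idx]) if perceptual is not None \
                else None
            pos_b = pos[real_idx] if pos is not None else None
            recon = decode_conditional(model, lat_real, perc_b, pos_b)
            l_recon = _loss_recon_tensor(x_real[real_idx], recon,
                                         cfg.recon_reduction)

            if w.lambda1 > 0:
                hist_hat = predict_pathology(model,
                                             shared_extract(model, lat_real))
                l_hist = loss_hist(y_hist[real_idx], hist_hat)
            else:
                l_hist = Tensor(0.0)

            if w.lambda3 > 0:
                p_real = grl_discriminate(model, lat_real)
                p_sim = grl_discriminate(model, lat_sim)
                l_match = loss_match(p_real, p_sim)
            else:
                l_match = Tensor(0.0)

            l_total = l_deconv + w.lambda1 * l_hist + w.lambda2 * l_recon \
                + w.lambda3 * l_match
            l_total.backward()
            opt.step()

            epoch_losses += np.array([l_deconv.item(), l_hist.item(),
                                      l_recon.item(), l_match.item(),
                                      l_total.item()])
            n_batches += 1
        for key, val in zip(("deconv", "hist", "recon", "match", "total"),
                            epoch_losses / n_batches):
            curves[key].append(float(val))
    return model, curves


def deconvolve(model: ModelParams, real: StDataset,
               *, graph: Optional[SpatialGraph] = None,
               type_names: Optional[list[str]] = None,
               graph_k: int = 5, use_sce: bool = True) -> ProportionMatrix:
    """Predict per-spot cell-type proportions for a real dataset."""
    if real.expression.n_genes != model.n_genes:
        raise ValueError(
            f"gene-space mismatch: model expects {model.n_genes} genes, "
            f"dataset has {real.expression.n_genes}")
    x = _prepare_expression(real.expression)
    if use_sce:
        if graph is None:
            graph = build_knn_adjacency(real.coords, k=graph_k)
        x = gcn_encode(x, graph, model.gcn)
    shared = shared_extract(model, encode(model, x))
    probs = predict_proportions(model, shared)
    names = type_names or [f"type_{t}" for t in range(model.n_cell_types)]
    return ProportionMatrix(probs, names, list(real.expression.spot_ids))


def cross_validate(simulated: StDataset, real: StDataset,
                   model_factory, cfg: TrainConfig, w: LossWeights,
                   *, inductive: bool = False
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """K-fold protocol over real spots.

    Per fold, a fresh model is trained with the held-out real spots
    contributing no real-side gradient, then those spots are predicted
    once.  By default the spatial graph spans all spots (transductive);
    ``inductive`` rebuilds it from the training spots only and predicts
    held-out spots without graph encoding.
    Returns (held-out indices, predicted proportion rows) per fold, ready
    for :func:`spotdecon.metrics.evaluate_folds`.
    """
    n = real.expression.n_spots
    folds = kfold_split(n, cfg.k_folds, cfg.seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    full_graph = None if inductive else \
        build_knn_adjacency(real.coords, k=cfg.graph_k)
    for f_i, held in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), held)
        model = model_factory()
        model, _ = fit(simulated, real, model, cfg, w, graph=full_graph,
                       train_real_idx=train_idx)
        props = deconvolve(model, real, graph=full_graph,
                           use_sce=full_graph is not None)
        out.append((held, props.values[held]))
    return out
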