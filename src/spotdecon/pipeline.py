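"""End-to-end orchestration shared by the CLI and the evaluation scripts.

``simulate_run`` materializes a complete synthetic study from one config:
a single-cell reference, labelled pseudo-spots (the simulated domain), and
a region-structured slide whose spots get region-biased expression with
known planted composition (the stand-in for the real domain).
``train_run`` aligns gene spaces, trains the multitask autoencoder, and
``deconvolve_run`` predicts proportions for the real spots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import data_io, simulator
from .config import RunConfig
from .data_io import StDataset
from .model import ModelParams
from .training import LossWeights, TrainConfig, deconvolve, fit

__all__ = ["SimulatedStudy", "simulate_run", "build_model", "train_run"]


@dataclass
class SimulatedStudy:
    reference: simulator.SyntheticScRna
    simulated: StDataset          # pseudo-spots with proportion labels
    real: StDataset               # slide spots: expression+coords+image+labels
    real_truth: data_io.ProportionMatrix
    dominant_type: np.ndarray     # planted dominant cell type per real spot
    slide: simulator.SyntheticSlide


def simulate_run(cfg: RunConfig) -> SimulatedStudy:
    sim = cfg["simulator"]
    ref = simulator.generate_synthetic_scrna(
        n_cells=sim["n_cells"], n_genes=sim["n_genes"], n_types=sim["n_types"],
        marker_fold=sim["marker_fold"], base_rate=sim["base_rate"],
        seed=cfg.module_seed("scrna"))
    ps_cfg = simulator.PseudoSpotConfig(
        n_spots=sim["n_spots"], mu_cells=sim["mu_cells"],
        sigma_cells=sim["sigma_cells"], mu_types=sim["mu_types"],
        sigma_types=sim["sigma_types"],
        downsample_fraction=sim["downsample_fraction"],
        seed=cfg.module_seed("pseudospots"))
    sim_expr, sim_props = simulator.simulate_pseudospots(ref, ps_cfg)
    simulated = StDataset(expression=sim_expr, proportions=sim_props)

    slide = simulator.generate_synthetic_slide(
        n_rows=sim["slide_rows"], n_cols=sim["slide_cols"],
        spacing_px=sim["spacing_px"], n_regions=sim["n_regions"],
        image_margin_px=sim["image_margin_px"], seed=cfg.module_seed("slide"))
    # the slide stands in for real ST data: binomial thinning emulates the
    # much shallower sequencing depth of spot-based platforms
    slide_cfg = simulator.PseudoSpotConfig(
        n_spots=len(slide.coords.spot_ids), mu_cells=sim["mu_cells"],
        sigma_cells=sim["sigma_cells"], mu_types=sim["mu_types"],
        sigma_types=sim["sigma_types"],
        downsample_fraction=sim["real_downsample_fraction"],
        seed=cfg.module_seed("slide_expression"))
    real_expr, real_truth = simulator.simulate_slide_dataset(
        ref, slide, slide_cfg, dominant_weight=sim["dominant_weight"])
    real = StDataset(expression=real_expr, coords=slide.coords,
                     image=slide.image, pathology=slide.regions)
    dominant = slide.regions.class_indices % ref.n_types
    return SimulatedStudy(ref, simulated, real, real_truth, dominant, slide)


def build_model(cfg: RunConfig, n_genes: int, n_types: int,
                n_classes: int) -> ModelParams:
    m = cfg["model"]
    return ModelParams(n_genes=n_genes, n_cell_types=n_types,
                       n_path_classes=n_classes, d_f=m["d_f"], d_s=m["d_s"],
                       hidden=m["hidden"], pos_dim=m["pos_dim"], d_k=m["d_k"],
                       n_heads=cfg["sfe"]["heads"], perc_dim=cfg["sfe"]["dim"],
                       grl_coeff=m["grl_coeff"], seed=cfg.module_seed("model"))


def train_run(cfg: RunConfig, study: SimulatedStudy,
              *, epochs: Optional[int] = None,
              batch_size: Optional[int] = None,
              use_sce: bool = True, use_sfe: bool = True,
              seed: Optional[int] = None
              ) -> tuple[ModelParams, dict[str, list[float]]]:
    tr = cfg["training"]
    n_top = tr["n_top_genes"]
    sim_expr, real_expr = data_io.align_genes(study.simulated.expression,
                                              study.real.expression,
                                              n_top=n_top)
    simulated = StDataset(expression=sim_expr,
                          proportions=study.simulated.proportions)
    real = StDataset(expression=real_expr, coords=study.real.coords,
                     image=study.real.image, pathology=study.real.pathology)
    n_classes = len(study.real.pathology.class_names) \
        if study.real.pathology is not None else 1
    model = build_model(cfg, sim_expr.n_genes, study.reference.n_types,
                        n_classes)
    if seed is not None:
        model = ModelParams(
            n_genes=model.n_genes, n_cell_types=model.n_cell_types,
            n_path_classes=model.n_path_classes, d_f=model.d_f,
            d_s=model.d_s, hidden=model.hidden, pos_dim=model.pos_dim,
            d_k=model.d_k, n_heads=model.n_heads, perc_dim=model.perc_dim,
            grl_coeff=model.grl_coeff, seed=seed)
    train_cfg = TrainConfig(
        learning_rate=tr["learning_rate"],
        epochs=tr["epochs"] if epochs is None else epochs,
        batch_size=tr["batch_size"] if batch_size is None else batch_size,
        k_folds=tr["k_folds"],
        seed=cfg.module_seed("training") if seed is None else seed,
        graph_k=cfg["graph"]["k"])
    weights = LossWeights(tr["lambda1"], tr["lambda2"], tr["lambda3"])
    model, curves = fit(simulated, real, model, train_cfg, weights,
                        use_sce=use_sce, use_sfe=use_sfe)
    model._trained_real = real  # type: ignore[attr-defined]
    return model, curves


def reconstruction_pcc(model: ModelParams, real: StDataset,
                       image: Optional[np.ndarray] = None) -> float:
    """Mean per-spot PCC between normalized expression and its reconstruction.

    The decoder is conditioned on the perceptual embedding of ``image``
    (default: the dataset's own image), so this is the model output that
    responds to histology artifacts — proportion prediction itself does not
    consume the image at inference time.
    """
    from .image_features import PerceptualPipeline
    from .metrics import pcc
    from .model import decode_conditional, encode as enc, positional_encode
    from .spatial_graph import build_knn_adjacency, gcn_encode
    from .training import _prepare_expression

    x = _prepare_expression(real.expression)
    graph = build_knn_adjacency(real.coords, k=5)
    latent = enc(model, gcn_encode(x, graph, model.gcn))
    img = real.image if image is None else image
    perc = PerceptualPipeline(dim=model.perc_dim).embed(img, real.coords)
    pos = positional_encode(real.coords, model.pos_dim)
    recon = decode_conditional(model, latent, perc, pos)
    return float(np.mean([pcc(x[i], recon[i]) for i in range(x.shape[0])]))
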