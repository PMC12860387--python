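"""Synthetic data generation: single-cell references, pseudo-spots, slides.

Pseudo-spots are built the way deconvolution benchmarks build them: per
spot, draw the number of cells ``N_c`` and number of cell types ``N_t``
from normal distributions (rounded and truncated), pick ``N_t`` types
uniformly, sample cells of those types with replacement proportionally to
their abundance in the reference, and sum their count rows.  The recorded
proportion label is the exact ratio of sampled cells per type.  Count
matrices can then be binomially downsampled (per-entry thinning) to mimic
the shallower depth of real spot data.

A synthetic slide supplies the pieces the histology-aware parts of the
model need without real imagery: a regular spot grid, contiguous seed-grown
tissue regions, a region-tinted RGB image, and one-hot region labels.
In-silico artifacts (cracks, folds, stain irregularities) perturb that
image for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_io import (PathologyLabels, ProportionMatrix, SpotCoordinates,
                      SpotExpressionMatrix)

__all__ = [
    "SyntheticScRna", "PseudoSpotConfig", "SyntheticSlide",
    "generate_synthetic_scrna", "simulate_pseudospots", "downsample_counts",
    "generate_synthetic_slide", "apply_artifact", "simulate_slide_dataset",
]


@dataclass
class SyntheticScRna:
    """A marker-gene-separated synthetic single-cell reference."""

    counts: np.ndarray              # cells × genes, non-negative ints
    cell_types: np.ndarray          # per-cell type index in [0, n_types)
    marker_map: dict[int, list[int]]
    params: dict

    @property
    def n_types(self) -> int:
        return len(self.marker_map)

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene_{j}" for j in range(self.counts.shape[1])]

    @property
    def type_names(self) -> list[str]:
        return [f"type_{t}" for t in range(self.n_types)]


@dataclass
class PseudoSpotConfig:
    """Sampling parameters for pseudo-spot construction."""

    n_spots: int = 500
    mu_cells: float = 10.0
    sigma_cells: float = 3.0
    mu_types: float = 3.0
    sigma_types: float = 1.0
    downsample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.mu_cells < 1:
            raise ValueError("mu_cells must be >= 1")
        if self.sigma_cells < 0 or self.sigma_types < 0:
            raise ValueError("sigma parameters must be >= 0")
        if not (0 < self.downsample_fraction <= 1):
            raise ValueError("downsample_fraction must be in (0, 1]")


@dataclass
class SyntheticSlide:
    coords: SpotCoordinates
    image: np.ndarray               # H × W × 3 uint8
    regions: PathologyLabels
    region_geometry: dict[int, np.ndarray]   # region -> polygon vertices (px)


def generate_synthetic_scrna(n_cells: int = 2000, n_genes: int = 200,
                             n_types: int = 4, marker_fold: float = 8.0,
                             base_rate: float = 1.0,
                             seed: int = 0) -> SyntheticScRna:
    """Poisson counts with per-type marker genes elevated ``marker_fold``-fold.

    Genes are split evenly across types as markers; a marker's Poisson mean
    is ``marker_fold * base_rate`` inside its own type and ``base_rate``
    elsewhere.  Cells are assigned round-robin so every type is populated.
    """
    if n_types > n_genes:
        raise ValueError("n_types cannot exceed n_genes")
    if marker_fold <= 1:
        raise ValueError("marker_fold must be > 1")
    rng = np.random.default_rng(seed)
    cell_types = np.arange(n_cells) % n_types
    rng.shuffle(cell_types)
    markers_per_type = n_genes // n_types
    marker_map = {t: list(range(t * markers_per_type, (t + 1) * markers_per_type))
                  for t in range(n_types)}
    rates = np.full((n_types, n_genes), base_rate, dtype=float)
    for t, genes in marker_map.items():
        rates[t, genes] = marker_fold * base_rate
    counts = rng.poisson(rates[cell_types])
    return SyntheticScRna(counts.astype(np.int64), cell_types, marker_map,
                          dict(n_cells=n_cells, n_genes=n_genes,
                               n_types=n_types, marker_fold=marker_fold,
                               base_rate=base_rate, seed=seed))


def _draw_spot_composition(rng: np.random.Generator, cfg: PseudoSpotConfig,
                           n_types: int,
                           type_weights: Optional[np.ndarray] = None
                           ) -> tuple[int, np.ndarray]:
    """Draw (N_c, chosen type set) for one spot, truncating as specified."""
    n_c = max(1, int(round(rng.normal(cfg.mu_cells, cfg.sigma_cells))))
    n_t = int(round(rng.normal(cfg.mu_types, cfg.sigma_types)))
    n_t = min(max(1, n_t), n_types)
    if type_weights is None:
        chosen = rng.choice(n_types, size=n_t, replace=False)
    else:
        p = np.asarray(type_weights, dtype=float)
        chosen = rng.choice(n_types, size=n_t, replace=False, p=p / p.sum())
    return n_c, chosen


def _sample_spot_cells(rng: np.random.Generator, ref: SyntheticScRna,
                       n_c: int, chosen: np.ndarray,
                       dominant: Optional[int] = None,
                       dominant_weight: float = 0.7) -> np.ndarray:
    """Sample ``n_c`` cell indices of the chosen types, abundance-weighted."""
    pool_mask = np.isin(ref.cell_types, chosen)
    pool = np.flatnonzero(pool_mask)
    weights = np.ones(pool.size, dtype=float)
    if dominant is not None and dominant in chosen and chosen.size > 1:
        is_dom = ref.cell_types[pool] == dominant
        n_dom, n_other = is_dom.sum(), (~is_dom).sum()
        if n_dom and n_other:
            weights[is_dom] = dominant_weight / n_dom
            weights[~is_dom] = (1 - dominant_weight) / n_other
    return rng.choice(pool, size=n_c, replace=True, p=weights / weights.sum())


def simulate_pseudospots(ref: SyntheticScRna, cfg: PseudoSpotConfig,
                         *, type_weights: Optional[np.ndarray] = None,
                         dominant_per_spot: Optional[np.ndarray] = None,
                         dominant_weight: float = 0.7,
                         record_cells: bool = False
                         ) -> tuple[SpotExpressionMatrix, ProportionMatrix]:
    """Aggregate sampled single cells into labelled pseudo-spots.

    Proportion labels are exact sampled-count ratios k / N_c, so rows sum
    to 1 by construction.  ``dominant_per_spot`` optionally forces each
    spot's type set to include a given type and up-weights its cells —
    used when emulating region-structured tissue.  When ``record_cells``
    is true the sampled cell indices are attached to the returned
    expression matrix as ``.sampled_cells`` for replay verification.
    """
    if min(np.bincount(ref.cell_types, minlength=ref.n_types)) < 1:
        raise ValueError("reference must contain at least one cell per type")
    rng = np.random.default_rng(cfg.seed)
    n_types = ref.n_types
    expr = np.zeros((cfg.n_spots, ref.counts.shape[1]), dtype=np.int64)
    props = np.zeros((cfg.n_spots, n_types), dtype=float)
    sampled: list[np.ndarray] = []
    for s in range(cfg.n_spots):
        n_c, chosen = _draw_spot_composition(rng, cfg, n_types, type_weights)
        dom = None if dominant_per_spot is None else int(dominant_per_spot[s])
        if dom is not None and dom not in chosen:
            chosen = np.concatenate([[dom], chosen[:-1]]) if chosen.size > 1 \
                else np.array([dom])
        cells = _sample_spot_cells(rng, ref, n_c, chosen, dom, dominant_weight)
        expr[s] = ref.counts[cells].sum(axis=0)
        counts_per_type = np.bincount(ref.cell_types[cells], minlength=n_types)
        props[s] = counts_per_type / n_c
        if record_cells:
            sampled.append(cells)
    spot_ids = [f"pseudo_{s}" for s in range(cfg.n_spots)]
    m = SpotExpressionMatrix(expr, spot_ids, ref.gene_ids)
    if cfg.downsample_fraction < 1.0:
        m = downsample_counts(m, cfg.downsample_fraction, seed=cfg.seed + 1)
    if record_cells:
        m.sampled_cells = sampled  # type: ignore[attr-defined]
    return m, ProportionMatrix(props, ref.type_names, spot_ids)


def downsample_counts(m: SpotExpressionMatrix, fraction: float,
                      seed: int = 0) -> SpotExpressionMatrix:
    """Binomial thinning: each count becomes Binomial(count, fraction)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if m.layer_tag != "counts":
        raise ValueError("downsample_counts expects a counts layer")
    if fraction == 1.0:
        return SpotExpressionMatrix(m.values.copy(), list(m.spot_ids),
                                    list(m.gene_ids), "counts")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(m.values.astype(np.int64), fraction)
    return SpotExpressionMatrix(thinned, list(m.spot_ids), list(m.gene_ids),
                                "counts")


# ---------------------------------------------------------------------------
# synthetic slides and artifacts
# ---------------------------------------------------------------------------

_REGION_TINTS = np.array([
    [200, 120, 160],   # eosin-ish pink
    [140, 110, 190],   # hematoxylin-ish purple
    [220, 180, 140],   # pale tan
    [120, 160, 150],   # grey-green
    [190, 150, 200],
    [160, 190, 120],
], dtype=float)


def generate_synthetic_slide(n_rows: int = 16, n_cols: int = 16,
                             spacing_px: float = 60.0, n_regions: int = 4,
                             image_margin_px: int = 80,
                             seed: int = 0) -> SyntheticSlide:
    """Grid of spots with seed-grown contiguous regions and a tinted image.

    Regions grow by repeated frontier expansion from ``n_regions`` random
    grid seeds, so each is contiguous; the image is tinted per region (with
    mild pixel noise) so patches are region-discriminative.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    width = int(2 * image_margin_px + (n_cols - 1) * spacing_px)
    height = int(2 * image_margin_px + (n_rows - 1) * spacing_px)
    if width <= 0 or height <= 0:
        raise ValueError("grid does not fit in a positive-size image")

    xs = image_margin_px + spacing_px * np.arange(n_cols)
    ys = image_margin_px + spacing_px * np.arange(n_rows)
    gx, gy = np.meshgrid(xs, ys)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    n_spots = xy.shape[0]
    spot_ids = [f"spot_{r}_{c}" for r in range(n_rows) for c in range(n_cols)]

    # seed-grown contiguous region assignment on the grid
    assign = -np.ones((n_rows, n_cols), dtype=int)
    seeds = rng.choice(n_spots, size=min(n_regions, n_spots), replace=False)
    frontiers: list[list[tuple[int, int]]] = []
    for reg, s in enumerate(seeds):
        r, c = divmod(s, n_cols)
        assign[r, c] = reg
        frontiers.append([(r, c)])
    while (assign < 0).any():
        for reg in rng.permutation(len(frontiers)):
            new_frontier = []
            for (r, c) in frontiers[reg]:
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols and assign[rr, cc] < 0:
                        assign[rr, cc] = reg
                        new_frontier.append((rr, cc))
            if new_frontier:
                frontiers[reg] = frontiers[reg] + new_frontier
    region_of_spot = assign.ravel()

    # paint image: nearest-spot region per pixel, then tint + noise
    image = np.empty((height, width, 3), dtype=np.uint8)
    px_y, px_x = np.mgrid[0:height, 0:width]
    col_idx = np.clip(np.round((px_x - image_margin_px) / spacing_px), 0,
                      n_cols - 1).astype(int)
    row_idx = np.clip(np.round((px_y - image_margin_px) / spacing_px), 0,
                      n_rows - 1).astype(int)
    pixel_region = assign[row_idx, col_idx]
    tints = _REGION_TINTS[np.arange(n_regions) % len(_REGION_TINTS)]
    base = tints[pixel_region]
    noise = rng.normal(0, 8.0, size=base.shape)
    image[:] = np.clip(base + noise, 0, 255).astype(np.uint8)

    onehot = np.zeros((n_spots, n_regions), dtype=int)
    onehot[np.arange(n_spots), region_of_spot] = 1
    regions = PathologyLabels(onehot, [f"region_{r}" for r in range(n_regions)],
                              spot_ids)

    # per-region bounding geometry: rectangle hulls of member pixel cells
    geometry: dict[int, np.ndarray] = {}
    half = spacing_px / 2.0
    for reg in range(n_regions):
        pts = xy[region_of_spot == reg]
        x0, y0 = pts.min(axis=0) - half
        x1, y1 = pts.max(axis=0) + half
        geometry[reg] = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])

    return SyntheticSlide(SpotCoordinates(xy, spot_ids), image, regions,
                          geometry)


def apply_artifact(image: np.ndarray, kind: str, severity: float,
                   seed: int = 0) -> np.ndarray:
    """Apply an in-silico H&E artifact; output dimensions unchanged.

    ``crack``: dark random polyline band; ``fold``: translucent duplicated
    band shifted and alpha-blended; ``stain``: hue/saturation shift inside
    random blobs; ``crack_fold_stain`` applies all three in that order.
    """
    if image.size == 0:
        raise ValueError("image is empty")
    if not (0 < severity <= 1):
        raise ValueError("severity must be in (0, 1]")
    kinds = {"crack": _crack, "fold": _fold, "stain": _stain}
    if kind == "crack_fold_stain":
        out = image
        for i, k in enumerate(("crack", "fold", "stain")):
            out = kinds[k](out, severity, np.random.default_rng(seed + i))
        return out
    if kind not in kinds:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return kinds[kind](image, severity, np.random.default_rng(seed))


def _polyline_mask(shape: tuple[int, int], rng: np.random.Generator,
                   width: int) -> np.ndarray:
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    x = rng.integers(0, w)
    y = 0
    pts = [(y, x)]
    while y < h - 1:
        y = min(h - 1, y + rng.integers(3, 12))
        x = int(np.clip(x + rng.integers(-15, 16), 0, w - 1))
        pts.append((y, x))
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        n = max(abs(y1 - y0), abs(x1 - x0), 1)
        ys = np.linspace(y0, y1, n + 1).round().astype(int)
        xs = np.linspace(x0, x1, n + 1).round().astype(int)
        for yy, xx in zip(ys, xs):
            mask[max(0, yy - width):yy + width + 1,
                 max(0, xx - width):xx + width + 1] = True
    return mask


def _crack(image: np.ndarray, severity: float,
           rng: np.random.Generator) -> np.ndarray:
    out = image.copy()
    width = max(1, int(round(severity * 6)))
    mask = _polyline_mask(image.shape[:2], rng, width)
    out[mask] = (out[mask].astype(float) * 0.25).astype(np.uint8)
    return out


def _fold(image: np.ndarray, severity: float,
          rng: np.random.Generator) -> np.ndarray:
    out = image.copy().astype(float)
    h, w = image.shape[:2]
    band_w = max(2, int(round(severity * 0.25 * w)))
    x0 = int(rng.integers(0, max(1, w - band_w)))
    shift = max(1, band_w // 3)
    band = out[:, x0:x0 + band_w]
    src = out[:, max(0, x0 - shift):max(0, x0 - shift) + band.shape[1]]
    if src.shape == band.shape:
        alpha = 0.55
        out[:, x0:x0 + band_w] = alpha * src * 0.7 + (1 - alpha) * band
    return np.clip(out, 0, 255).astype(np.uint8)


def _stain(image: np.ndarray, severity: float,
           rng: np.random.Generator) -> np.ndarray:
    out = image.copy().astype(float)
    h, w = image.shape[:2]
    n_blobs = 1 + int(round(severity * 4))
    yy, xx = np.mgrid[0:h, 0:w]
    shift = np.array([40.0, -25.0, 30.0]) * severity
    for _ in range(n_blobs):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        radius = (0.05 + 0.2 * severity) * min(h, w)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        out[blob] += shift
    return np.clip(out, 0, 255).astype(np.uint8)


def simulate_slide_dataset(ref: SyntheticScRna, slide: SyntheticSlide,
                           cfg: PseudoSpotConfig,
                           dominant_weight: float = 0.7
                           ) -> tuple[SpotExpressionMatrix, ProportionMatrix]:
    """Region-structured expression for a slide's spots.

    Each region is associated with one dominant cell type (region index
    modulo the number of types); spots sample cells with that type holding
    ``dominant_weight`` of the sampling mass, so the planted dominant type
    and the exact sampled proportions are both known.
    """
    region = slide.regions.class_indices
    dominant = region % ref.n_types
    cfg2 = PseudoSpotConfig(n_spots=len(slide.coords.spot_ids),
                            mu_cells=cfg.mu_cells, sigma_cells=cfg.sigma_cells,
                            mu_types=cfg.mu_types, sigma_types=cfg.sigma_types,
                            downsample_fraction=cfg.downsample_fraction,
                            seed=cfg.seed)
    expr, props = simulate_pseudospots(ref, cfg2, dominant_per_spot=dominant,
                                       dominant_weight=dominant_weight)
    expr.spot_ids = list(slide.coords.spot_ids)
    props.spot_ids = list(slide.coords.spot_ids)
    return expr, props
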