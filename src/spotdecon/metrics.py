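"""Evaluation metrics: PCC, global-statistics SSIM, RMSE, fold aggregation.

PCC and RMSE are computed per spot across its values and then averaged.
SSIM follows the global-statistic dialect: per gene the spot values are
max-normalized to [0, 1], rasterized onto the 2-D lattice implied by the
spot coordinates, and a single SSIM is computed from the whole-map means,
variances, and covariance (no sliding window), then averaged over genes.
Fold evaluation concatenates all held-out predictions first and computes
the metrics once on the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["MetricReport", "pcc", "ssim", "rmse", "rasterize",
           "evaluate_matrices", "evaluate_folds"]

C1_DEFAULT = 0.01 ** 2
C2_DEFAULT = 0.03 ** 2


@dataclass
class MetricReport:
    pcc_mean: float
    ssim_mean: float
    rmse: float
    pcc_per_spot: np.ndarray
    rmse_per_spot: np.ndarray
    ssim_per_gene: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return dict(pcc_mean=self.pcc_mean, ssim_mean=self.ssim_mean,
                    rmse=self.rmse)


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; raises on constant input rather than yielding NaN."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pcc needs two equal-length vectors of length >= 2")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum()) * np.sqrt((yc ** 2).sum())
    if denom == 0:
        raise ValueError("pcc undefined for a constant vector")
    return float((xc * yc).sum() / denom)


def ssim(a: np.ndarray, b: np.ndarray, c1: float = C1_DEFAULT,
         c2: float = C2_DEFAULT) -> float:
    """Global-statistics SSIM between two maps (population moments)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ssim inputs must have the same shape")
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                 / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("rmse of empty input")
    if x.shape != y.shape:
        raise ValueError("rmse inputs must have equal length")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def rasterize(values: np.ndarray, coords: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Snap spots to the integer lattice implied by their coordinate gaps.

    Returns (grid, occupancy mask); grid pitch per axis is the minimal
    positive coordinate gap, so regular grids map bijectively onto cells.
    """
    coords = np.asarray(coords, dtype=float)
    idx = np.empty_like(coords, dtype=int)
    for ax in range(2):
        vals = coords[:, ax]
        uniq = np.unique(vals)
        gaps = np.diff(uniq)
        pitch = gaps[gaps > 0].min() if (gaps > 0).any() else 1.0
        idx[:, ax] = np.round((vals - vals.min()) / pitch).astype(int)
    nx, ny = idx[:, 0].max() + 1, idx[:, 1].max() + 1
    grid = np.zeros((ny, nx))
    occupied = np.zeros((ny, nx), dtype=bool)
    for v, (ix, iy) in zip(values, idx):
        if occupied[iy, ix]:
            raise ValueError("two spots rasterize to the same grid cell")
        grid[iy, ix] = v
        occupied[iy, ix] = True
    return grid, occupied


def _ssim_per_gene(truth: np.ndarray, pred: np.ndarray,
                   coords: np.ndarray) -> np.ndarray:
    out = np.empty(truth.shape[1])
    for j in range(truth.shape[1]):
        t, p = truth[:, j], pred[:, j]
        t_max = t.max() if t.max() > 0 else 1.0
        p_max = p.max() if p.max() > 0 else 1.0
        grid_t, occ = rasterize(t / t_max, coords)
        grid_p, _ = rasterize(p / p_max, coords)
        out[j] = ssim(grid_t[occ], grid_p[occ])
    return out


def evaluate_matrices(truth: np.ndarray, pred: np.ndarray,
                      coords: Optional[np.ndarray] = None) -> MetricReport:
    """Spot-wise PCC/RMSE (then averaged) and per-gene SSIM (if coords given).

    Spots whose truth or prediction vector is constant (e.g. an exactly
    uniform composition) have undefined correlation; they appear as NaN in
    the per-spot breakdown and are excluded from the PCC average.
    """
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction shapes differ")
    pccs = np.empty(truth.shape[0])
    for i in range(truth.shape[0]):
        try:
            pccs[i] = pcc(truth[i], pred[i])
        except ValueError:
            pccs[i] = np.nan
    rmses = np.array([rmse(truth[i], pred[i]) for i in range(truth.shape[0])])
    ssims = None
    ssim_mean = float("nan")
    if coords is not None:
        ssims = _ssim_per_gene(truth, pred, coords)
        ssim_mean = float(ssims.mean())
    return MetricReport(float(np.nanmean(pccs)), ssim_mean,
                        float(rmses.mean()), pccs, rmses, ssims)


def evaluate_folds(fold_predictions: Sequence[tuple[np.ndarray, np.ndarray]],
                   truth: np.ndarray,
                   coords: Optional[np.ndarray] = None) -> MetricReport:
    """Concatenate held-out fold predictions, then evaluate once.

    ``fold_predictions`` is a sequence of (index array, predicted rows);
    the indices must cover every row of ``truth`` exactly once.
    """
    truth = np.asarray(truth, dtype=float)
    n = truth.shape[0]
    seen = np.zeros(n, dtype=int)
    pred = np.empty_like(truth)
    for idx, rows in fold_predictions:
        idx = np.asarray(idx)
        seen[idx] += 1
        pred[idx] = rows
    if np.any(seen != 1):
        bad = np.flatnonzero(seen != 1)
        raise ValueError(f"fold coverage error at spots {bad[:5].tolist()}")
    return evaluate_matrices(truth, pred, coords)
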