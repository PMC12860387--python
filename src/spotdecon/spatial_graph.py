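"""Spatial KNN graph construction and graph-convolutional encoding.

For each spot the k nearest Euclidean neighbors (self excluded, ties broken
by lower spot index) define a directed adjacency A; it is symmetrized by
logical OR, self-loops are added (Â = A + I), and the propagation operator
is the symmetric normalization D̂^(-1/2) Â D̂^(-1/2) with D̂_ii = Σ_j Â_ij.
A GCN layer then computes H(l+1) = ReLU(norm · H(l) · W(l)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data_io import SpotCoordinates

__all__ = ["SpatialGraph", "GcnStack", "build_knn_adjacency",
           "normalize_adjacency", "gcn_encode"]


@dataclass
class SpatialGraph:
    adjacency: np.ndarray           # binary, zero diagonal, symmetric
    k: int
    self_looped: np.ndarray = field(init=False)
    degrees: np.ndarray = field(init=False)
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a
        self.self_looped = a + np.eye(a.shape[0])
        self.degrees = self.self_looped.sum(axis=1)
        d_inv_sqrt = 1.0 / np.sqrt(self.degrees)
        self.normalized = self.self_looped * np.outer(d_inv_sqrt, d_inv_sqrt)

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]


def build_knn_adjacency(coords: SpotCoordinates, k: int = 5) -> SpatialGraph:
    """Directed KNN edges (ties by lower index), symmetrized by OR."""
    xy = coords.xy
    n = xy.shape[0]
    if n <= k:
        raise ValueError(f"need more spots ({n}) than neighbors k={k}")
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    a = np.zeros((n, n))
    for i in range(n):
        # lexsort: primary key distance, secondary key index (ascending)
        order = np.lexsort((np.arange(n), d2[i]))
        a[i, order[:k]] = 1
    directed = a.copy()
    a = np.logical_or(a, a.T).astype(float)
    g = SpatialGraph(a, k=k)
    g.directed = directed  # pre-symmetrization KNN relation, row sums == k
    return g


def normalize_adjacency(g: SpatialGraph) -> SpatialGraph:
    """Recompute the degree-normalized operator (idempotent by construction)."""
    return SpatialGraph(g.adjacency, k=g.k)


@dataclass
class GcnStack:
    """Per-layer weight matrices for the graph encoder."""

    weights: list           # list of Tensor, shapes d(l) × d(l+1)

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise ValueError("GCN stack needs at least one layer")
        for wa, wb in zip(self.weights[:-1], self.weights[1:]):
            if wa.shape[1] != wb.shape[0]:
                raise ValueError("consecutive GCN layer dims incompatible")

    @property
    def layer_dims(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    @staticmethod
    def init(layer_dims: list[int], rng: np.random.Generator) -> "GcnStack":
        weights = []
        for d_in, d_out in zip(layer_dims[:-1], layer_dims[1:]):
            lim = np.sqrt(6.0 / (d_in + d_out))
            weights.append(Tensor.param(rng.uniform(-lim, lim, (d_in, d_out))))
        return GcnStack(weights)


def gcn_encode(features, g: SpatialGraph, stack: GcnStack):
    """Run the GCN over all layers; returns same container kind as input.

    Accepts a numpy array (inference) or an autodiff :class:`Tensor`
    (training, gradients flow into the stack weights).
    """
    is_tensor = isinstance(features, Tensor)
    h = features if is_tensor else Tensor(np.asarray(features, dtype=float))
    if h.shape[1] != stack.weights[0].shape[0]:
        raise ValueError(
            f"feature dim {h.shape[1]} does not match GCN layer 0 input "
            f"dim {stack.weights[0].shape[0]}")
    if h.shape[0] != g.n_spots:
        raise ValueError("feature rows do not match graph size")
    norm = Tensor(g.normalized)
    for w in stack.weights:
        h = (norm @ h @ w).relu()
    return h if is_tensor else h.data
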