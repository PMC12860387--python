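"""Containers and I/O for spot-based spatial-transcriptomics datasets.

Reads 10x-style MatrixMarket triplets (matrix.mtx + genes/barcodes lists)
and dense CSVs into a :class:`SpotExpressionMatrix`, plus coordinate,
proportion and pathology-label CSVs.  Also hosts gene-space alignment
between a simulated reference-derived matrix and a real matrix (they must
share a gene space to share one encoder) and library-size normalization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SpotExpressionMatrix", "SpotCoordinates", "ProportionMatrix",
    "PathologyLabels", "StDataset", "read_spot_matrix", "read_coordinates",
    "read_pathology_labels", "align_genes", "normalize_expression",
    "write_proportions", "read_proportions", "write_spot_matrix",
    "write_coordinates",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i).strip() for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated {what}: {dupes[:5]}")
    return ids


@dataclass
class SpotExpressionMatrix:
    """Spots × genes expression, counts or normalized values."""

    values: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if sparse.issparse(self.values):  # pragma: no cover - defensive
            self.values = self.values.toarray()
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        self.spot_ids = _check_unique(self.spot_ids, "spot ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        if len(self.spot_ids) != self.values.shape[0]:
            raise ValueError("spot_ids length does not match row count")
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("gene_ids length does not match column count")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            r, c = neg[0]
            raise ValueError(
                f"negative expression value at spot row {r}, gene column {c}")
        if self.layer_tag not in ("counts", "normalized"):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "SpotExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        cols = [index[g] for g in genes]
        return SpotExpressionMatrix(self.values[:, cols], list(self.spot_ids),
                                    list(genes), self.layer_tag)


@dataclass
class SpotCoordinates:
    """Per-spot (x, y) in full-resolution image pixel units."""

    xy: np.ndarray
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("coordinates must have exactly 2 columns")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        self.spot_ids = _check_unique(self.spot_ids, "spot ids")
        if len(self.spot_ids) != self.xy.shape[0]:
            raise ValueError("spot_ids length does not match coordinate rows")


@dataclass
class ProportionMatrix:
    """Per-spot cell-type composition; every row lies on the simplex."""

    values: np.ndarray
    type_names: list[str]
    spot_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.type_names = _check_unique(self.type_names, "type names")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.type_names):
            raise ValueError("proportion shape does not match type_names")
        if np.any(self.values < 0):
            raise ValueError("proportions must be non-negative")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"proportion row {bad} sums to {sums[bad]}, not 1")


@dataclass
class PathologyLabels:
    """One-hot spot-level pathology classes."""

    values: np.ndarray
    class_names: list[str]
    spot_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.class_names = _check_unique(self.class_names, "class names")
        if not np.array_equal(np.unique(self.values), np.array([0, 1])) \
                and not np.array_equal(np.unique(self.values), np.array([1])):
            raise ValueError("pathology labels must be 0/1")
        if np.any(self.values.sum(axis=1) != 1):
            raise ValueError("each pathology row must have exactly one 1")

    @property
    def class_indices(self) -> np.ndarray:
        return self.values.argmax(axis=1)


@dataclass
class StDataset:
    """One slide's worth of aligned components, all indexed by the same spots."""

    expression: SpotExpressionMatrix
    coords: Optional[SpotCoordinates] = None
    image: Optional[np.ndarray] = None
    proportions: Optional[ProportionMatrix] = None
    pathology: Optional[PathologyLabels] = None

    def __post_init__(self) -> None:
        ids = self.expression.spot_ids
        if self.coords is not None and self.coords.spot_ids != ids:
            raise ValueError("coordinate spot ids do not match expression")
        for comp in (self.proportions, self.pathology):
            if comp is not None and comp.spot_ids is not None \
                    and comp.spot_ids != ids:
                raise ValueError("component spot ids do not match expression")
        for comp in (self.proportions, self.pathology):
            if comp is not None and comp.values.shape[0] != len(ids):
                raise ValueError("component row count does not match expression")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_spot_matrix(path: str | Path, format: str = "auto",
                     genes_in_rows: Optional[bool] = None) -> SpotExpressionMatrix:
    """Read an expression matrix from an MTX triplet or a dense CSV.

    For the triplet form, ``path`` is the ``.mtx`` file and sibling
    ``genes.tsv`` / ``barcodes.tsv`` files must exist.  On-disk orientation
    (genes×spots is the 10x convention) is auto-detected from the sidecar
    list lengths; a square matrix needs an explicit ``genes_in_rows`` flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if format == "auto":
        format = "mtx-triplet" if path.suffix == ".mtx" else "dense-csv"

    if format == "mtx-triplet":
        genes_file = path.with_name("genes.tsv")
        barcodes_file = path.with_name("barcodes.tsv")
        for f in (genes_file, barcodes_file):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file: {f}")
        genes = [l.split("\t")[0].strip()
                 for l in genes_file.read_text().splitlines() if l.strip()]
        barcodes = [l.strip() for l in barcodes_file.read_text().splitlines()
                    if l.strip()]
        mat = np.asarray(spio.mmread(os.fspath(path)).todense()
                         if sparse.issparse(spio.mmread(os.fspath(path)))
                         else spio.mmread(os.fspath(path)))
        n_r, n_c = mat.shape
        if n_r == n_c and len(genes) == len(barcodes):
            if genes_in_rows is None:
                raise ValueError(
                    "square matrix with equal sidecar lengths: pass genes_in_rows")
        else:
            if n_r == len(genes) and n_c == len(barcodes):
                genes_in_rows = True
            elif n_r == len(barcodes) and n_c == len(genes):
                genes_in_rows = False
            else:
                raise ValueError(
                    f"matrix shape {mat.shape} matches neither sidecar "
                    f"({len(genes)} genes, {len(barcodes)} barcodes)")
        if genes_in_rows:
            mat = mat.T
        return SpotExpressionMatrix(mat, barcodes, genes)

    if format == "dense-csv":
        df = pd.read_csv(path, index_col=0)
        return SpotExpressionMatrix(df.to_numpy(), [str(i) for i in df.index],
                                    [str(c) for c in df.columns])

    raise ValueError(f"unknown format {format!r}")


def write_spot_matrix(m: SpotExpressionMatrix, path: str | Path,
                      format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "mtx-triplet" if path.suffix == ".mtx" else "dense-csv"
    if format == "mtx-triplet":
        # 10x convention: genes in rows on disk
        spio.mmwrite(os.fspath(path), sparse.coo_matrix(m.values.T))
        path.with_name("genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
        path.with_name("barcodes.tsv").write_text("\n".join(m.spot_ids) + "\n")
    else:
        pd.DataFrame(m.values, index=m.spot_ids, columns=m.gene_ids).to_csv(path)


def read_coordinates(path: str | Path) -> SpotCoordinates:
    """Read a spot-id,x,y CSV; file order and pixel units preserved verbatim."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    ids: list[str] = []
    xy: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if lineno == 1 and not _is_number(parts[1]):
                continue  # header
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected id,x,y")
            try:
                x, y = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: non-numeric coordinate {parts[1:3]}") from exc
            ids.append(parts[0].strip())
            xy.append([x, y])
    return SpotCoordinates(np.array(xy), ids)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_coordinates(c: SpotCoordinates, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("spot_id,x,y\n")
        for sid, (x, y) in zip(c.spot_ids, c.xy):
            fh.write(f"{sid},{float(x)!r},{float(y)!r}\n")


def read_pathology_labels(path: str | Path,
                          class_names: Optional[list[str]] = None) -> PathologyLabels:
    """Read an id,class CSV into one-hot labels (classes sorted if not given)."""
    df = pd.read_csv(path, header=None, names=["spot_id", "label"],
                     skiprows=1 if _has_header(path) else 0)
    labels = df["label"].astype(str).str.strip().tolist()
    if class_names is None:
        class_names = sorted(set(labels))
    onehot = np.zeros((len(labels), len(class_names)), dtype=int)
    for i, lab in enumerate(labels):
        onehot[i, class_names.index(lab)] = 1
    return PathologyLabels(onehot, class_names,
                           [str(s).strip() for s in df["spot_id"]])


def _has_header(path: str | Path) -> bool:
    first = Path(path).read_text().splitlines()[0]
    return "spot" in first.lower() or "id" in first.lower().split(",")[0]


def align_genes(simulated: SpotExpressionMatrix, real: SpotExpressionMatrix,
                n_top: Optional[int] = 3000
                ) -> tuple[SpotExpressionMatrix, SpotExpressionMatrix]:
    """Restrict both matrices to one ordered shared gene list.

    The intersection keeps the simulated matrix's gene order; if ``n_top`` is
    given, it is further reduced to the ``n_top`` genes with the highest
    variance in the simulated matrix (deterministic, reference-driven).
    """
    real_set = set(real.gene_ids)
    shared = [g for g in simulated.gene_ids if g in real_set]
    if not shared:
        raise ValueError("no shared genes between simulated and real matrices")
    if n_top is not None and n_top < len(shared):
        sub = simulated.subset_genes(shared)
        var = sub.values.var(axis=0)
        # stable selection: by descending variance, ties by gene order
        order = np.lexsort((np.arange(len(shared)), -var))[:n_top]
        shared = [shared[i] for i in sorted(order)]
    return simulated.subset_genes(shared), real.subset_genes(shared)


def normalize_expression(m: SpotExpressionMatrix,
                         target_sum: float = 1e4) -> SpotExpressionMatrix:
    """Library-size scale each spot to ``target_sum`` total, then log1p.

    All-zero rows pass through as all-zero.  Applied identically to the
    simulated and real matrices so the shared encoder sees one scale.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    if m.layer_tag != "counts":
        raise ValueError("normalize_expression expects a counts layer")
    totals = m.values.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals, dtype=float),
                      where=totals > 0)
    return SpotExpressionMatrix(np.log1p(m.values * scale), list(m.spot_ids),
                                list(m.gene_ids), layer_tag="normalized")


def write_proportions(p: ProportionMatrix, path: str | Path) -> None:
    ids = p.spot_ids if p.spot_ids is not None \
        else [f"spot_{i}" for i in range(p.values.shape[0])]
    df = pd.DataFrame(p.values, index=ids, columns=p.type_names)
    df.to_csv(path, float_format="%.10g", index_label="spot_id")


def read_proportions(path: str | Path) -> ProportionMatrix:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy(dtype=float)
    # renormalize away round-trip float noise only; real violations still raise
    sums = vals.sum(axis=1, keepdims=True)
    if np.allclose(sums, 1.0, atol=1e-6):
        vals = vals / sums
    return ProportionMatrix(vals, [str(c) for c in df.columns],
                            [str(i) for i in df.index])
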