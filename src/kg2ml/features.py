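"""Sparse binary gene x EFO feature matrix.

Each row is a gene (labeled positive or unlabeled), each column an EFO
node from the labeling stage's feature vocabulary; entry (i, j) is 1 iff
gene i is adjacent to EFO j in the graph.  Genes rarely touch more than a
handful of EFO terms, so the matrix is held in Compressed Sparse Row
(CSR) form.  All-zero rows are retained: dropping genes without EFO links
would silently shrink the unlabeled set and bias the class-prior
estimate.  Persistence is MatrixMarket plus plain-text sidecars for the
row/column identifiers and labels, so a round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .graph import PropertyGraph
from .labeling import LabelSet, label_vector

__all__ = [
    "FeatureMatrix",
    "FeatureMatrixError",
    "build_feature_matrix",
    "prune_columns",
    "write_matrix",
    "read_matrix",
]


class FeatureMatrixError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Binary CSR matrix (genes x EFO features) with its label vector.

    ``row_cuis``/``col_cuis`` give the gene and EFO identity of each axis;
    ``y`` is 1 for labeled positives and 0 for unlabeled genes, aligned
    with rows.
    """

    row_cuis: list[str]
    col_cuis: list[str]
    values: sp.csr_matrix
    y: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.int8)
        self.y = np.asarray(self.y, dtype=np.int8)
        n, m = self.values.shape
        if n != len(self.row_cuis) or m != len(self.col_cuis):
            raise FeatureMatrixError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_cuis)} row / {len(self.col_cuis)} column ids"
            )
        if self.y.shape != (n,):
            raise FeatureMatrixError("label vector length does not match rows")
        if self.values.nnz and not np.all(self.values.data == 1):
            raise FeatureMatrixError("stored values must all be exactly 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_unlabeled(self) -> int:
        return int(np.sum(self.y == 0))


def build_feature_matrix(graph: PropertyGraph, labels: LabelSet) -> FeatureMatrix:
    """Encode Gene-EFO adjacency as a binary CSR matrix.

    Row order follows :func:`~kg2ml.labeling.label_vector` (positives
    first, each block CUI-sorted); column order is the CUI-sorted feature
    vocabulary.  Deterministic given graph and labels.
    """
    if not labels.feature_efo_cuis:
        raise FeatureMatrixError("empty feature set: no EFO features to learn from")
    rows = label_vector(labels)
    row_cuis = [c for c, _ in rows]
    y = np.array([cls for _, cls in rows], dtype=np.int8)
    col_cuis = sorted(labels.feature_efo_cuis)
    col_index = {c: j for j, c in enumerate(col_cuis)}

    ii: list[int] = []
    jj: list[int] = []
    for i, gene in enumerate(row_cuis):
        for nb in graph.adjacency[gene]:
            j = col_index.get(nb)
            if j is not None:
                ii.append(i)
                jj.append(j)
    values = sp.csr_matrix(
        (np.ones(len(ii), dtype=np.int8), (ii, jj)),
        shape=(len(row_cuis), len(col_cuis)),
    )
    return FeatureMatrix(row_cuis, col_cuis, values, y)


def prune_columns(fm: FeatureMatrix, min_count: int = 1) -> FeatureMatrix:
    """Drop feature columns observed in fewer than ``min_count`` genes.

    ``min_count=0`` is the identity.  Dropped column CUIs are recorded on
    the result as ``dropped_col_cuis``.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = np.asarray(fm.values.sum(axis=0)).ravel()
    keep = counts >= min_count
    if not keep.any():
        raise FeatureMatrixError("pruning would drop every feature column")
    out = FeatureMatrix(
        row_cuis=list(fm.row_cuis),
        col_cuis=[c for c, k in zip(fm.col_cuis, keep) if k],
        values=fm.values[:, keep],
        y=fm.y.copy(),
    )
    out.dropped_col_cuis = [c for c, k in zip(fm.col_cuis, keep) if not k]  # type: ignore[attr-defined]
    return out


def write_matrix(fm: FeatureMatrix, path: str | Path) -> dict[str, Path]:
    """Persist to ``path`` (directory): fm.mtx + row/column id sidecars + labels.

    Returns the mapping of artifact names to paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {
        "matrix": path / "fm.mtx",
        "rows": path / "row_cuis.txt",
        "cols": path / "col_cuis.txt",
        "labels": path / "labels.tsv",
    }
    mmwrite(out["matrix"], fm.values.tocoo(), field="integer")
    out["rows"].write_text("".join(f"{c}\n" for c in fm.row_cuis))
    out["cols"].write_text("".join(f"{c}\n" for c in fm.col_cuis))
    with out["labels"].open("w") as fh:
        fh.write("gene_cui\tclass\n")
        for c, cls in zip(fm.row_cuis, fm.y):
            fh.write(f"{c}\t{int(cls)}\n")
    return out


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Inverse of :func:`write_matrix`; validates sidecar/matrix agreement."""
    path = Path(path)
    values = sp.csr_matrix(mmread(path / "fm.mtx"))
    row_cuis = (path / "row_cuis.txt").read_text().splitlines()
    col_cuis = (path / "col_cuis.txt").read_text().splitlines()
    labels: dict[str, int] = {}
    with (path / "labels.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_cui", "class"]:
            raise FeatureMatrixError(f"unexpected labels header {header}")
        for line in fh:
            cui, cls = line.rstrip("\n").split("\t")
            labels[cui] = int(cls)
    if values.shape != (len(row_cuis), len(col_cuis)):
        raise FeatureMatrixError(
            f"matrix shape {values.shape} does not match sidecar ids "
            f"({len(row_cuis)} rows, {len(col_cuis)} cols)"
        )
    if set(labels) != set(row_cuis):
        raise FeatureMatrixError("labels.tsv genes do not match row_cuis.txt")
    y = np.array([labels[c] for c in row_cuis], dtype=np.int8)
    return FeatureMatrix(row_cuis, col_cuis, values, y)
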