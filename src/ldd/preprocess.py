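"""Expression-matrix I/O, basic QC and the linear embedding.

All downstream kernels, densities and clusters operate on the PCA
embedding produced here, never on the raw gene space.  PCA is used
deliberately: an orthogonal linear map keeps Euclidean geometry, so the
diffusion kernel, the k-means partition and ultimately the potential are
invariant under rotations of the input coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "Embedding",
    "load_expression",
    "save_expression",
    "qc_filter",
    "reduce_dimensions",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes real-valued matrix with identifiers.

    ``values[i, j]`` is the expression of gene ``gene_ids[j]`` in cell
    ``cell_ids[i]``.  Values must be finite and identifiers unique.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 cells, got {n}")
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        bad = ~np.isfinite(self.values)
        if bad.any():
            rows = sorted({self.cell_ids[i] for i in np.nonzero(bad)[0]})
            raise ValueError(
                f"non-finite expression values in cells: {', '.join(rows[:10])}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class Embedding:
    """Cells x m reduced coordinates: the state x in which the method runs.

    Coordinates are centred (column means ~ 0) and ``component_variances``
    is nonincreasing, as produced by PCA.
    """

    coords: np.ndarray
    component_variances: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.component_variances = np.asarray(self.component_variances, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValueError("embedding must be n x m with m >= 2")
        dv = np.diff(self.component_variances)
        if (dv > 1e-8 * max(1.0, self.component_variances[0])).any():
            raise ValueError("component variances must be nonincreasing")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.coords.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.coords.shape[1]


def load_expression(
    path: str | Path,
    format: str | None = None,
    *,
    transpose: bool = False,
    log1p: bool = False,
) -> ExpressionMatrix:
    """Read a cells x genes matrix from CSV/TSV (header row = gene names,
    first column = cell names) or MatrixMarket MTX with ``<stem>_cells.txt``
    and ``<stem>_genes.txt`` sidecars (one id per line).

    ``transpose`` flips a genes x cells file; ``log1p`` applies log(1+x).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv"
        )
    if format not in ("csv", "tsv", "mtx"):
        raise ValueError(f"unknown format {format!r}")

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        cell_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in df.columns]
    else:
        mat = mmread(path)
        values = np.asarray(mat.todense(), dtype=float) if hasattr(mat, "todense") else np.asarray(mat, dtype=float)
        stem = path.with_suffix("")
        cells_file = Path(f"{stem}_cells.txt")
        genes_file = Path(f"{stem}_genes.txt")
        if cells_file.exists():
            cell_ids = cells_file.read_text().split()
        else:
            cell_ids = [f"cell_{i}" for i in range(values.shape[0])]
        if genes_file.exists():
            gene_ids = genes_file.read_text().split()
        else:
            gene_ids = [f"gene_{j}" for j in range(values.shape[1])]

    if transpose:
        values = values.T
        cell_ids, gene_ids = gene_ids, cell_ids

    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.nonzero(bad)
        where = ", ".join(
            f"(row {cell_ids[a]}, column {gene_ids[b]})" for a, b in list(zip(i, j))[:10]
        )
        raise ValueError(f"non-finite entries at {where}")
    if log1p:
        if (values < 0).any():
            raise ValueError("log1p requested but matrix has negative entries")
        values = np.log1p(values)
    return ExpressionMatrix(values, cell_ids, gene_ids)


def save_expression(X: ExpressionMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a matrix in one of the formats :func:`load_expression` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        X.to_frame().to_csv(path, sep=sep)
    elif format == "mtx":
        mmwrite(str(path), coo_matrix(X.values))
        stem = path.with_suffix("")
        Path(f"{stem}_cells.txt").write_text("\n".join(X.cell_ids) + "\n")
        Path(f"{stem}_genes.txt").write_text("\n".join(X.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def qc_filter(
    X: ExpressionMatrix,
    min_cells_per_gene: int = 0,
    min_genes_per_cell: int = 0,
) -> ExpressionMatrix:
    """Drop genes expressed (nonzero) in fewer than ``min_cells_per_gene``
    cells, then cells expressing fewer than ``min_genes_per_cell`` of the
    remaining genes.  Thresholds of 0 are the identity."""
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("QC thresholds must be >= 0")
    gene_keep = (X.values != 0).sum(axis=0) >= min_cells_per_gene
    values = X.values[:, gene_keep]
    cell_keep = (values != 0).sum(axis=1) >= min_genes_per_cell
    n_drop_genes = int((~gene_keep).sum())
    n_drop_cells = int((~cell_keep).sum())
    if n_drop_genes or n_drop_cells:
        logger.info(
            "qc_filter removed %d genes and %d cells", n_drop_genes, n_drop_cells
        )
    if gene_keep.sum() == 0:
        raise ValueError("QC removed every gene; lower min_cells_per_gene")
    if cell_keep.sum() < 2:
        raise ValueError("QC removed all (or all but one) cells; lower thresholds")
    return ExpressionMatrix(
        values[cell_keep],
        [c for c, k in zip(X.cell_ids, cell_keep) if k],
        [g for g, k in zip(X.gene_ids, gene_keep) if k],
    )


def reduce_dimensions(X: ExpressionMatrix, m: int = 2, seed: int = 0) -> Embedding:
    """Project onto the top-``m`` principal components after centring.

    Deterministic up to component sign; the sign is fixed so that the
    largest-magnitude loading of each component is positive.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if m > min(X.n_cells, X.n_genes):
        raise ValueError(
            f"m={m} exceeds min(n_cells, n_genes)={min(X.n_cells, X.n_genes)}"
        )
    if np.allclose(X.values, X.values[0], atol=0.0):
        raise ValueError("zero-variance matrix: all cells identical")
    pca = PCA(n_components=m, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(X.values)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(m):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    return Embedding(coords, pca.explained_variance_, list(X.cell_ids))
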