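"""Reading and writing unfiltered cell-by-gene count matrices.

Supported on-disk formats:

* MatrixMarket coordinate (``.mtx``) with ``barcodes.tsv`` / ``features.tsv``
  (or ``genes.tsv``) sidecar files, in either CellRanger orientation
  (genes as rows, the default) or cells as rows;
* delimited text (CSV/TSV) with a header row of gene symbols and one row per
  barcode (or the transpose, via the orientation flag);
* AnnData HDF5 containers (``.h5ad``), reading the raw count layer when one
  is stored.

All readers return a :class:`CountMatrix` in cells x genes orientation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "MatrixFormatError",
    "MatrixStructureError",
    "read_count_matrix",
    "write_mtx",
    "write_h5ad",
]


class MatrixFormatError(ValueError):
    """The file could not be parsed in the requested format."""


class MatrixStructureError(ValueError):
    """Matrix dimensions disagree with sidecar/metadata dimensions."""


def _deduplicate(symbols: list[str]) -> list[str]:
    """Suffix-deduplicate gene symbols (``ACTB``, ``ACTB.1``, ...).

    Category tagging and marker lookup need unique handles; suffixing keeps
    the prefix intact so mito/ribo tagging still works.
    """
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
            n_dup += 1
        else:
            seen[s] = 0
            out.append(s)
    if n_dup:
        logger.warning("deduplicated %d duplicate gene symbols", n_dup)
    return out


@dataclass
class CountMatrix:
    """Sparse cells x genes integer count matrix with cell and gene names."""

    counts: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = [str(b) for b in self.barcodes]
        self.genes = _deduplicate([str(g) for g in self.genes])
        if self.counts.shape[0] != len(self.barcodes):
            raise MatrixStructureError(
                f"{len(self.barcodes)} barcodes but matrix has "
                f"{self.counts.shape[0]} rows"
            )
        if self.counts.shape[1] != len(self.genes):
            raise MatrixStructureError(
                f"{len(self.genes)} gene symbols but matrix has "
                f"{self.counts.shape[1]} columns"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise MatrixStructureError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise MatrixStructureError("negative entries in count matrix")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        """Return a new matrix restricted to masked cells/genes."""
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask, bool)
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask, bool)
        return CountMatrix(
            self.counts[cm][:, gm],
            [b for b, k in zip(self.barcodes, cm) if k],
            [g for g, k in zip(self.genes, gm) if k],
        )

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.astype(np.int32),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )


def _find_sidecar(mtx_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for ext in (".tsv", ".tsv.gz", ".txt", ".csv"):
            p = mtx_path.parent / f"{stem}{ext}"
            if p.exists():
                return p
    raise MatrixFormatError(
        f"no sidecar file {stems} next to {mtx_path}"
    )


def _read_mtx(path: Path, orientation: str) -> CountMatrix:
    try:
        mat = scipy.io.mmread(os.fspath(path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise MatrixFormatError(f"could not parse MatrixMarket file {path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    barcodes = pd.read_csv(_find_sidecar(path, ("barcodes",)), sep="\t", header=None)
    feat = pd.read_csv(_find_sidecar(path, ("features", "genes")), sep="\t", header=None)
    # CellRanger features.tsv carries (id, symbol, type); use the symbol column
    genes = feat.iloc[:, 1] if feat.shape[1] >= 2 else feat.iloc[:, 0]
    if orientation == "genes_as_rows":
        mat = sp.csr_matrix(mat.T)
    if mat.shape[0] != len(barcodes) or mat.shape[1] != len(genes):
        raise MatrixStructureError(
            f"matrix is {mat.shape[0]} cells x {mat.shape[1]} genes after "
            f"orientation, but sidecars declare {len(barcodes)} barcodes and "
            f"{len(genes)} features"
        )
    return CountMatrix(mat, barcodes.iloc[:, 0].tolist(), genes.tolist())


def _read_delimited(path: Path, orientation: str, sep: str) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise MatrixFormatError(f"could not parse delimited file {path}: {exc}") from exc
    if orientation == "genes_as_rows":
        df = df.T
    mat = sp.csr_matrix(df.to_numpy())
    return CountMatrix(mat, df.index.tolist(), df.columns.tolist())


def _read_h5ad(path: Path) -> CountMatrix:
    import anndata as ad

    try:
        adata = ad.read_h5ad(os.fspath(path))
    except Exception as exc:
        raise MatrixFormatError(f"could not read AnnData container {path}: {exc}") from exc
    if adata.raw is not None:
        X, genes = adata.raw.X, adata.raw.var_names.tolist()
    elif "counts" in adata.layers:
        X, genes = adata.layers["counts"], adata.var_names.tolist()
    else:
        X, genes = adata.X, adata.var_names.tolist()
    return CountMatrix(sp.csr_matrix(X), adata.obs_names.tolist(), genes)


def read_count_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    orientation: str = "genes_as_rows",
) -> CountMatrix:
    """Load an unfiltered count matrix in mtx, csv, tsv or h5ad format.

    Parameters
    ----------
    path
        Matrix file. For MTX, ``barcodes.tsv`` and ``features.tsv`` (or
        ``genes.tsv``) must sit in the same directory.
    format
        One of ``mtx``, ``csv``, ``tsv``, ``h5ad``; inferred from the file
        suffix when omitted.
    orientation
        On-disk orientation: ``genes_as_rows`` (CellRanger convention,
        default) or ``cells_as_rows``. Ignored for h5ad, which is always
        cells x genes.
    """
    path = Path(path)
    if not path.exists():
        raise MatrixFormatError(f"input file does not exist: {path}")
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".h5ad": "h5ad"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise MatrixFormatError(f"cannot infer format from suffix of {path}")
    if orientation not in ("genes_as_rows", "cells_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if format == "mtx":
        return _read_mtx(path, orientation)
    if format in ("csv", "tsv", "txt"):
        return _read_delimited(path, orientation, "," if format == "csv" else "\t")
    if format == "h5ad":
        return _read_h5ad(path)
    raise MatrixFormatError(f"unknown format {format!r}")


def write_mtx(matrix: CountMatrix, out_dir: str | os.PathLike) -> Path:
    """Write matrix.mtx + barcodes.tsv + features.tsv (genes as rows)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(os.fspath(out / "matrix.mtx"), sp.coo_matrix(matrix.counts.T))
    pd.Series(matrix.barcodes).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame({"id": matrix.genes, "symbol": matrix.genes}).to_csv(
        out / "features.tsv", sep="\t", index=False, header=False
    )
    return out / "matrix.mtx"


def write_h5ad(matrix: CountMatrix, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_anndata().write_h5ad(os.fspath(path))
    return path
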