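"""Reading, writing and preprocessing of multi-batch expression datasets.

The on-disk dialects are the field's usual ones: a CellRanger-style
MatrixMarket directory, a dense CSV (header row = gene ids, first column =
cell ids), and an AnnData ``.h5ad`` container.  Counts are raw UMIs and are
preserved bit-exactly through every round trip; the models consume raw
counts of the selected highly-variable genes, since the ZINB likelihood is
defined on integers.  Depth normalisation and log transform are applied
only transiently for dispersion-based gene ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as an
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: reserved marker for a cell whose type annotation is missing
UNLABELED = "unlabeled"

FORMATS = ("mtx_dir", "csv", "h5container")


class DataError(ValueError):
    """Structural problem in an input dataset (dimensions, dtypes, labels)."""


@dataclass
class ExpressionDataset:
    """Raw UMI counts with per-cell batch and optional cell-type labels.

    counts : (cells, genes) ndarray of non-negative integers
    batch : per-cell categorical label (no missing entries)
    cell_type : per-cell label, ``UNLABELED`` marking missing annotations,
        or None when the dataset carries no annotations at all
    """

    counts: np.ndarray
    batch: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type: np.ndarray | None = None

    def __post_init__(self):
        c = self.counts
        if sp.issparse(c):
            c = np.asarray(c.todense())
        c = np.asarray(c)
        if np.any(c < 0):
            raise DataError("counts contain negative entries")
        if not np.issubdtype(c.dtype, np.integer):
            if np.any(c != np.round(c)):
                raise DataError("counts contain non-integer entries")
            c = c.astype(np.int64)
        self.counts = c.astype(np.int64, copy=False)
        n, g = self.counts.shape
        self.batch = np.asarray(self.batch, dtype=object)
        if len(self.batch) != n:
            raise DataError(f"batch labels ({len(self.batch)}) do not match cell count ({n})")
        if any(b is None or (isinstance(b, float) and np.isnan(b)) for b in self.batch):
            raise DataError("batch labels contain missing entries")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if len(self.cell_type) != n:
                raise DataError(
                    f"cell_type labels ({len(self.cell_type)}) do not match cell count ({n})"
                )
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.cell_ids = [str(x) for x in self.cell_ids]
        if len(self.gene_ids) != g:
            raise DataError(f"gene_ids ({len(self.gene_ids)}) do not match gene count ({g})")
        if len(self.cell_ids) != n:
            raise DataError(f"cell_ids ({len(self.cell_ids)}) do not match cell count ({n})")
        if len(set(self.gene_ids)) != g:
            raise DataError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise DataError("cell_ids are not unique")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def batches(self) -> list:
        return sorted(set(self.batch))

    def labeled_mask(self) -> np.ndarray:
        """Boolean mask of cells with an observed (non-missing) type label."""
        if self.cell_type is None:
            return np.zeros(self.n_cells, dtype=bool)
        return np.asarray([c != UNLABELED for c in self.cell_type])

    def to_anndata(self) -> an.AnnData:
        adata = an.AnnData(
            X=sp.csr_matrix(self.counts),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.obs["batch"] = pd.Categorical([str(b) for b in self.batch])
        if self.cell_type is not None:
            adata.obs["cell_type"] = pd.Categorical([str(c) for c in self.cell_type])
        return adata


@dataclass
class HVGSelection:
    """Outcome of highly-variable-gene ranking.

    ``selected_gene_indices`` index the raw (input) count matrix;
    ``dispersion_stats`` holds per-eligible-gene mean and normalised
    dispersion used for the ranking.
    """

    selected_gene_indices: np.ndarray
    dispersion_stats: pd.DataFrame = field(repr=False)


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def _read_mtx_dir(path: Path, transpose: bool) -> ExpressionDataset:
    mtx = path / "matrix.mtx"
    mat = scipy.io.mmread(str(mtx))
    mat = np.asarray(sp.coo_matrix(mat).todense())
    if transpose:
        mat = mat.T
    barcodes = [ln.split("\t")[0] for ln in (path / "barcodes.tsv").read_text().splitlines() if ln]
    genes = [ln.split("\t")[0] for ln in (path / "genes.tsv").read_text().splitlines() if ln]
    if mat.shape[0] != len(barcodes):
        raise DataError(
            f"{path / 'barcodes.tsv'}: {len(barcodes)} barcodes but matrix has {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(genes):
        raise DataError(
            f"{path / 'genes.tsv'}: {len(genes)} genes but matrix has {mat.shape[1]} columns"
        )
    labels = pd.read_csv(path / "labels.tsv", sep="\t", dtype=str)
    if len(labels) != len(barcodes):
        raise DataError(
            f"{path / 'labels.tsv'}: {len(labels)} rows but {len(barcodes)} barcodes"
        )
    if "batch" not in labels.columns:
        raise DataError(f"{path / 'labels.tsv'}: missing required 'batch' column")
    cell_type = labels["cell_type"].to_numpy() if "cell_type" in labels.columns else None
    return ExpressionDataset(mat, labels["batch"].to_numpy(), genes, barcodes, cell_type)


def _write_mtx_dir(ds: ExpressionDataset, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(ds.counts), field="integer")
    (path / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
    (path / "genes.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    lab = pd.DataFrame({"batch": ds.batch})
    if ds.cell_type is not None:
        lab["cell_type"] = ds.cell_type
    lab.to_csv(path / "labels.tsv", sep="\t", index=False)


def _read_csv(path: Path) -> ExpressionDataset:
    df = pd.read_csv(path, index_col=0)
    labels = pd.read_csv(path.with_suffix(".labels.csv"), index_col=0, dtype=str)
    if len(labels) != len(df):
        raise DataError(
            f"{path.with_suffix('.labels.csv')}: {len(labels)} label rows but matrix has {len(df)} cells"
        )
    if "batch" not in labels.columns:
        raise DataError(f"{path.with_suffix('.labels.csv')}: missing required 'batch' column")
    cell_type = labels["cell_type"].to_numpy() if "cell_type" in labels.columns else None
    return ExpressionDataset(
        df.to_numpy(), labels["batch"].to_numpy(), list(df.columns), list(df.index.astype(str)), cell_type
    )


def _write_csv(ds: ExpressionDataset, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ds.counts, index=ds.cell_ids, columns=ds.gene_ids).to_csv(path)
    lab = pd.DataFrame({"batch": ds.batch}, index=ds.cell_ids)
    if ds.cell_type is not None:
        lab["cell_type"] = ds.cell_type
    lab.to_csv(path.with_suffix(".labels.csv"))


def _read_h5(path: Path, batch_key: str, cell_type_key: str) -> ExpressionDataset:
    adata = an.read_h5ad(str(path))
    X = adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    if batch_key not in adata.obs:
        raise DataError(f"{path}: obs column '{batch_key}' not found")
    cell_type = (
        adata.obs[cell_type_key].astype(str).to_numpy() if cell_type_key in adata.obs else None
    )
    return ExpressionDataset(
        X,
        adata.obs[batch_key].astype(str).to_numpy(),
        list(adata.var_names),
        list(adata.obs_names),
        cell_type,
    )


def read_dataset(
    path,
    format: str = "h5container",
    *,
    transpose: bool = False,
    batch_key: str = "batch",
    cell_type_key: str = "cell_type",
) -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from one of the supported formats."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input path does not exist: {path}")
    if format == "mtx_dir":
        return _read_mtx_dir(path, transpose)
    if format == "csv":
        return _read_csv(path)
    if format == "h5container":
        return _read_h5(path, batch_key, cell_type_key)
    raise DataError(f"unknown format '{format}'; expected one of {FORMATS}")


def write_dataset(ds: ExpressionDataset, path, format: str = "h5container") -> None:
    """Write ``ds`` so that :func:`read_dataset` round-trips it exactly."""
    path = Path(path)
    if format == "mtx_dir":
        _write_mtx_dir(ds, path)
    elif format == "csv":
        _write_csv(ds, path)
    elif format == "h5container":
        path.parent.mkdir(parents=True, exist_ok=True)
        ds.to_anndata().write_h5ad(str(path))
    else:
        raise DataError(f"unknown format '{format}'; expected one of {FORMATS}")


def write_embedding(path, cell_ids, Z: np.ndarray) -> None:
    """Write a per-cell embedding as TSV (cell_id + one column per dim)."""
    df = pd.DataFrame(Z, index=pd.Index(cell_ids, name="cell_id"),
                      columns=[f"z{i}" for i in range(Z.shape[1])])
    df.to_csv(path, sep="\t")


def attach_embedding(h5ad_path, cell_ids, Z: np.ndarray, key: str = "X_integrated") -> None:
    """Store an embedding in an existing ``.h5ad`` container's obsm slot."""
    adata = an.read_h5ad(str(h5ad_path))
    if list(adata.obs_names) != [str(c) for c in cell_ids]:
        raise DataError(f"{h5ad_path}: cell ids do not match the embedding rows")
    adata.obsm[key] = np.asarray(Z, dtype=np.float64)
    adata.write_h5ad(str(h5ad_path))


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def genes_in_all_batches(ds: ExpressionDataset) -> np.ndarray:
    """Boolean mask of genes with nonzero total count in every batch."""
    mask = np.ones(ds.n_genes, dtype=bool)
    for b in ds.batches:
        mask &= ds.counts[ds.batch == b].sum(axis=0) > 0
    return mask


def select_hvg(ds: ExpressionDataset, n_top: int = 2000) -> HVGSelection:
    """Rank genes by normalised dispersion and keep the top ``n_top``.

    Only genes expressed in every batch are eligible.  Counts are depth
    normalised to the median per-cell total and log1p transformed solely
    for the dispersion computation (seurat-flavour ranking: genes binned by
    mean expression, dispersion z-scored within bin); the returned indices
    point into the raw count matrix.  Deterministic: ties in normalised
    dispersion are broken by gene id.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    eligible = np.flatnonzero(genes_in_all_batches(ds))
    if eligible.size == 0:
        raise DataError("no gene is expressed in every batch")
    adata = an.AnnData(X=sp.csr_matrix(ds.counts[:, eligible].astype(np.float64)))
    adata.var_names = [ds.gene_ids[i] for i in eligible]
    sc.pp.normalize_total(adata)  # scales to the median per-cell total
    sc.pp.log1p(adata)
    n_eligible = eligible.size
    if n_eligible < n_top:
        logger.warning("only %d eligible genes (< n_top=%d); returning all", n_eligible, n_top)
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=min(n_top, n_eligible))
    stats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "raw_index": eligible,
            "mean": adata.var["means"].to_numpy(),
            "dispersion_norm": np.nan_to_num(adata.var["dispersions_norm"].to_numpy(), nan=0.0),
        }
    )
    order = stats.sort_values(["dispersion_norm", "gene_id"], ascending=[False, True], kind="mergesort")
    chosen = np.sort(order["raw_index"].to_numpy()[: min(n_top, n_eligible)])
    return HVGSelection(selected_gene_indices=chosen, dispersion_stats=stats)


def subset_and_split(ds: ExpressionDataset, hvg: HVGSelection) -> ExpressionDataset:
    """Restrict the dataset to the selected genes (raw counts unchanged)."""
    idx = np.asarray(hvg.selected_gene_indices)
    if idx.size and (idx.min() < 0 or idx.max() >= ds.n_genes):
        raise DataError("gene index out of range")
    return ExpressionDataset(
        ds.counts[:, idx],
        ds.batch.copy(),
        [ds.gene_ids[i] for i in idx],
        list(ds.cell_ids),
        None if ds.cell_type is None else ds.cell_type.copy(),
    )


def preprocess(ds: ExpressionDataset, n_top: int = 2000, max_mito_fraction: float | None = None) -> ExpressionDataset:
    """Shared-gene filtering + HVG selection, returning raw counts of HVGs.

    ``max_mito_fraction``, when set, drops cells whose fraction of counts on
    MT-prefixed genes exceeds the threshold (off by default).
    """
    if max_mito_fraction is not None:
        mito = np.asarray([g.upper().startswith("MT-") for g in ds.gene_ids])
        if mito.any():
            frac = ds.counts[:, mito].sum(axis=1) / np.maximum(ds.counts.sum(axis=1), 1)
            keep = frac <= max_mito_fraction
            ds = ExpressionDataset(
                ds.counts[keep],
                ds.batch[keep],
                ds.gene_ids,
                [c for c, k in zip(ds.cell_ids, keep) if k],
                None if ds.cell_type is None else ds.cell_type[keep],
            )
    return subset_and_split(ds, select_hvg(ds, n_top=n_top))
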