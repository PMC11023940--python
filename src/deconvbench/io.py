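"""File readers/writers, QC filtering and gene-space harmonization.

Supported on-disk formats are plain text only: delimited matrices (first
column gene id, header row of cell/sample ids, tab or comma separated,
auto-detected) and MatrixMarket coordinate files with one-id-per-line
companion files for genes and barcodes. Annotation tables are delimited
with mandatory columns ``cell_id``, ``sample_id``, ``cell_type``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datasets import BulkMatrix, ProportionMatrix, SingleCellDataset, StructuralError

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the offending file/line."""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_delimited_matrix(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no data columns found (separator {sep!r})")
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        raise ParseError(
            f"{path}: non-numeric values in columns {list(non_numeric)[:3]}"
        )
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def _companion_files(path: Path) -> tuple[Path, Path]:
    """Locate gene/barcode index files next to a MatrixMarket file."""
    stem = path.with_suffix("")
    candidates = [
        (Path(f"{stem}.genes.txt"), Path(f"{stem}.barcodes.txt")),
        (path.parent / "genes.tsv", path.parent / "barcodes.tsv"),
        (path.parent / "genes.txt", path.parent / "barcodes.txt"),
    ]
    for genes, barcodes in candidates:
        if genes.exists() and barcodes.exists():
            return genes, barcodes
    raise FileNotFoundError(
        f"no companion gene/barcode index files found for {path} "
        f"(looked for {stem}.genes.txt/.barcodes.txt and genes.tsv/barcodes.tsv)"
    )


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        # first whitespace-delimited token per line is the id
        ids = [line.split()[0].strip() for line in fh if line.strip()]
    return ids


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        n_before = len(df)
        df = df.groupby(level=0, sort=False).sum()
        logger.info("collapsed %d duplicate gene rows by summation",
                    n_before - len(df))
    return df


def read_matrix(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read an expression matrix (genes x columns) as a DataFrame.

    ``fmt`` is ``"tsv"`` (any delimited text) or ``"mtx"``; inferred from
    the file suffix when omitted. Duplicate gene ids are collapsed by
    summation. For MatrixMarket input the orientation is asserted from the
    companion index-file lengths, never guessed from shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = _read_delimited_matrix(path)
    elif fmt == "mtx":
        genes_path, barcodes_path = _companion_files(path)
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_id_file(genes_path)
        barcodes = _read_id_file(barcodes_path)
        if mat.shape == (len(genes), len(barcodes)):
            pass
        elif mat.shape == (len(barcodes), len(genes)):
            logger.info("transposing %s to genes-in-rows per index files", path)
            mat = mat.T
        else:
            raise StructuralError(
                f"{path}: matrix shape {mat.shape} matches neither "
                f"{len(genes)} genes x {len(barcodes)} barcodes nor its transpose"
            )
        df = pd.DataFrame(mat, index=genes, columns=barcodes)
        df.index = df.index.astype(str).str.strip()
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")
    return _collapse_duplicate_genes(df)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a cell annotation table (cell_id, sample_id, cell_type)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    ann = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in ("cell_id", "sample_id", "cell_type")
               if c not in ann.columns]
    if missing:
        raise ParseError(f"{path}: annotation missing columns {missing}")
    return ann


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    annotation: str | Path | pd.DataFrame | None = None,
) -> SingleCellDataset | BulkMatrix:
    """Read an expression matrix, returning a single-cell dataset when a
    cell annotation is supplied and a bulk matrix otherwise."""
    df = read_matrix(path, fmt=fmt)
    if annotation is None:
        return BulkMatrix.from_frame(df)
    if not isinstance(annotation, pd.DataFrame):
        annotation = read_annotation(annotation)
    return SingleCellDataset(
        counts=df.to_numpy(),
        gene_ids=list(df.index),
        cell_ids=list(df.columns),
        annotation=annotation,
    )


def read_proportions(path: str | Path) -> ProportionMatrix:
    """Read a samples x cell-types proportion table."""
    df = _read_delimited_matrix(Path(path))
    return ProportionMatrix.from_frame(df)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: str | Path, fmt: str = "tsv",
                 index_label: str = "gene") -> None:
    """Write a matrix as TSV (default) or MatrixMarket + companions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
    elif fmt == "mtx":
        sparse = scipy.sparse.coo_matrix(df.to_numpy())
        scipy.io.mmwrite(str(path), sparse)
        stem = path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(map(str, df.index)) + "\n")
        Path(f"{stem}.barcodes.txt").write_text("\n".join(map(str, df.columns)) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_proportions(props: ProportionMatrix, path: str | Path) -> None:
    props.to_frame().to_csv(Path(path), sep="\t", index_label="sample",
                            float_format="%.10g")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def qc_filter_cells(
    ds: SingleCellDataset,
    min_genes: int = 200,
    max_mito_frac: float = 0.05,
    mito_prefix: str = "MT-",
) -> SingleCellDataset:
    """Remove low-quality cells.

    A cell is dropped when it has fewer than ``min_genes`` detected genes
    (nonzero counts) or when the fraction of its counts coming from
    mitochondrial genes (gene id starting with ``mito_prefix``,
    case-insensitive) exceeds ``max_mito_frac``. Fractions are computed on
    raw counts.
    """
    detected = (ds.counts > 0).sum(axis=0)
    mito_mask = np.array(
        [g.upper().startswith(mito_prefix.upper()) for g in ds.gene_ids]
    )
    totals = ds.counts.sum(axis=0)
    mito = ds.counts[mito_mask].sum(axis=0) if mito_mask.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    keep = (detected >= min_genes) & (frac <= max_mito_frac)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"QC removed all {ds.n_cells} cells; review min_genes={min_genes} "
            f"and max_mito_frac={max_mito_frac}"
        )
    if n_removed:
        logger.info("qc_filter_cells removed %d/%d cells", n_removed, ds.n_cells)
    return ds.subset_cells(np.flatnonzero(keep))


def qc_filter_genes(ds: SingleCellDataset, min_cells: int = 3) -> SingleCellDataset:
    """Remove genes with nonzero counts in fewer than ``min_cells`` cells."""
    n_expressing = (ds.counts > 0).sum(axis=1)
    keep = n_expressing >= min_cells
    if keep.sum() == 0:
        raise ValueError("QC removed all genes; review min_cells")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("qc_filter_genes removed %d/%d genes", n_removed, ds.n_genes)
    return ds.subset_genes(np.flatnonzero(keep))


def qc_filter(ds: SingleCellDataset, min_genes: int = 200, min_cells: int = 3,
              max_mito_frac: float = 0.05, mito_prefix: str = "MT-") -> SingleCellDataset:
    """Standard QC: filter cells, then genes."""
    ds = qc_filter_cells(ds, min_genes=min_genes, max_mito_frac=max_mito_frac,
                         mito_prefix=mito_prefix)
    return qc_filter_genes(ds, min_cells=min_cells)


# ---------------------------------------------------------------------------
# gene-space harmonization
# ---------------------------------------------------------------------------

def harmonize_genes(
    bulk: BulkMatrix, ref_genes: list[str]
) -> tuple[BulkMatrix, np.ndarray]:
    """Restrict a bulk matrix to the genes shared with a reference.

    Gene ids match by exact string equality after whitespace strip. Returns
    the restricted bulk (rows in reference gene order) and the index map:
    for each kept gene, its row position in the original bulk.
    """
    bulk_ids = [g.strip() for g in bulk.gene_ids]
    ref_ids = [str(g).strip() for g in ref_genes]
    pos = {g: i for i, g in enumerate(bulk_ids)}
    kept_ref = [g for g in ref_ids if g in pos]
    if not kept_ref:
        raise ValueError(
            "no genes shared between bulk and reference "
            f"(bulk ids look like {bulk_ids[:3]}, reference ids like {ref_ids[:3]})"
        )
    idx = np.array([pos[g] for g in kept_ref])
    dropped = bulk.n_genes - len(kept_ref)
    if dropped:
        logger.info("harmonize_genes dropped %d/%d bulk genes", dropped, bulk.n_genes)
    out = BulkMatrix(values=bulk.values[idx, :], gene_ids=kept_ref,
                     sample_ids=list(bulk.sample_ids))
    return out, idx
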