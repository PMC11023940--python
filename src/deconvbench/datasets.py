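"""Core in-memory containers for deconvolution benchmarking.

All expression matrices are oriented genes-in-rows. Three containers cover
the data that flows through the toolkit:

* :class:`SingleCellDataset` — raw counts plus per-cell annotation
  (cell id, donor/sample id, cell-type label); the source for references
  and pseudo-bulk pools.
* :class:`BulkMatrix` — a genes x samples expression matrix to deconvolve
  (real bulk or simulated pseudo-bulk).
* :class:`ProportionMatrix` — samples x cell-types fractional composition;
  every solver and the consensus return one, rows on the unit simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("cell_id", "sample_id", "cell_type")

#: tolerance on proportion row sums
ROW_SUM_TOL = 1e-8


class StructuralError(ValueError):
    """Inconsistent dimensions / labels between matrix and companion data."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise StructuralError(f"duplicate {what}: {dupes}")
    return ids


@dataclass
class SingleCellDataset:
    """Raw gene x cell count matrix with cell-level annotation.

    Parameters
    ----------
    counts
        Non-negative raw counts, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Ordered unique identifiers matching the matrix axes.
    annotation
        DataFrame with columns ``cell_id``, ``sample_id``, ``cell_type``;
        exactly one row per cell, in any order.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise StructuralError("counts must be 2-D (genes x cells)")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise StructuralError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.isfinite(self.counts).all():
            raise ValueError("counts contain non-finite values")
        if (self.counts < 0).any():
            raise ValueError("counts contain negative values")
        ann = self.annotation
        missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
        if missing:
            raise StructuralError(f"annotation missing columns {missing}")
        ann = ann.copy()
        for c in ANNOTATION_COLUMNS:
            ann[c] = ann[c].astype(str)
        if (ann["cell_type"].str.len() == 0).any():
            raise ValueError("empty cell_type labels in annotation")
        ann_ids = _check_unique(ann["cell_id"].tolist(), "annotation cell ids")
        if set(ann_ids) != set(self.cell_ids):
            raise StructuralError(
                "annotation cell ids do not match matrix cell ids"
            )
        # align annotation rows to matrix column order
        ann = ann.set_index("cell_id").loc[self.cell_ids].reset_index()
        self.annotation = ann

    # -- convenience accessors ------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> np.ndarray:
        """Cell-type label per matrix column."""
        return self.annotation["cell_type"].to_numpy()

    @property
    def cell_type_labels(self) -> list[str]:
        """Sorted unique cell-type labels."""
        return sorted(set(self.annotation["cell_type"]))

    def subset_cells(self, idx: np.ndarray) -> "SingleCellDataset":
        """New dataset restricted to the cells at column positions ``idx``."""
        idx = np.asarray(idx)
        return SingleCellDataset(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            annotation=self.annotation.iloc[idx].reset_index(drop=True),
        )

    def subset_genes(self, idx: np.ndarray) -> "SingleCellDataset":
        idx = np.asarray(idx)
        return SingleCellDataset(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            annotation=self.annotation.copy(),
        )

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        """Column positions of the cells annotated with ``cell_type``."""
        return np.flatnonzero(self.cell_types == cell_type)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class BulkMatrix:
    """Genes x samples expression matrix."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StructuralError("values must be 2-D (genes x samples)")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise StructuralError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("bulk values contain non-finite entries")
        if (self.values < 0).any():
            raise ValueError("bulk values contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BulkMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
        )

    def with_values(self, values: np.ndarray) -> "BulkMatrix":
        """Same labels, new matrix (e.g. after normalization)."""
        return BulkMatrix(values=values, gene_ids=list(self.gene_ids),
                          sample_ids=list(self.sample_ids))


@dataclass
class ProportionMatrix:
    """Samples x cell-types composition; non-negative rows summing to one."""

    values: np.ndarray
    sample_ids: list[str]
    cell_type_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StructuralError("values must be 2-D (samples x cell types)")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.cell_type_labels = _check_unique(self.cell_type_labels, "cell-type labels")
        if self.values.shape != (len(self.sample_ids), len(self.cell_type_labels)):
            raise StructuralError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x "
                f"{len(self.cell_type_labels)} cell types"
            )
        if (self.values < -0.0).any() and (self.values < 0).any():
            raise ValueError("proportions contain negative entries")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=ROW_SUM_TOL, rtol=0):
            bad = np.argmax(np.abs(sums - 1.0))
            raise ValueError(
                f"proportion rows must sum to 1 (sample {self.sample_ids[bad]} "
                f"sums to {sums[bad]:.6g})"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.cell_type_labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProportionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(s) for s in df.index],
            cell_type_labels=[str(c) for c in df.columns],
        )
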