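"""Reference construction for deconvolution.

From a single-cell dataset the builder derives the four artifacts every
reference-consuming solver family needs:

* ``C0`` — the raw training-half single-cell matrix with its metadata
  (consumed by single-cell-input methods);
* ``C1`` — genes x cell-types matrix of per-type arithmetic mean
  expression, the signature matrix of regression-based solvers;
* ``C2`` — per-cell-type ranked marker-gene lists from one-vs-rest
  differential expression (Wilcoxon rank-sum by default, Welch's t as the
  alternative);
* ``refVar`` — genes x cell-types matrix of per-type sample standard
  deviations, structurally parallel to ``C1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import SingleCellDataset

logger = logging.getLogger(__name__)


@dataclass
class ReferenceBundle:
    """The four reference artifacts built from a training split."""

    C0: SingleCellDataset
    C1: pd.DataFrame            # genes x cell types, per-type means
    C2: dict[str, list[str]]    # cell type -> ranked marker genes
    ref_var: pd.DataFrame       # genes x cell types, per-type SDs
    marker_table: pd.DataFrame | None = None

    @property
    def cell_type_labels(self) -> list[str]:
        return list(self.C1.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.C1.index)


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def split_train_test(
    ds: SingleCellDataset, fraction: float = 0.5, seed: int = 0
) -> tuple[SingleCellDataset, SingleCellDataset]:
    """Stratified split of cells into training and testing halves.

    Each cell type's cells are shuffled and divided with
    ``floor(n_type * fraction)`` going to the training half and the
    remainder to the testing half, so every type is represented on both
    sides. Disjoint and exhaustive by construction.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    types = ds.cell_types
    train_idx: list[int] = []
    test_idx: list[int] = []
    for ct in sorted(set(types)):
        idx = np.flatnonzero(types == ct)
        if len(idx) < 2:
            raise ValueError(
                f"cell type {ct!r} has {len(idx)} cell(s); need >= 2 to "
                "appear in both halves"
            )
        idx = rng.permutation(idx)
        n_train = int(np.floor(len(idx) * fraction))
        n_train = max(1, min(n_train, len(idx) - 1))  # both halves non-empty
        train_idx += list(idx[:n_train])
        test_idx += list(idx[n_train:])
    return ds.subset_cells(np.sort(train_idx)), ds.subset_cells(np.sort(test_idx))


# ---------------------------------------------------------------------------
# C1 / refVar
# ---------------------------------------------------------------------------

def build_c1(train: SingleCellDataset) -> pd.DataFrame:
    """Per-cell-type arithmetic mean expression (genes x cell types)."""
    cols = {}
    for ct in train.cell_type_labels:
        idx = train.cells_of_type(ct)
        cols[ct] = train.counts[:, idx].mean(axis=1)
    return pd.DataFrame(cols, index=train.gene_ids)


def build_ref_var(train: SingleCellDataset) -> pd.DataFrame:
    """Per-cell-type gene-wise sample SD (ddof=1); single-cell types get 0."""
    cols = {}
    for ct in train.cell_type_labels:
        idx = train.cells_of_type(ct)
        if len(idx) < 2:
            warnings.warn(
                f"cell type {ct!r} has a single cell; refVar column set to 0"
            )
            cols[ct] = np.zeros(train.n_genes)
        else:
            cols[ct] = train.counts[:, idx].std(axis=1, ddof=1)
    return pd.DataFrame(cols, index=train.gene_ids)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midrank ties; p-values come from the exact null distribution of U
    for small tie-free samples (combined n <= 30, the convention of the
    standard implementations) and otherwise from the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction. Returns ``(U, p)`` where ``U`` is the Mann-Whitney
    statistic of the first sample. Degenerate input (all values
    identical across both groups) yields ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    if tie_term == 0 and n <= 30:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact")
        return float(u), float(res.pvalue)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u), float(min(p, 1.0))


def _wilcoxon_vectorized(in_mat: np.ndarray, out_mat: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rank-sum test: each row is one gene, columns are cells."""
    n1, n2 = in_mat.shape[1], out_mat.shape[1]
    n = n1 + n2
    combined = np.concatenate([in_mat, out_mat], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    srt = np.sort(combined, axis=1)
    new_val = np.ones_like(srt, dtype=bool)
    new_val[:, 1:] = srt[:, 1:] != srt[:, :-1]
    tie_term = np.empty(combined.shape[0])
    for g in range(combined.shape[0]):
        counts = np.diff(np.append(np.flatnonzero(new_val[g]), n))
        tie_term[g] = (counts.astype(float) ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = np.zeros_like(u)
    ok = var > 0
    z[ok] = (u[ok] - mu - 0.5 * np.sign(u[ok] - mu)) / np.sqrt(var[ok])
    p = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return u, np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# marker discovery
# ---------------------------------------------------------------------------

def _normalize_log(counts: np.ndarray, target: float = 1e4) -> np.ndarray:
    """Library-size normalize each cell to ``target`` counts, then log1p."""
    totals = counts.sum(axis=0)
    scaled = counts / np.maximum(totals, 1) * target
    return np.log1p(scaled)


def find_markers(
    train: SingleCellDataset,
    test_name: str = "wilcox",
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    alpha: float = 0.05,
    top_n: int | None = None,
    correction: str = "fdr_bh",
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """One-vs-rest differential expression per cell type.

    Expression is library-size normalized (1e4 per cell) and
    log-transformed before testing. Genes must be expressed in at least
    ``min_pct`` of in-group cells and show a natural-log fold change of
    de-logged means of at least ``logfc_min``; surviving genes with
    adjusted p below ``alpha`` are ranked by adjusted p, then |logFC|,
    and the top ``top_n`` retained per type.

    Returns the C2 mapping (cell type -> ranked marker list) and the full
    per-gene test table.
    """
    labels = train.cell_type_labels
    if len(labels) < 2:
        raise ValueError("marker finding needs >= 2 cell types")
    if test_name not in ("wilcox", "t"):
        raise ValueError(f"unknown test {test_name!r}; use 'wilcox' or 't'")
    logx = _normalize_log(train.counts.astype(float))
    types = train.cell_types

    rows = []
    c2: dict[str, list[str]] = {}
    gene_ids = np.array(train.gene_ids)
    for ct in labels:
        in_mask = types == ct
        in_mat = logx[:, in_mask]
        out_mat = logx[:, ~in_mask]
        pct_in = (in_mat > 0).mean(axis=1)
        pct_out = (out_mat > 0).mean(axis=1)
        # Seurat-style logFC: ln of de-logged means with pseudocount 1
        lfc = (np.log(np.expm1(in_mat).mean(axis=1) + 1)
               - np.log(np.expm1(out_mat).mean(axis=1) + 1))
        candidate = (pct_in >= min_pct) & (lfc >= logfc_min)
        stat = np.full(train.n_genes, np.nan)
        pval = np.ones(train.n_genes)
        if candidate.any():
            if test_name == "wilcox":
                s, p = _wilcoxon_vectorized(in_mat[candidate], out_mat[candidate])
            else:
                s, p = stats.ttest_ind(in_mat[candidate], out_mat[candidate],
                                       axis=1, equal_var=False)
                p = np.where(np.isnan(p), 1.0, p)
            stat[candidate] = s
            pval[candidate] = p
        # correct over the full gene family (non-candidates enter at p=1)
        padj = multipletests(pval, method=correction)[1] if len(pval) else pval
        sig = candidate & (padj < alpha)
        order = np.lexsort((-np.abs(lfc), padj))
        ranked = [i for i in order if sig[i]]
        if top_n is not None:
            ranked = ranked[:top_n]
        if not ranked:
            warnings.warn(f"no markers found for cell type {ct!r}")
        c2[ct] = [gene_ids[i] for i in ranked]
        tested = np.flatnonzero(candidate)
        rows.append(pd.DataFrame({
            "gene": gene_ids[tested],
            "cell_type": ct,
            "statistic": stat[tested],
            "p_value": pval[tested],
            "adjusted_p": padj[tested],
            "log_fold_change": lfc[tested],
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
        }))
    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["gene", "cell_type", "statistic",
                                        "p_value", "adjusted_p",
                                        "log_fold_change", "pct_in", "pct_out"]))
    return c2, table


def marker_overlap(c2a: dict[str, list[str]],
                   c2b: dict[str, list[str]]) -> dict[str, list[str]]:
    """Per-type intersection of two marker mappings, keeping c2a's order.

    Empty intersections are allowed but flagged with a warning, since
    marker-consuming solvers degrade badly on near-empty lists.
    """
    if set(c2a) != set(c2b):
        raise ValueError(
            f"cell-type label sets differ: {sorted(set(c2a) ^ set(c2b))}"
        )
    out = {}
    for ct, genes in c2a.items():
        other = set(c2b[ct])
        overlap = [g for g in genes if g in other]
        if not overlap:
            warnings.warn(f"marker overlap for {ct!r} is empty")
        out[ct] = overlap
    return out


# ---------------------------------------------------------------------------
# bundle construction
# ---------------------------------------------------------------------------

def build_reference(
    train: SingleCellDataset,
    marker_test: str = "wilcox",
    find_markers_kwargs: dict | None = None,
    with_markers: bool = True,
) -> ReferenceBundle:
    """Assemble the full reference bundle from a training split."""
    c1 = build_c1(train)
    rv = build_ref_var(train)
    if with_markers:
        c2, table = find_markers(train, test_name=marker_test,
                                 **(find_markers_kwargs or {}))
    else:
        c2, table = {ct: [] for ct in train.cell_type_labels}, None
    return ReferenceBundle(C0=train, C1=c1, C2=c2, ref_var=rv,
                           marker_table=table)
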