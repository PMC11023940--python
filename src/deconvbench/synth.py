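"""Synthetic single-cell data with planted cell-type structure.

Counts are drawn from a negative binomial parameterized by (mean,
dispersion) with variance ``mean + dispersion * mean**2``, the standard
overdispersed model for UMI count data. Each cell type receives a set of
designated marker genes whose mean is multiplied by ``marker_fold``; with
``marker_fold = 1`` there is no cell-type signal at all, which gives a
clean null for marker-discovery false-positive checks.

Per-gene base means are drawn log-normal around ``base_mean`` so the
dataset shows the heavy-tailed mean distribution typical of expression
data. Cells are assigned round-robin to ``n_samples`` donors; donor-level
effects can be added separately with :func:`inject_batch_effect`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import BulkMatrix, SingleCellDataset


@dataclass
class SynthConfig:
    """Parameters of the synthetic single-cell generator.

    Defaults describe the desk-scale dataset used throughout the test
    bench: 2000 genes, four cell types of 300 cells each, 25 markers per
    type at four-fold elevation, three donors.
    """

    n_genes: int = 2000
    cell_types: tuple[str, ...] = ("typeA", "typeB", "typeC", "typeD")
    cells_per_type: int = 300
    n_markers_per_type: int = 25
    marker_fold: float = 4.0
    base_mean: float = 0.5
    mean_log_sd: float = 1.0
    dispersion: float = 0.5
    n_samples: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.cells_per_type < 1 or self.n_samples < 1:
            raise ValueError("counts must be >= 1")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError(
                f"{self.n_markers_per_type} markers x {len(self.cell_types)} "
                f"types exceed {self.n_genes} genes"
            )


def _gene_means(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    # log-normal around base_mean: median = base_mean
    return rng.lognormal(mean=np.log(cfg.base_mean), sigma=cfg.mean_log_sd,
                         size=cfg.n_genes)


def planted_markers(cfg: SynthConfig) -> dict[str, list[str]]:
    """Marker-gene assignment for a config; pure function of the config.

    The assignment is drawn from the same seeded stream the generator
    uses, so it reproduces exactly the markers planted by
    :func:`generate_sc` for the same config.
    """
    rng = np.random.default_rng(cfg.seed)
    _gene_means(cfg, rng)  # advance the stream identically to generate_sc
    k = len(cfg.cell_types)
    chosen = rng.choice(cfg.n_genes, size=cfg.n_markers_per_type * k,
                        replace=False)
    gene_ids = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    out: dict[str, list[str]] = {}
    for j, ct in enumerate(cfg.cell_types):
        idx = chosen[j * cfg.n_markers_per_type:(j + 1) * cfg.n_markers_per_type]
        out[ct] = [gene_ids[i] for i in sorted(idx)]
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float, size: tuple[int, ...]) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_sc(cfg: SynthConfig) -> SingleCellDataset:
    """Generate a synthetic single-cell count matrix.

    Fully reproducible from ``cfg.seed``. Marker genes of each type have
    their negative-binomial mean multiplied by ``cfg.marker_fold`` in the
    cells of that type only.
    """
    rng = np.random.default_rng(cfg.seed)
    means = _gene_means(cfg, rng)
    k = len(cfg.cell_types)
    chosen = rng.choice(cfg.n_genes, size=cfg.n_markers_per_type * k,
                        replace=False)
    gene_ids = [f"gene_{i:05d}" for i in range(cfg.n_genes)]

    blocks = []
    cell_ids: list[str] = []
    cell_types: list[str] = []
    for j, ct in enumerate(cfg.cell_types):
        type_means = means.copy()
        idx = chosen[j * cfg.n_markers_per_type:(j + 1) * cfg.n_markers_per_type]
        type_means[idx] *= cfg.marker_fold
        block = _nb_draw(rng, type_means[:, None], cfg.dispersion,
                         (cfg.n_genes, cfg.cells_per_type))
        blocks.append(block)
        cell_ids += [f"cell_{ct}_{i:04d}" for i in range(cfg.cells_per_type)]
        cell_types += [ct] * cfg.cells_per_type
    counts = np.concatenate(blocks, axis=1)

    n_cells = counts.shape[1]
    sample_ids = [f"donor_{i % cfg.n_samples + 1}" for i in range(n_cells)]
    annotation = pd.DataFrame(
        {"cell_id": cell_ids, "sample_id": sample_ids, "cell_type": cell_types}
    )
    return SingleCellDataset(counts=counts, gene_ids=gene_ids,
                             cell_ids=cell_ids, annotation=annotation)


def inject_batch_effect(ds: SingleCellDataset, log_sd: float,
                        seed: int) -> SingleCellDataset:
    """Multiply each gene's counts by a gene-wise log-normal factor.

    Factors are drawn log-normal with log-mean 0 and log-SD ``log_sd``;
    results are re-rounded to integers. ``log_sd = 0`` returns the data
    unchanged. This emulates a multiplicative technology/batch shift
    between a reference and the bulk it is asked to deconvolve.
    """
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    if log_sd == 0:
        return ds.subset_cells(np.arange(ds.n_cells))
    rng = np.random.default_rng(seed)
    factors = rng.lognormal(mean=0.0, sigma=log_sd, size=ds.n_genes)
    counts = np.rint(ds.counts * factors[:, None]).astype(ds.counts.dtype)
    return SingleCellDataset(counts=counts, gene_ids=list(ds.gene_ids),
                             cell_ids=list(ds.cell_ids),
                             annotation=ds.annotation.copy())


def generate_purified_bulk(ref, cell_type: str, depth: int,
                           seed: int) -> tuple[BulkMatrix, np.ndarray]:
    """One-sample bulk of a single purified cell type.

    Draws ``depth`` reads multinomially from the reference mean profile
    (C1 column) of ``cell_type``. Returns the bulk and the one-hot
    ground-truth proportion vector over the reference's cell types.
    """
    labels = list(ref.cell_type_labels)
    if cell_type not in labels:
        raise ValueError(
            f"unknown cell type {cell_type!r}; known types: {labels}"
        )
    col = ref.C1[cell_type].to_numpy(dtype=float)
    total = col.sum()
    if total <= 0:
        raise ValueError(f"reference profile for {cell_type!r} is all zero")
    rng = np.random.default_rng(seed)
    sample = rng.multinomial(depth, col / total)
    bulk = BulkMatrix(values=sample[:, None].astype(float),
                      gene_ids=list(ref.C1.index),
                      sample_ids=[f"purified_{cell_type}"])
    truth = np.array([1.0 if ct == cell_type else 0.0 for ct in labels])
    return bulk, truth
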