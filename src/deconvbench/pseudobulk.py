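"""Pseudo-bulk mixture simulation with known ground truth.

Two generation modes:

* **mode 1** — per sample, ``c`` cells are drawn uniformly with
  replacement from the whole testing pool; ground truth is the realized
  cell-type composition of the draw. With a large pool this produces
  near-identical samples whose composition mirrors the pool frequencies.
* **mode 2** — per sample, target proportions are drawn first (see
  :func:`generate_proportions`), converted to integer per-type cell
  counts, and that many cells are drawn with replacement within each
  type. This yields realistic between-sample proportion variability and,
  optionally, dropout of whole cell types (``sampleCT``).

Ground truth is always the realized composition — integer counts divided
by ``c`` — so truth rows are exactly rational and consistent with the
cells actually mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import BulkMatrix, ProportionMatrix, SingleCellDataset


@dataclass
class SimulationConfig:
    """Pseudo-bulk simulation parameters.

    ``p`` (proportional variance) is sign-sensitive: negative selects
    uniform(0.01, 0.99) proportions; positive selects integer weights
    uniform on {1, ..., 1+2*floor(p)} (small p -> homogeneous mixtures,
    large p -> highly variable ones). With ``sample_ct`` set, ``p`` is
    instead the SD of the "kept" mode of a bimodal assignment that drops
    a random subset of cell types to near zero.
    """

    n: int = 50
    c: int = 1000
    p: float = -1.0
    sample_ct: bool = False
    mode: int = 2
    aggregate: str = "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.c < 1:
            raise ValueError("n and c must be >= 1")
        if self.mode not in (1, 2):
            raise ValueError("mode must be 1 or 2")
        if self.aggregate not in ("sum", "mean"):
            raise ValueError("aggregate must be 'sum' or 'mean'")
        if self.sample_ct and self.p <= 0:
            raise ValueError("sample_ct requires p > 0")


def generate_proportions(k: int, p: float, sample_ct: bool,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw one vector of target mixture proportions for ``k`` cell types.

    * ``sample_ct`` false, ``p < 0`` — independent uniform(0.01, 0.99)
      draws, normalized to sum 1.
    * ``sample_ct`` false, ``p > 0`` — integer weights uniform on
      {1, ..., 1+2*floor(p)}, normalized; non-integer ``p`` floors with a
      warning. ``p = 0`` is rejected (the sign convention leaves it
      undefined).
    * ``sample_ct`` true — each type lands with probability 1/2 in a
      near-zero mode (normal, mean 0, SD 1e-4) or a kept mode (normal,
      mean 1, SD ``p``); absolute values are taken per draw and the
      vector normalized. At least one type is forced into the kept mode
      by redrawing the assignment, so normalization is well-posed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sample_ct:
        if p <= 0:
            raise ValueError("sample_ct requires p > 0")
        while True:
            kept = rng.random(k) < 0.5
            if kept.any():
                break
        draws = np.where(kept,
                         rng.normal(1.0, p, size=k),
                         rng.normal(0.0, 1e-4, size=k))
        raw = np.abs(draws)
    elif p < 0:
        raw = rng.uniform(0.01, 0.99, size=k)
    elif p > 0:
        hi = 1 + 2 * int(np.floor(p))
        if p != np.floor(p):
            warnings.warn(f"non-integer p={p} floored to {int(np.floor(p))}")
        raw = rng.integers(1, hi + 1, size=k).astype(float)
    else:
        raise ValueError(
            "p = 0 is undefined: use p < 0 for uniform(0.01, 0.99) "
            "proportions or p > 0 for integer-weight proportions"
        )
    return raw / raw.sum()


def realize_cell_counts(props: np.ndarray, c: int) -> np.ndarray:
    """Convert target proportions into integer cell counts summing to ``c``.

    Largest-remainder rounding: start from ``floor(c * props)`` and give
    the remaining cells to the types with the largest fractional parts,
    ties broken by lowest type index.
    """
    props = np.asarray(props, dtype=float)
    if c < 1:
        raise ValueError("c must be >= 1")
    if not np.isclose(props.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1")
    scaled = c * props
    counts = np.floor(scaled).astype(int)
    deficit = c - counts.sum()
    if deficit > 0:
        remainders = scaled - counts
        # stable sort descending by remainder; ties resolve to lowest index
        order = np.argsort(-remainders, kind="stable")
        counts[order[:deficit]] += 1
    return counts


def simulate(test: SingleCellDataset, cfg: SimulationConfig) -> "PseudoBulkExperiment":
    """Run the pseudo-bulk simulation on a testing pool."""
    if test.n_cells == 0:
        raise ValueError("testing pool is empty")
    rng = np.random.default_rng(cfg.seed)
    labels = test.cell_type_labels
    k = len(labels)
    type_idx = {ct: test.cells_of_type(ct) for ct in labels}
    if cfg.mode == 2:
        empty = [ct for ct in labels if len(type_idx[ct]) == 0]
        if empty:
            raise ValueError(f"cell types absent from testing pool: {empty}")

    bulk_cols = np.empty((test.n_genes, cfg.n))
    truth = np.empty((cfg.n, k))
    counts_f = test.counts.astype(float)
    for s in range(cfg.n):
        if cfg.mode == 1:
            chosen = rng.integers(0, test.n_cells, size=cfg.c)
            realized = np.array([
                np.isin(chosen, type_idx[ct]).sum() for ct in labels
            ])
        else:
            props = generate_proportions(k, cfg.p, cfg.sample_ct, rng)
            realized = realize_cell_counts(props, cfg.c)
            chosen_parts = []
            for j, ct in enumerate(labels):
                if realized[j] > 0:
                    pool = type_idx[ct]
                    chosen_parts.append(rng.choice(pool, size=realized[j],
                                                   replace=True))
            chosen = np.concatenate(chosen_parts)
        agg = counts_f[:, chosen].sum(axis=1)
        if cfg.aggregate == "mean":
            agg = agg / cfg.c
        bulk_cols[:, s] = agg
        truth[s, :] = realized / cfg.c

    sample_ids = [f"pbulk_{i + 1:04d}" for i in range(cfg.n)]
    bulk = BulkMatrix(values=bulk_cols, gene_ids=list(test.gene_ids),
                      sample_ids=sample_ids)
    truth_pm = ProportionMatrix(values=truth, sample_ids=sample_ids,
                                cell_type_labels=labels)
    return PseudoBulkExperiment(bulk=bulk, truth=truth_pm, config=cfg)


@dataclass
class PseudoBulkExperiment:
    """A simulated mixture experiment: bulk, ground truth and provenance."""

    bulk: BulkMatrix
    truth: ProportionMatrix
    config: SimulationConfig


def simulation_diagnostics(
    exp: PseudoBulkExperiment, ref_bulk: BulkMatrix | None = None
) -> dict[str, pd.DataFrame]:
    """Distributional diagnostics of a pseudo-bulk experiment.

    Returns per-gene mean/variance/CV of the simulated bulk, the full
    pairwise Pearson correlation matrix between samples, and — when a
    comparison bulk is supplied — the same gene statistics for it on the
    shared gene space.
    """
    if exp.bulk.n_samples < 2:
        raise ValueError("diagnostics need >= 2 samples")

    def gene_stats(values: np.ndarray, gene_ids) -> pd.DataFrame:
        mean = values.mean(axis=1)
        var = values.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, np.sqrt(var) / mean, 0.0)
        return pd.DataFrame({"mean": mean, "variance": var, "cv": cv},
                            index=gene_ids)

    out: dict[str, pd.DataFrame] = {
        "gene_stats": gene_stats(exp.bulk.values, exp.bulk.gene_ids)
    }
    corr = np.corrcoef(exp.bulk.values.T)
    out["sample_correlation"] = pd.DataFrame(
        corr, index=exp.bulk.sample_ids, columns=exp.bulk.sample_ids
    )
    if ref_bulk is not None:
        shared = [g for g in exp.bulk.gene_ids if g in set(ref_bulk.gene_ids)]
        pos = {g: i for i, g in enumerate(ref_bulk.gene_ids)}
        idx = [pos[g] for g in shared]
        out["ref_gene_stats"] = gene_stats(ref_bulk.values[idx, :], shared)
    return out


def median_pairwise_correlation(exp: PseudoBulkExperiment) -> float:
    """Median off-diagonal pairwise sample correlation (similarity score)."""
    corr = np.corrcoef(exp.bulk.values.T)
    iu = np.triu_indices_from(corr, k=1)
    return float(np.median(corr[iu]))
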