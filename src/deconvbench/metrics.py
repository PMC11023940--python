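"""Evaluation of predicted against ground-truth cell-type proportions.

Nine metrics are computed: Pearson and Spearman correlation, RMSE,
weighted RMSE (rare cell types upweighted), mean absolute error,
Euclidean distance, distance correlation, cosine similarity and R².
The default aggregation scope flattens the samples x types matrices into
one vector per method; per-sample and per-cell-type means are available
because errors are often concentrated in particular types.

Correlations on constant input are undefined; they are reported as NaN
sentinels and must be excluded from rankings explicitly, never coerced
to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datasets import ProportionMatrix

logger = logging.getLogger(__name__)

METRIC_NAMES = ("pearson", "spearman", "rmse", "wrmse", "mae",
                "euclidean", "dcor", "cosine", "r2")

SCOPES = ("overall", "per_sample", "per_celltype")


# ---------------------------------------------------------------------------
# individual metrics
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(stats.spearmanr(a, b)[0])


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _mae(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(a - b)))


def _euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def _r2(pred: np.ndarray, truth: np.ndarray) -> float:
    """Truth-referenced coefficient of determination (directional)."""
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return float(1.0 - np.sum((truth - pred) ** 2) / ss_tot)


def distance_correlation(x, y) -> float:
    """Distance correlation between two equal-length vectors.

    Double-centers the pairwise absolute-difference matrices and
    normalizes the resulting distance covariance. Constant input is
    defined as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")

    def centered(v: np.ndarray) -> np.ndarray:
        d = np.abs(v[:, None] - v[None, :])
        return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()

    ax, by = centered(x), centered(y)
    dcov2 = (ax * by).mean()
    dvarx = (ax * ax).mean()
    dvary = (by * by).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def weighted_rmse(pred: ProportionMatrix | np.ndarray,
                  truth: ProportionMatrix | np.ndarray,
                  eps: float = 1e-6) -> float:
    """RMSE with per-cell-type weights favouring rare types.

    Type k receives weight ``(1/(m_k+eps)) / sum_j 1/(m_j+eps)`` where
    ``m_k`` is the mean true proportion of type k over samples; the score
    is ``sqrt(sum_k w_k * mean_i (pred_ik - truth_ik)^2)``. When all
    types share the same mean true proportion the weights collapse to
    ``1/k`` and the score equals the plain RMSE.
    """
    p = pred.values if isinstance(pred, ProportionMatrix) else np.asarray(pred, float)
    t = truth.values if isinstance(truth, ProportionMatrix) else np.asarray(truth, float)
    if p.shape != t.shape:
        raise ValueError("pred and truth shapes differ")
    m = t.mean(axis=0)
    inv = 1.0 / (m + eps)
    w = inv / inv.sum()
    mse_per_type = ((p - t) ** 2).mean(axis=0)
    return float(np.sqrt(np.sum(w * mse_per_type)))


def log_loss_purified(pred: ProportionMatrix, truth_labels,
                      eps: float = 1e-15) -> pd.Series:
    """Logarithmic loss for purified (single-cell-type) samples.

    ``loss_i = -ln(clip(pred_i[label_i], eps, 1))``: near zero when the
    purified type dominates the prediction, large when probability mass
    spills onto background types. Returns per-sample losses; the mean is
    ``result.mean()``.
    """
    labels = list(truth_labels)
    if len(labels) != pred.n_samples:
        raise ValueError("one truth label per sample required")
    unknown = sorted(set(labels) - set(pred.cell_type_labels))
    if unknown:
        raise ValueError(f"unknown cell types in truth labels: {unknown}")
    df = pred.to_frame()
    vals = np.array([df.loc[s, lab] for s, lab in zip(pred.sample_ids, labels)])
    losses = -np.log(np.clip(vals, eps, 1.0))
    return pd.Series(losses, index=pred.sample_ids, name="log_loss")


# ---------------------------------------------------------------------------
# aggregate evaluation
# ---------------------------------------------------------------------------

def _all_metrics(p: np.ndarray, t: np.ndarray,
                 wrmse_value: float | None = None) -> dict[str, float]:
    scores = {
        "pearson": _pearson(p, t),
        "spearman": _spearman(p, t),
        "rmse": _rmse(p, t),
        "wrmse": wrmse_value if wrmse_value is not None else np.nan,
        "mae": _mae(p, t),
        "euclidean": _euclidean(p, t),
        "dcor": distance_correlation(p, t) if p.size >= 2 else np.nan,
        "cosine": _cosine(p, t),
        "r2": _r2(p, t),
    }
    return scores


def evaluate_all(pred: ProportionMatrix, truth: ProportionMatrix,
                 scope: str = "overall") -> pd.Series:
    """All nine metrics for one prediction at the requested scope.

    ``overall`` flattens both matrices; ``per_sample`` and
    ``per_celltype`` compute each metric per row/column and return the
    mean over the slices (weighted RMSE keeps the global type weights in
    the per-sample scope).
    """
    if pred.sample_ids != truth.sample_ids:
        raise ValueError("sample ids differ between pred and truth")
    if pred.cell_type_labels != truth.cell_type_labels:
        raise ValueError("cell-type labels differ between pred and truth")
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; choose from {SCOPES}")
    p, t = pred.values, truth.values
    if scope == "overall":
        scores = _all_metrics(p.ravel(), t.ravel(),
                              wrmse_value=weighted_rmse(pred, truth))
    else:
        axis_slices = (range(p.shape[0]) if scope == "per_sample"
                       else range(p.shape[1]))
        per = []
        m = t.mean(axis=0)
        inv = 1.0 / (m + 1e-6)
        w = inv / inv.sum()
        for i in axis_slices:
            if scope == "per_sample":
                pi, ti = p[i, :], t[i, :]
                wr = float(np.sqrt(np.sum(w * (pi - ti) ** 2)))
            else:
                pi, ti = p[:, i], t[:, i]
                wr = _rmse(pi, ti)
            per.append(_all_metrics(pi, ti, wrmse_value=wr))
        with np.errstate(invalid="ignore"):
            scores = {k: float(np.nanmean([d[k] for d in per]))
                      for k in METRIC_NAMES}
    out = pd.Series(scores, name=scope).reindex(list(METRIC_NAMES))
    undefined = out.index[out.isna()]
    if len(undefined):
        logger.info("metrics undefined (constant input): %s",
                    list(undefined))
    return out


def build_metrics_report(results: dict[str, ProportionMatrix],
                         truth: ProportionMatrix,
                         scopes: tuple[str, ...] = ("overall",)) -> pd.DataFrame:
    """Method x metric table with one row per (method, scope)."""
    rows = []
    for name, pred in results.items():
        for scope in scopes:
            s = evaluate_all(pred, truth, scope=scope)
            rows.append(pd.concat([pd.Series({"method": name, "scope": scope}), s]))
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# agreement without ground truth
# ---------------------------------------------------------------------------

def agreement_analysis(
    results: dict[str, ProportionMatrix],
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise cross-method agreement when no ground truth exists.

    Returns the symmetric Pearson correlation matrix over the flattened
    proportion matrices and the method ordering from average-linkage
    hierarchical clustering on ``1 - correlation``, so similar methods
    appear adjacent in heatmaps.
    """
    names = list(results)
    if len(names) < 2:
        raise ValueError("agreement analysis needs >= 2 methods")
    first = results[names[0]]
    for n in names[1:]:
        if (results[n].sample_ids != first.sample_ids
                or results[n].cell_type_labels != first.cell_type_labels):
            raise ValueError(f"method {n!r} has mismatched labels")
    flat = np.stack([results[n].values.ravel() for n in names])
    corr = np.corrcoef(flat)
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [names[i] for i in hierarchy.leaves_list(link)]
    return corr_df, order


def plot_agreement_heatmap(corr: pd.DataFrame, order: list[str],
                           path) -> None:
    """Optional PNG heatmap of the agreement matrix in cluster order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = corr.loc[order, order]
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(order),) * 2)
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_yticks(range(len(order)), order)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
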