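"""Normalization and transformation of expression matrices.

The benchmark treats preprocessing as a grid of (normalization,
transformation, order) choices applied independently to the bulk matrix
and the reference signature before solving. Ten normalizations and three
transformations are available; single-cell-specific normalizers
(SCTransform, scran, scater, Linnorm) and the vst transformation are
deliberately unsupported and raise a clear error.

All methods preserve matrix shape and gene order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("none", "column", "row", "mean", "column_zscore",
                  "global_minmax", "TMM", "median_ratio", "quantile", "CPM")
TRANSFORMATIONS = ("none", "log", "sqrt")
ORDERS = ("normalize_first", "transform_first")

_UNSUPPORTED = {"vst", "sctransform", "scran", "scater", "linnorm"}


@dataclass(frozen=True)
class PreprocessSpec:
    """One cell of the preprocessing grid."""

    normalization: str = "none"
    transformation: str = "none"
    order: str = "normalize_first"

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            _raise_unknown_normalization(self.normalization)
        if self.transformation not in TRANSFORMATIONS:
            if self.transformation.lower() in _UNSUPPORTED:
                raise NotImplementedError(
                    f"transformation {self.transformation!r} is out of scope"
                )
            raise ValueError(f"unknown transformation {self.transformation!r}")
        if self.order not in ORDERS:
            raise ValueError(f"unknown order {self.order!r}")

    @property
    def label(self) -> str:
        return f"{self.normalization}+{self.transformation}+{self.order}"


def _raise_unknown_normalization(method: str) -> None:
    if method.lower() in _UNSUPPORTED:
        raise NotImplementedError(
            f"normalization {method!r} is a single-cell-specific external "
            "method and is out of scope for this toolkit"
        )
    raise ValueError(f"unknown normalization {method!r}; "
                     f"choose one of {NORMALIZATIONS}")


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_scale_factors(m: np.ndarray, trim_m: float = 0.3,
                      trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors per column.

    The reference column is the one whose upper quartile (of counts
    scaled by library size) is closest to the mean upper quartile. For
    each column, genes positive in both it and the reference contribute
    an M value (log2 ratio of library-scaled expression) and an A value
    (average log2 abundance); after trimming the extreme ``trim_m``
    fraction of M values and ``trim_a`` of A values on each side, the
    factor is 2 to the precision-weighted mean of the remaining M
    values. Factors are rescaled to have geometric mean 1.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[1] < 2:
        raise ValueError("TMM needs >= 2 columns")
    lib = m.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("TMM requires positive library sizes")
    uq = np.array([np.quantile(m[:, k][m[:, k] > 0] / lib[k], 0.75)
                   if (m[:, k] > 0).any() else 0.0
                   for k in range(m.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(m.shape[1])
    xr, nr = m[:, ref], lib[ref]
    for k in range(m.shape[1]):
        if k == ref:
            continue
        xk, nk = m[:, k], lib[k]
        ok = (xk > 0) & (xr > 0)
        if ok.sum() == 0:
            continue
        mk = np.log2((xk[ok] / nk) / (xr[ok] / nr))
        ak = 0.5 * np.log2((xk[ok] / nk) * (xr[ok] / nr))
        w = (nk - xk[ok]) / (nk * xk[ok]) + (nr - xr[ok]) / (nr * xr[ok])
        n = ok.sum()
        lo_m, hi_m = np.floor(n * trim_m), n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a), n - np.floor(n * trim_a)
        rank_m = np.argsort(np.argsort(mk, kind="stable"), kind="stable")
        rank_a = np.argsort(np.argsort(ak, kind="stable"), kind="stable")
        keep = (rank_m >= lo_m) & (rank_m < hi_m) & \
               (rank_a >= lo_a) & (rank_a < hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[k] = 2.0 ** (np.sum(mk[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# normalize / transform
# ---------------------------------------------------------------------------

def normalize(m: np.ndarray, method: str) -> np.ndarray:
    """Apply one of the supported normalizations; shape is preserved."""
    m = np.asarray(m, dtype=float)
    if method == "none":
        return m.copy()
    if method == "column":
        s = m.sum(axis=0)
        return np.divide(m, s, out=np.zeros_like(m), where=s > 0)
    if method == "row":
        s = m.sum(axis=1, keepdims=True)
        if (s == 0).any():
            warnings.warn("zero-sum rows left as zeros under row normalization")
        return np.divide(m, s, out=np.zeros_like(m), where=s > 0)
    if method == "mean":
        mu = m.mean(axis=0)
        return np.divide(m, mu, out=np.zeros_like(m), where=mu > 0)
    if method == "column_zscore":
        mu = m.mean(axis=0)
        sd = m.std(axis=0)
        out = np.zeros_like(m)
        np.divide(m - mu, sd, out=out, where=sd > 0)
        return out
    if method == "global_minmax":
        lo, hi = m.min(), m.max()
        if hi == lo:
            raise ValueError("global_minmax undefined on a constant matrix")
        return (m - lo) / (hi - lo)
    if method == "CPM":
        s = m.sum(axis=0)
        return np.divide(m * 1e6, s, out=np.zeros_like(m), where=s > 0)
    if method == "TMM":
        factors = tmm_scale_factors(m)
        eff_lib = m.sum(axis=0) * factors
        return m / eff_lib * 1e6
    if method == "median_ratio":
        if m.shape[1] < 2:
            raise ValueError("median_ratio needs >= 2 columns")
        positive = (m > 0).all(axis=1)
        if not positive.any():
            raise ValueError("median_ratio: no gene positive in all columns")
        logm = np.log(m[positive])
        pseudo_ref = np.exp(logm.mean(axis=1, keepdims=True))
        size = np.median(m[positive] / pseudo_ref, axis=0)
        return m / size
    if method == "quantile":
        order = np.argsort(m, axis=0, kind="stable")
        ranks = np.argsort(order, axis=0, kind="stable")
        mean_sorted = np.sort(m, axis=0).mean(axis=1)
        return mean_sorted[ranks]
    _raise_unknown_normalization(method)


def transform(m: np.ndarray, method: str) -> np.ndarray:
    """Elementwise transformation: ``log`` is ln(1+x), ``sqrt`` is √x."""
    m = np.asarray(m, dtype=float)
    if method == "none":
        return m.copy()
    if (m < 0).any():
        raise ValueError(
            f"transformation {method!r} requires non-negative input; "
            "negative entries typically arise after z-scoring — apply the "
            "transformation before column_zscore, or drop it"
        )
    if method == "log":
        return np.log1p(m)
    if method == "sqrt":
        return np.sqrt(m)
    if method.lower() in _UNSUPPORTED:
        raise NotImplementedError(f"transformation {method!r} is out of scope")
    raise ValueError(f"unknown transformation {method!r}")


class MatrixPreprocessor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer applying a :class:`PreprocessSpec`.

    Stateless: ``fit`` only validates the parameters. ``transform``
    expects a genes x columns array and applies normalization and
    transformation in the configured order.
    """

    def __init__(self, normalization: str = "none",
                 transformation: str = "none",
                 order: str = "normalize_first"):
        self.normalization = normalization
        self.transformation = transformation
        self.order = order

    def fit(self, X, y=None):
        self.spec_ = PreprocessSpec(self.normalization, self.transformation,
                                    self.order)
        if (self.spec_.order == "normalize_first"
                and self.spec_.normalization == "column_zscore"
                and self.spec_.transformation != "none"):
            raise ValueError(
                "column_zscore followed by a transformation produces "
                "negative inputs for log/sqrt; use transform_first or "
                "transformation='none'"
            )
        return self

    def transform(self, X):
        if not hasattr(self, "spec_"):
            self.fit(X)
        m = np.asarray(X, dtype=float)
        if self.spec_.order == "normalize_first":
            m = normalize(m, self.spec_.normalization)
            m = transform(m, self.spec_.transformation)
        else:
            m = transform(m, self.spec_.transformation)
            m = normalize(m, self.spec_.normalization)
        return m


def preprocess_pair(bulk, ref, spec: PreprocessSpec):
    """Apply a preprocessing spec to a bulk matrix and a reference bundle.

    Both matrices are processed independently with the same spec; the
    reference's C1 signature is the processed artifact (the raw C0 counts
    are left untouched — the regression family consumes C1 only).
    Returns ``(bulk', C1')`` where ``C1'`` is a processed copy of the
    signature DataFrame.
    """
    pre = MatrixPreprocessor(spec.normalization, spec.transformation,
                             spec.order).fit(None)
    new_bulk = bulk.with_values(pre.transform(bulk.values))
    c1 = ref.C1.copy()
    c1.iloc[:, :] = pre.transform(c1.to_numpy())
    return new_bulk, c1
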