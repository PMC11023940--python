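"""Regression-based deconvolution solvers and the consensus estimator.

Every solver estimates, per bulk sample, the cell-type weight vector w
minimizing a (possibly penalized or re-weighted) least-squares criterion

    || y - C1 w ||^2

where ``C1`` is the genes x cell-types signature matrix and ``y`` the
sample's expression over the same genes. Negative coefficients are
truncated at zero and the vector renormalized to the unit simplex, so
every output is a valid proportion vector; a degenerate all-zero solution
falls back to the uniform vector with a warning.

Solvers are scikit-learn style estimators: construct with hyperparameters,
``fit(reference)`` with the signature matrix (genes x types DataFrame or
array), ``predict(bulk)`` with a genes x samples matrix to obtain a
samples x types proportion DataFrame. ``get_params``/``set_params`` work
as usual, so the estimators compose with sklearn model-selection tooling.
"""

from __future__ import annotations

import logging
import resource
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.utils.validation import check_is_fitted

from .datasets import BulkMatrix, ProportionMatrix

logger = logging.getLogger(__name__)


def _simplex_project(w: np.ndarray, context: str = "") -> np.ndarray:
    """Truncate negatives and renormalize to sum 1; uniform on collapse."""
    w = np.clip(np.asarray(w, dtype=float), 0.0, None)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        warnings.warn(f"all-zero solution{context}; returning uniform proportions")
        return np.full(w.shape, 1.0 / w.size)
    return w / total


class BaseDeconvolver(BaseEstimator):
    """Common fit/predict machinery for the regression solver family."""

    #: registry short name, set by subclasses
    name: str = "base"

    def fit(self, reference, y=None):
        """Store and validate the signature matrix (genes x cell types)."""
        if isinstance(reference, pd.DataFrame):
            sig = reference.to_numpy(dtype=float)
            self.gene_ids_ = [str(g) for g in reference.index]
            self.cell_type_labels_ = [str(c) for c in reference.columns]
        else:
            sig = np.asarray(reference, dtype=float)
            self.gene_ids_ = None
            self.cell_type_labels_ = [f"type_{j}" for j in range(sig.shape[1])]
        if sig.ndim != 2:
            raise ValueError("reference must be 2-D (genes x cell types)")
        if sig.shape[0] < sig.shape[1]:
            raise ValueError(
                f"reference has fewer genes ({sig.shape[0]}) than cell "
                f"types ({sig.shape[1]})"
            )
        if not np.isfinite(sig).all():
            raise ValueError("reference contains non-finite values")
        zero_cols = np.flatnonzero((sig == 0).all(axis=0))
        if len(zero_cols):
            raise ValueError(
                f"reference columns all-zero: "
                f"{[self.cell_type_labels_[j] for j in zero_cols]}"
            )
        self.signature_ = sig
        self.n_features_in_ = sig.shape[0]
        return self

    def _coerce_bulk(self, bulk) -> tuple[np.ndarray, list[str]]:
        if isinstance(bulk, BulkMatrix):
            values, sample_ids = bulk.values, list(bulk.sample_ids)
        elif isinstance(bulk, pd.DataFrame):
            values, sample_ids = bulk.to_numpy(dtype=float), [str(s) for s in bulk.columns]
        else:
            values = np.asarray(bulk, dtype=float)
            if values.ndim == 1:
                values = values[:, None]
            sample_ids = [f"sample_{i}" for i in range(values.shape[1])]
        if values.shape[0] != self.signature_.shape[0]:
            raise ValueError(
                f"bulk has {values.shape[0]} genes but the fitted signature "
                f"has {self.signature_.shape[0]}; harmonize gene spaces first"
            )
        if not np.isfinite(values).all():
            raise ValueError("bulk contains non-finite values")
        return values, sample_ids

    def predict(self, bulk) -> pd.DataFrame:
        """Per-sample proportions for a genes x samples bulk matrix."""
        check_is_fitted(self, "signature_")
        values, sample_ids = self._coerce_bulk(bulk)
        out = np.empty((values.shape[1], self.signature_.shape[1]))
        for s in range(values.shape[1]):
            try:
                w = self._solve(self.signature_, values[:, s])
            except Exception as exc:
                logger.warning("solver %s failed on sample %s (%s); "
                               "falling back to uniform", self.name,
                               sample_ids[s], exc)
                w = np.full(self.signature_.shape[1], np.nan)
            out[s, :] = _simplex_project(w, context=f" for sample {sample_ids[s]}")
        return pd.DataFrame(out, index=sample_ids, columns=self.cell_type_labels_)

    def _solve(self, A: np.ndarray, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class OLSDeconvolver(BaseDeconvolver):
    """Unconstrained least squares; negatives truncated afterwards."""

    name = "ols"

    def _solve(self, A, y):
        w, *_ = np.linalg.lstsq(A, y, rcond=None)
        return w


class NNLSDeconvolver(BaseDeconvolver):
    """Non-negative least squares (Lawson–Hanson active set)."""

    name = "nnls"

    def _solve(self, A, y):
        w, _ = scipy.optimize.nnls(A, y)
        return w


class RLRDeconvolver(BaseDeconvolver):
    """Robust linear regression with Huber weights (IRLS)."""

    name = "rlr"

    def __init__(self, huber_k: float = 1.345, max_iter: int = 50):
        self.huber_k = huber_k
        self.max_iter = max_iter

    def _solve(self, A, y):
        model = sm.RLM(y, A, M=sm.robust.norms.HuberT(t=self.huber_k))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=self.max_iter)
        return res.params


class RidgeDeconvolver(BaseDeconvolver):
    """L2-penalized least squares; the penalty defaults to a weak value so
    noiseless mixtures are recovered essentially unbiased."""

    name = "ridge"

    def __init__(self, alpha: float = 1e-4):
        self.alpha = alpha

    def _solve(self, A, y):
        model = Ridge(alpha=self.alpha, fit_intercept=False)
        model.fit(A, y)
        return model.coef_


class LassoDeconvolver(BaseDeconvolver):
    """L1-penalized least squares by coordinate descent."""

    name = "lasso"

    def __init__(self, alpha: float = 1e-4, max_iter: int = 10000,
                 tol: float = 1e-8):
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol

    def _solve(self, A, y):
        model = Lasso(alpha=self.alpha, fit_intercept=False,
                      max_iter=self.max_iter, tol=self.tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(A, y)
        return model.coef_


class ElasticNetDeconvolver(BaseDeconvolver):
    """Elastic-net-penalized least squares by coordinate descent."""

    name = "elastic_net"

    def __init__(self, alpha: float = 1e-4, l1_ratio: float = 0.5,
                 max_iter: int = 10000, tol: float = 1e-8):
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.max_iter = max_iter
        self.tol = tol

    def _solve(self, A, y):
        model = ElasticNet(alpha=self.alpha, l1_ratio=self.l1_ratio,
                           fit_intercept=False, max_iter=self.max_iter,
                           tol=self.tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(A, y)
        return model.coef_


class DWLSDeconvolver(BaseDeconvolver):
    """Dampened weighted least squares.

    Starting from the NNLS solution, genes are re-weighted by the inverse
    squared fitted expression, ``1 / max((C1 w)^2, eps)``, so that
    low-expressed genes — which carry the signal of rare cell types — are
    not drowned out by highly expressed ones. Unbounded weights make the
    iteration unstable, so they are dampened: the weight ratio is capped
    at ``2**d`` for a dampening exponent ``d`` selected from a grid by
    minimizing the variance of the weighted solution under bootstrap
    resampling of genes. The weighted NNLS iteration then runs to a fixed
    point.
    """

    name = "dwls"

    def __init__(self, dampening_grid: tuple = tuple(range(1, 15)),
                 n_resamples: int = 100, max_iter: int = 100,
                 tol: float = 1e-6, eps: float = 1e-8,
                 random_state: int | None = 0):
        self.dampening_grid = dampening_grid
        self.n_resamples = n_resamples
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.random_state = random_state

    def _dampened_weights(self, fitted: np.ndarray, d: int) -> np.ndarray:
        w = 1.0 / np.maximum(fitted ** 2, self.eps)
        ratio = w / w.min()
        return np.minimum(ratio, 2.0 ** d)

    def _select_dampening(self, A: np.ndarray, y: np.ndarray,
                          fitted: np.ndarray,
                          rng: np.random.Generator) -> int:
        """Pick the exponent whose weighted solution is most stable under
        gene resampling (smallest mean coefficient variance)."""
        n_genes = A.shape[0]
        best_d, best_score = self.dampening_grid[0], np.inf
        for d in self.dampening_grid:
            weights = self._dampened_weights(fitted, d)
            sols = np.empty((self.n_resamples, A.shape[1]))
            for b in range(self.n_resamples):
                idx = rng.integers(0, n_genes, size=n_genes)
                sw = np.sqrt(weights[idx])
                Aw = A[idx] * sw[:, None]
                yw = y[idx] * sw
                sol, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
                total = np.abs(sol).sum()
                sols[b] = sol / total if total > 0 else sol
            score = sols.var(axis=0).mean()
            if score < best_score:
                best_score, best_d = score, d
        return best_d

    def _solve(self, A, y):
        w, _ = scipy.optimize.nnls(A, y)
        if w.sum() <= 0:
            return w
        rng = np.random.default_rng(self.random_state)
        fitted = A @ w
        d = self._select_dampening(A, y, fitted, rng)
        self.dampening_exponent_ = d
        w_cur = w / w.sum()
        for _ in range(self.max_iter):
            fitted = A @ w_cur
            weights = self._dampened_weights(np.maximum(fitted, 0), d)
            sw = np.sqrt(weights)
            sol, _ = scipy.optimize.nnls(A * sw[:, None], y * sw)
            total = sol.sum()
            if total <= 0:
                break
            w_new = sol / total
            if np.max(np.abs(w_new - w_cur)) < self.tol:
                w_cur = w_new
                break
            w_cur = w_new
        return w_cur


SOLVER_REGISTRY: dict[str, type[BaseDeconvolver]] = {
    cls.name: cls
    for cls in (OLSDeconvolver, NNLSDeconvolver, RLRDeconvolver,
                RidgeDeconvolver, LassoDeconvolver, ElasticNetDeconvolver,
                DWLSDeconvolver)
}


@dataclass
class SolverSpec:
    """A solver name plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SOLVER_REGISTRY:
            raise ValueError(
                f"unknown solver {self.name!r}; available: "
                f"{sorted(SOLVER_REGISTRY)}"
            )


def make_solver(spec: SolverSpec | str) -> BaseDeconvolver:
    if isinstance(spec, str):
        spec = SolverSpec(spec)
    return SOLVER_REGISTRY[spec.name](**spec.hyperparameters)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def solve_sample(C1, y, spec: SolverSpec | str) -> np.ndarray:
    """Proportion vector for one bulk sample (thin wrapper over estimators)."""
    solver = make_solver(spec).fit(C1)
    y = np.asarray(y, dtype=float)
    return solver.predict(y[:, None]).to_numpy()[0]


def run_methods(
    C1,
    bulk: BulkMatrix,
    specs: list[SolverSpec | str],
    record_to: list | None = None,
) -> dict[str, ProportionMatrix]:
    """Run several solvers on the same (C1, bulk) pair.

    Per-method wall-clock time, CPU time and peak RSS are appended to
    ``record_to`` when given. Solver failures on individual samples fall
    back to uniform proportions with a logged diagnostic (handled inside
    the estimators), never silent omission.
    """
    results: dict[str, ProportionMatrix] = {}
    for spec in specs:
        solver = make_solver(spec)
        t0, c0 = time.perf_counter(), time.process_time()
        frame = solver.fit(C1).predict(bulk)
        wall, cpu = time.perf_counter() - t0, time.process_time() - c0
        results[solver.name] = ProportionMatrix.from_frame(frame)
        if record_to is not None:
            record_to.append({
                "stage": f"solver:{solver.name}",
                "wall_time_s": wall,
                "cpu_time_s": cpu,
                "max_rss_bytes": _max_rss_bytes(),
            })
    return results


def _max_rss_bytes() -> int | None:
    try:
        rss = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss
    except Exception:  # pragma: no cover - platform without getrusage
        return None
    # ru_maxrss is KiB on Linux, bytes on macOS
    import sys
    return rss if sys.platform == "darwin" else rss * 1024


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Cross-method average with agreement diagnostics."""

    mean_props: ProportionMatrix
    per_cell_type_sd: pd.DataFrame      # samples x cell types
    mean_pairwise_correlation: float
    members: list[str]


def consensus(
    results: dict[str, ProportionMatrix],
    members: tuple[str, ...] = ("dwls", "rlr", "nnls"),
) -> ConsensusResult:
    """Average the proportion estimates of several solvers.

    The consensus is the per-sample, per-cell-type arithmetic mean over
    the member methods, renormalized per row; the cross-method SD
    (population, ddof=0) and the mean pairwise Pearson correlation of the
    flattened member matrices quantify agreement.
    """
    missing = [m for m in members if m not in results]
    if missing:
        raise ValueError(
            f"consensus members {missing} absent from results; "
            f"available: {sorted(results)}"
        )
    if len(members) < 2:
        raise ValueError("consensus needs >= 2 members")
    first = results[members[0]]
    for m in members[1:]:
        other = results[m]
        if (other.sample_ids != first.sample_ids
                or other.cell_type_labels != first.cell_type_labels):
            raise ValueError(f"member {m!r} has mismatched sample/type labels")
    stack = np.stack([results[m].values for m in members])
    mean = stack.mean(axis=0)
    mean = mean / mean.sum(axis=1, keepdims=True)
    sd = stack.std(axis=0, ddof=0)
    corrs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            corrs.append(np.corrcoef(stack[i].ravel(), stack[j].ravel())[0, 1])
    return ConsensusResult(
        mean_props=ProportionMatrix(values=mean,
                                    sample_ids=list(first.sample_ids),
                                    cell_type_labels=list(first.cell_type_labels)),
        per_cell_type_sd=pd.DataFrame(sd, index=first.sample_ids,
                                      columns=first.cell_type_labels),
        mean_pairwise_correlation=float(np.mean(corrs)),
        members=list(members),
    )


def order_samples_by_abundance(props: ProportionMatrix) -> list[str]:
    """Sample order for consensus barplots: descending proportion of the
    overall most abundant cell type."""
    df = props.to_frame()
    top = df.mean(axis=0).idxmax()
    return list(df.sort_values(top, ascending=False).index)
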