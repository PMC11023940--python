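import numpy as np
import pandas as pd
import pytest
from scipy import stats

import deconvbench as db
from deconvbench.metrics import METRIC_NAMES


def naive_metrics(pred, truth):
    """Independent loop-based implementations of all nine metrics."""
    p = [float(v) for v in np.asarray(pred).ravel()]
    t = [float(v) for v in np.asarray(truth).ravel()]
    n = len(p)
    mp, mt = sum(p) / n, sum(t) / n
    cov = sum((a - mp) * (b - mt) for a, b in zip(p, t)) / n
    sp = (sum((a - mp) ** 2 for a in p) / n) ** 0.5
    st_ = (sum((b - mt) ** 2 for b in t) / n) ** 0.5
    pearson = cov / (sp * st_) if sp > 0 and st_ > 0 else float("nan")

    def ranks(v):
        order = sorted(range(n), key=lambda i: v[i])
        r = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rp, rt = ranks(p), ranks(t)
    mrp, mrt = sum(rp) / n, sum(rt) / n
    cov_r = sum((a - mrp) * (b - mrt) for a, b in zip(rp, rt)) / n
    sdp = (sum((a - mrp) ** 2 for a in rp) / n) ** 0.5
    sdt = (sum((b - mrt) ** 2 for b in rt) / n) ** 0.5
    spearman = cov_r / (sdp * sdt) if sdp > 0 and sdt > 0 else float("nan")

    rmse = (sum((a - b) ** 2 for a, b in zip(p, t)) / n) ** 0.5
    mae = sum(abs(a - b) for a, b in zip(p, t)) / n
    euclid = sum((a - b) ** 2 for a, b in zip(p, t)) ** 0.5
    dot = sum(a * b for a, b in zip(p, t))
    na = sum(a * a for a in p) ** 0.5
    nb = sum(b * b for b in t) ** 0.5
    cosine = dot / (na * nb) if na > 0 and nb > 0 else float("nan")
    ss_res = sum((b - a) ** 2 for a, b in zip(p, t))
    ss_tot = sum((b - mt) ** 2 for b in t)
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    # weighted rmse on the matrix shape
    P = np.asarray(pred, dtype=float)
    T = np.asarray(truth, dtype=float)
    k = T.shape[1]
    m = [sum(T[i, j] for i in range(T.shape[0])) / T.shape[0] for j in range(k)]
    inv = [1 / (mj + 1e-6) for mj in m]
    wts = [v / sum(inv) for v in inv]
    mse = [sum((P[i, j] - T[i, j]) ** 2 for i in range(T.shape[0])) / T.shape[0]
           for j in range(k)]
    wrmse = sum(w * e for w, e in zip(wts, mse)) ** 0.5

    return {"pearson": pearson, "spearman": spearman, "rmse": rmse,
            "wrmse": wrmse, "mae": mae, "euclidean": euclid,
            "dcor": naive_dcor(p, t), "cosine": cosine, "r2": r2}


def naive_dcor(x, y):
    """Direct O(n^2) distance correlation."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(d):
        row = [sum(r) / n for r in d]
        col = [sum(d[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[d[i][j] - row[i] - col[j] + grand for j in range(n)]
                for i in range(n)]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n ** 2
    dvx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n ** 2
    dvy = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n ** 2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return (max(dcov2, 0.0) / (dvx * dvy) ** 0.5) ** 0.5


def _pm(values, types=None):
    values = np.asarray(values, dtype=float)
    types = types or [f"T{j}" for j in range(values.shape[1])]
    return db.ProportionMatrix(values=values,
                               sample_ids=[f"s{i}" for i in range(values.shape[0])],
                               cell_type_labels=list(types))


class TestEvaluateAll:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        truth = _pm(rng.dirichlet(np.ones(4), size=6))
        s = db.evaluate_all(truth, truth)
        assert s["rmse"] == 0 and s["mae"] == 0 and s["euclidean"] == 0
        for m in ("pearson", "spearman", "cosine", "r2"):
            assert s[m] == pytest.approx(1.0)

    def test_uniform_vs_one_hot_closed_form(self):
        pred = _pm([[0.25, 0.25, 0.25, 0.25]])
        truth = _pm([[1.0, 0.0, 0.0, 0.0]])
        s = db.evaluate_all(pred, truth)
        expected = np.sqrt((0.75 ** 2 + 3 * 0.25 ** 2) / 4)
        assert s["rmse"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4330127, abs=1e-6)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pred = rng.dirichlet(np.ones(4), size=10)
            truth = rng.dirichlet(np.ones(4), size=10)
            s = db.evaluate_all(_pm(pred), _pm(truth))
            expected = naive_metrics(pred, truth)
            for m in METRIC_NAMES:
                assert s[m] == pytest.approx(expected[m], abs=1e-10), m

    def test_label_mismatch_rejected(self):
        a = _pm([[0.5, 0.5]], types=["A", "B"])
        b = _pm([[0.5, 0.5]], types=["A", "C"])
        with pytest.raises(ValueError, match="labels differ"):
            db.evaluate_all(a, b)

    def test_constant_truth_gives_nan_sentinel_not_zero(self):
        pred = _pm([[0.4, 0.6], [0.3, 0.7]])
        truth = _pm([[0.5, 0.5], [0.5, 0.5]])
        s = db.evaluate_all(pred, truth)
        assert np.isnan(s["r2"])
        assert s["rmse"] > 0

    def test_scopes_available(self):
        rng = np.random.default_rng(2)
        pred = _pm(rng.dirichlet(np.ones(3), size=8))
        truth = _pm(rng.dirichlet(np.ones(3), size=8))
        for scope in ("overall", "per_sample", "per_celltype"):
            s = db.evaluate_all(pred, truth, scope=scope)
            assert s["rmse"] >= 0

    def test_symmetric_metrics_unchanged_under_swap(self):
        rng = np.random.default_rng(3)
        pred = _pm(rng.dirichlet(np.ones(4), size=7))
        truth = _pm(rng.dirichlet(np.ones(4), size=7))
        a = db.evaluate_all(pred, truth)
        b = db.evaluate_all(truth, pred)
        for m in ("pearson", "spearman", "dcor", "cosine", "euclidean",
                  "rmse", "mae"):
            assert a[m] == pytest.approx(b[m], abs=1e-12)

    def test_pearson_affine_invariant_rmse_not(self):
        rng = np.random.default_rng(4)
        truth = rng.dirichlet(np.ones(3), size=6)
        pred = rng.dirichlet(np.ones(3), size=6)
        base = db.evaluate_all(_pm(pred), _pm(truth))
        scaled = 0.5 * pred + 0.5 / 3  # affine, still on the simplex
        after = db.evaluate_all(_pm(scaled), _pm(truth))
        assert after["pearson"] == pytest.approx(base["pearson"], abs=1e-12)
        assert after["rmse"] != pytest.approx(base["rmse"], abs=1e-12)

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(5)
        pred = rng.dirichlet(np.ones(4), size=9)
        truth = rng.dirichlet(np.ones(4), size=9)
        s = db.evaluate_all(_pm(pred), _pm(truth))
        rp = stats.rankdata(pred.ravel())
        rt = stats.rankdata(truth.ravel())
        assert s["spearman"] == pytest.approx(stats.pearsonr(rp, rt)[0],
                                              abs=1e-12)


class TestWeightedRmse:
    def test_zero_for_perfect(self):
        rng = np.random.default_rng(6)
        t = _pm(rng.dirichlet(np.ones(3), size=5))
        assert db.weighted_rmse(t, t) == 0

    def test_collapses_to_rmse_for_equal_mean_types(self):
        # truth types with identical mean proportions
        truth = np.array([[0.6, 0.4], [0.4, 0.6]])
        pred = np.array([[0.5, 0.5], [0.3, 0.7]])
        w = db.weighted_rmse(pred, truth)
        rmse = np.sqrt(np.mean((pred - truth) ** 2))
        assert w == pytest.approx(rmse, rel=1e-5)

    def test_rare_type_error_weighs_more(self):
        truth = np.tile([0.05, 0.5, 0.45], (4, 1))
        err_on_rare = truth.copy()
        err_on_rare[:, 0] += 0.1
        err_on_rare[:, 1] -= 0.1
        err_on_common = truth.copy()
        err_on_common[:, 1] += 0.1
        err_on_common[:, 2] -= 0.1
        assert (db.weighted_rmse(err_on_rare, truth)
                > db.weighted_rmse(err_on_common, truth))


class TestDistanceCorrelation:
    def test_perfect_linear_dependence(self):
        x = np.arange(10.0)
        assert db.distance_correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_constant_input_defined_as_zero(self):
        assert db.distance_correlation(np.full(5, 3.0), np.arange(5.0)) == 0.0

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert db.distance_correlation(x, y) == pytest.approx(
            naive_dcor(list(x), list(y)), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            db.distance_correlation(np.ones(3), np.ones(4))


class TestLogLoss:
    def test_one_hot_match_is_zero(self):
        pred = _pm([[1.0, 0.0], [0.0, 1.0]], types=["A", "B"])
        losses = db.log_loss_purified(pred, ["A", "B"])
        assert losses.max() == 0

    def test_uniform_over_four_types(self):
        pred = _pm([[0.25] * 4])
        losses = db.log_loss_purified(pred, ["T1"])
        assert losses.iloc[0] == pytest.approx(np.log(4))

    def test_zero_probability_clipped(self):
        pred = _pm([[0.0, 1.0]], types=["A", "B"])
        losses = db.log_loss_purified(pred, ["A"])
        assert losses.iloc[0] == pytest.approx(-np.log(1e-15))

    def test_unknown_label_rejected(self):
        pred = _pm([[0.5, 0.5]], types=["A", "B"])
        with pytest.raises(ValueError, match="unknown"):
            db.log_loss_purified(pred, ["C"])


class TestAgreement:
    def test_identical_methods_correlate_fully(self):
        rng = np.random.default_rng(8)
        p = _pm(rng.dirichlet(np.ones(3), size=5))
        corr, order = db.agreement_analysis({"a": p, "b": p})
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert set(order) == {"a", "b"}

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(9)
        mats = {n: _pm(rng.dirichlet(np.ones(3), size=6))
                for n in ("x", "y", "z")}
        corr, _ = db.agreement_analysis(mats)
        m = corr.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_row_permutation_decorrelates(self):
        rng = np.random.default_rng(10)
        vals = rng.dirichlet(np.ones(3), size=6)
        a = _pm(vals)
        b = _pm(vals[[3, 4, 5, 0, 1, 2]])
        corr, _ = db.agreement_analysis({"a": a, "b": b})
        assert corr.loc["a", "b"] < 1.0

    def test_clustering_groups_similar_methods(self):
        rng = np.random.default_rng(11)
        base = rng.dirichlet(np.ones(3), size=8)
        near = np.clip(base + rng.normal(0, 0.01, base.shape), 1e-6, None)
        near /= near.sum(axis=1, keepdims=True)
        far = rng.dirichlet(np.ones(3), size=8)
        corr, order = db.agreement_analysis(
            {"m1": _pm(base), "m2": _pm(near), "m3": _pm(far)})
        i1, i2, i3 = order.index("m1"), order.index("m2"), order.index("m3")
        assert abs(i1 - i2) == 1   # the similar pair is adjacent

    def test_heatmap_written(self, tmp_path):
        rng = np.random.default_rng(12)
        mats = {n: _pm(rng.dirichlet(np.ones(3), size=5)) for n in ("a", "b")}
        corr, order = db.agreement_analysis(mats)
        out = tmp_path / "heat.png"
        db.metrics.plot_agreement_heatmap(corr, order, out)
        assert out.stat().st_size > 0
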