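import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import deconvbench as db
from deconvbench.reference import _wilcoxon_vectorized


def _make_ds(counts, types):
    n_genes, n_cells = counts.shape
    cells = [f"c{i}" for i in range(n_cells)]
    ann = pd.DataFrame({"cell_id": cells, "sample_id": "s",
                        "cell_type": list(types)})
    return db.SingleCellDataset(counts=counts,
                                gene_ids=[f"g{i}" for i in range(n_genes)],
                                cell_ids=cells, annotation=ann)


class TestSplit:
    def test_even_split(self):
        ds = _make_ds(np.ones((3, 10), dtype=int), "A" * 10)
        train, test = db.split_train_test(ds, 0.5, seed=1)
        assert train.n_cells == 5 and test.n_cells == 5

    def test_odd_count_floors_to_train(self):
        ds = _make_ds(np.ones((3, 7), dtype=int), "A" * 7)
        train, test = db.split_train_test(ds, 0.5, seed=1)
        assert train.n_cells == 3 and test.n_cells == 4

    def test_partition_is_disjoint_and_exhaustive(self, small_synth):
        train, test = db.split_train_test(small_synth, seed=5)
        assert set(train.cell_ids).isdisjoint(test.cell_ids)
        assert set(train.cell_ids) | set(test.cell_ids) == set(small_synth.cell_ids)

    def test_stratified_every_type_on_both_sides(self, small_synth):
        train, test = db.split_train_test(small_synth, seed=5)
        assert train.cell_type_labels == test.cell_type_labels

    def test_reproducible_and_seed_sensitive(self, small_synth):
        t1, _ = db.split_train_test(small_synth, seed=5)
        t2, _ = db.split_train_test(small_synth, seed=5)
        t3, _ = db.split_train_test(small_synth, seed=6)
        assert t1.cell_ids == t2.cell_ids
        assert t1.cell_ids != t3.cell_ids

    def test_singleton_type_rejected(self):
        ds = _make_ds(np.ones((3, 3), dtype=int), "AAB")
        with pytest.raises(ValueError, match="B"):
            db.split_train_test(ds, seed=0)


class TestC1RefVar:
    def test_mean_of_two_cells(self):
        ds = _make_ds(np.array([[2, 4]]), "AA")
        assert db.build_c1(ds).loc["g0", "A"] == 3

    def test_single_cell_type_column_equals_cell(self):
        ds = _make_ds(np.array([[2, 9], [5, 1]]), "AB")
        c1 = db.build_c1(ds)
        assert list(c1["B"]) == [9, 1]

    def test_c1_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 30, (6, 9))
        types = "AABBBCCCC"
        ds = _make_ds(counts, types)
        c1 = db.build_c1(ds)
        for ct in "ABC":
            idx = [i for i, t in enumerate(types) if t == ct]
            for g in range(6):
                expected = sum(counts[g, i] for i in idx) / len(idx)
                assert c1.iloc[g][ct] == pytest.approx(expected, abs=1e-12)

    def test_refvar_closed_form_and_constant(self):
        ds = _make_ds(np.array([[2, 4], [7, 7]]), "AA")
        rv = db.build_ref_var(ds)
        assert rv.loc["g0", "A"] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert rv.loc["g1", "A"] == 0

    def test_refvar_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 30, (5, 8))
        types = "AAABBBCC"
        ds = _make_ds(counts, types)
        rv = db.build_ref_var(ds)
        for ct in "ABC":
            idx = [i for i, t in enumerate(types) if t == ct]
            for g in range(5):
                vals = [counts[g, i] for i in idx]
                mean = sum(vals) / len(vals)
                sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
                assert rv.iloc[g][ct] == pytest.approx(sd, abs=1e-12)

    def test_single_cell_type_refvar_zero_with_warning(self):
        ds = _make_ds(np.array([[2, 4, 5]]), "AAB")
        with pytest.warns(UserWarning, match="single cell"):
            rv = db.build_ref_var(ds)
        assert rv.loc["g0", "B"] == 0


def exact_rank_sum_p(x, y):
    """Exhaustive two-sided permutation p-value of the rank-sum statistic."""
    from scipy.stats import rankdata
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    mu = n1 * len(y) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestWilcoxon:
    def test_identical_multisets_give_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = db.wilcoxon_rank_sum(x, x)
        assert p == 1.0

    def test_separated_groups_exact_enumeration(self):
        x, y = (1, 2, 3), (4, 5, 6)
        assert exact_rank_sum_p(x, y) == pytest.approx(0.1)
        _, p = db.wilcoxon_rank_sum(x, y)
        assert abs(p - 0.1) < 0.05

    def test_all_identical_values_p_one(self):
        _, p = db.wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            db.wilcoxon_rank_sum([], [1.0])

    def test_ties_handled_with_midranks(self):
        _, p = db.wilcoxon_rank_sum([1, 1, 2, 2], [2, 3, 3, 4])
        assert 0 < p < 1

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(12)
        in_mat = rng.poisson(2.0, (20, 8)).astype(float)
        out_mat = rng.poisson(3.0, (20, 11)).astype(float)
        u_vec, p_vec = _wilcoxon_vectorized(in_mat, out_mat)
        for g in range(20):
            u, p = db.wilcoxon_rank_sum(in_mat[g], out_mat[g])
            assert u_vec[g] == pytest.approx(u, abs=1e-9)
            assert p_vec[g] == pytest.approx(p, abs=1e-12)


class TestFindMarkers:
    def test_planted_markers_recovered(self):
        cfg = db.SynthConfig(n_genes=600, cells_per_type=150,
                             cell_types=("x", "y", "z"),
                             n_markers_per_type=12, marker_fold=4.0, seed=21)
        ds = db.qc_filter(db.generate_sc(cfg), min_genes=50)
        c2, table = db.find_markers(ds)
        planted = db.planted_markers(cfg)
        for ct in cfg.cell_types:
            hits = set(planted[ct]) & set(c2[ct])
            assert len(hits) / len(planted[ct]) >= 0.8

    def test_t_test_variant_also_recovers(self):
        cfg = db.SynthConfig(n_genes=400, cells_per_type=120,
                             cell_types=("x", "y"), n_markers_per_type=10,
                             marker_fold=4.0, seed=22)
        ds = db.generate_sc(cfg)
        c2, _ = db.find_markers(ds, test_name="t")
        planted = db.planted_markers(cfg)
        hits = set(planted["x"]) & set(c2["x"])
        assert len(hits) / 10 >= 0.8

    def test_low_pct_gene_excluded_regardless_of_p(self):
        # one gene massively expressed in 5% of in-group cells only
        rng = np.random.default_rng(30)
        counts = rng.poisson(5.0, (50, 200))
        counts[0, :] = 0
        counts[0, :5] = 1000     # cells 0..99 are type A; 5% of in-group
        ds = _make_ds(counts, "A" * 100 + "B" * 100)
        c2, table = db.find_markers(ds, min_pct=0.1)
        assert "g0" not in c2["A"]
        assert "g0" not in set(table[table.cell_type == "A"].gene)

    def test_marker_table_p_values_valid(self):
        cfg = db.SynthConfig(n_genes=300, cells_per_type=80,
                             cell_types=("x", "y"), seed=23)
        ds = db.generate_sc(cfg)
        _, table = db.find_markers(ds)
        assert ((table.p_value >= 0) & (table.p_value <= 1)).all()
        assert ((table.adjusted_p >= 0) & (table.adjusted_p <= 1)).all()
        # BH is monotone: sorting by p sorts adjusted p within a type
        for ct, grp in table.groupby("cell_type"):
            srt = grp.sort_values("p_value")
            assert srt.adjusted_p.is_monotonic_increasing

    def test_single_type_rejected(self):
        ds = _make_ds(np.ones((5, 4), dtype=int), "AAAA")
        with pytest.raises(ValueError, match="2 cell types"):
            db.find_markers(ds)


class TestMarkerOverlap:
    def test_identical_inputs(self):
        c2 = {"A": ["g1", "g2"], "B": ["g3"]}
        assert db.marker_overlap(c2, c2) == c2

    def test_intersection_keeps_first_order(self):
        a = {"A": ["g1", "g2", "g3"]}
        b = {"A": ["g2", "g4"]}
        assert db.marker_overlap(a, b) == {"A": ["g2"]}

    def test_disjoint_warns_and_empties(self):
        a = {"A": ["g1"]}
        b = {"A": ["g2"]}
        with pytest.warns(UserWarning, match="empty"):
            out = db.marker_overlap(a, b)
        assert out == {"A": []}

    def test_mismatched_labels_error(self):
        with pytest.raises(ValueError, match="differ"):
            db.marker_overlap({"A": []}, {"B": []})
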