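import numpy as np
import pytest
from scipy import stats

from genefs import (
    ExpressionDataset,
    MRMRSelector,
    TTestScreen,
    f_statistic,
    mrmr_select_fcq,
    pearson,
    ttest_from_summary,
    ttest_screen,
    ttest_two_tailed,
)


def _dataset(values, labels):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
        values=values,
        labels=np.asarray(labels),
    )


class TestFStatistic:
    def test_identical_group_means_give_zero(self):
        assert f_statistic([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1]) == pytest.approx(0)

    def test_two_group_hand_example(self):
        # [1,2,3] vs [4,5,6]: between MS = 13.5, pooled variance = 1
        assert f_statistic([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1]) == pytest.approx(13.5)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=24)
            y = rng.integers(0, 3, size=24)
            if np.unique(y).size < 2:
                continue
            groups = [x[y == c] for c in np.unique(y)]
            expected = stats.f_oneway(*groups).statistic
            assert f_statistic(x, y) == pytest.approx(expected, rel=1e-10)

    def test_equals_squared_pooled_t_for_two_classes(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(size=30)
            y = (rng.random(30) < 0.5).astype(int)
            if np.unique(y).size < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
                continue
            t, _, _ = ttest_two_tailed(x[y == 1], x[y == 0], variant="student")
            assert f_statistic(x, y) == pytest.approx(t ** 2, rel=1e-8)

    def test_zero_pooled_variance_is_error(self):
        with pytest.raises(ValueError, match="pooled"):
            f_statistic([1, 1, 2, 2], [0, 0, 1, 1])


class TestPearson:
    def test_self_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # x=[1,2,3], y=[1,2,4]: r = 9 / (2 * sqrt(21))
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / (2 * np.sqrt(21)))

    def test_degenerate_vector_is_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson([1, 1, 1], [1, 2, 3])


def _fcq_oracle_selection(X, y, k, floor=1e-5):
    """Independent greedy FCQ re-evaluation using scipy primitives only."""
    n = X.shape[1]
    relevance = []
    for j in range(n):
        g1, g0 = X[y == 1, j], X[y == 0, j]
        t = stats.ttest_ind(g1, g0).statistic
        relevance.append(t ** 2)
    relevance = np.array(relevance)
    selected = [int(np.argmax(relevance))]
    for _ in range(1, k):
        best_score, best_j = -np.inf, None
        for j in range(n):
            if j in selected:
                continue
            corrs = [abs(stats.pearsonr(X[:, j], X[:, s]).statistic)
                     for s in selected]
            score = relevance[j] / max(np.mean(corrs), floor)
            if score > best_score + 1e-12:
                best_score, best_j = score, j
        selected.append(best_j)
    return selected


class TestMRMR:
    def test_k1_reduces_to_relevance_ranking(self, balanced_dataset):
        result = mrmr_select_fcq(balanced_dataset, k=1)
        sel = MRMRSelector(k=1).fit(balanced_dataset.values, balanced_dataset.labels)
        assert result.selected[0] == balanced_dataset.gene_ids[int(np.argmax(sel.relevance_))]

    def test_k_equals_n_selects_all(self, balanced_dataset):
        result = mrmr_select_fcq(balanced_dataset, k=balanced_dataset.n_genes)
        assert sorted(result.selected) == sorted(balanced_dataset.gene_ids)

    def test_duplicated_informative_gene_demoted(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 30 + [1] * 30)
        signal = rng.normal(0, 1, 60) + 2.0 * y
        X = np.column_stack([
            signal,
            signal + rng.normal(0, 0.01, 60),  # near-duplicate of column 0
            rng.normal(0, 1, 60) + 0.8 * y,
            rng.normal(0, 1, (60, 3)).reshape(60, 3)[:, 0],
            rng.normal(0, 1, 60),
            rng.normal(0, 1, 60),
        ])
        sel = MRMRSelector(k=3).fit(X, y)
        assert sel.selected_idx_[0] in (0, 1)
        # the near-duplicate is penalized by redundancy: second pick is not it
        assert sel.selected_idx_[1] not in (0, 1)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            n_genes = 8 + 3 * trial  # up to 20 genes
            y = np.array([0] * 20 + [1] * 20)
            X = rng.normal(0, 1, (40, n_genes))
            X[:, :3] += np.outer(y, rng.uniform(0.5, 2.0, 3))
            expected = _fcq_oracle_selection(X, y, k=5)
            sel = MRMRSelector(k=5).fit(X, y)
            assert list(sel.selected_idx_) == expected

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="single-class"):
            MRMRSelector(k=2).fit(X, np.zeros(10, dtype=int))

    def test_constant_gene_warns_and_gets_zero_relevance(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 10 + [1] * 10)
        X = np.column_stack([np.full(20, 2.0), rng.normal(size=20) + y])
        with pytest.warns(RuntimeWarning, match="constant"):
            sel = MRMRSelector(k=1).fit(X, y)
        assert sel.relevance_[0] == 0.0


class TestTTest:
    def test_identical_groups(self):
        t, df, p = ttest_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0) and p == pytest.approx(1)

    def test_swap_antisymmetry(self):
        x1, x0 = [6.0, 7, 8, 9], [5.0, 5, 6, 6]
        t, _, p = ttest_two_tailed(x1, x0)
        t2, _, p2 = ttest_two_tailed(x0, x1)
        assert t2 == pytest.approx(-t) and p2 == pytest.approx(p)

    @pytest.mark.parametrize("variant,equal_var", [("student", True), ("welch", False)])
    def test_matches_scipy_oracle(self, variant, equal_var):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x1 = rng.normal(0.3, 1.2, rng.integers(3, 20))
            x0 = rng.normal(0.0, 0.8, rng.integers(3, 20))
            t, df, p = ttest_two_tailed(x1, x0, variant=variant)
            ref = stats.ttest_ind(x1, x0, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)
            assert df == pytest.approx(ref.df, rel=1e-10)

    def test_summary_equals_raw(self):
        x1 = np.array([6.0, 7.0, 8.0, 9.0])
        x0 = np.array([5.0, 5.0, 6.0, 6.0])
        raw = ttest_two_tailed(x1, x0)
        summ = ttest_from_summary(x1.mean(), x1.std(ddof=1), 4,
                                  x0.mean(), x0.std(ddof=1), 4)
        assert raw == pytest.approx(summ)

    def test_reported_biomarker_row(self):
        # strongest screened biomarker: 6.8492 +/- 1.274 vs 5.9011 +/- 0.458
        t, df, p = ttest_from_summary(6.8492, 1.274, 176, 5.9011, 0.458, 176)
        assert t == pytest.approx(9.29, abs=0.01)
        assert df == 350
        assert p < 1e-4

    def test_doubling_n_decreases_p(self):
        _, _, p1 = ttest_from_summary(1.0, 1.0, 10, 0.5, 1.0, 10)
        _, _, p2 = ttest_from_summary(1.0, 1.0, 20, 0.5, 1.0, 20)
        assert p2 < p1

    def test_equal_constant_groups_defined(self):
        t, _, p = ttest_from_summary(2.0, 0.0, 5, 2.0, 0.0, 5)
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(ValueError, match="unequal means"):
            ttest_from_summary(2.0, 0.0, 5, 3.0, 0.0, 5)


class TestScreen:
    def test_alpha_zero_selects_nothing(self, balanced_dataset):
        _, selected = ttest_screen(balanced_dataset, alpha=0.0)
        assert selected == []

    def test_planted_genes_selected(self):
        from genefs.datasets import SyntheticSpec, generate_dataset, informative_gene_ids

        spec = SyntheticSpec(n_tumor=50, n_normal=50, n_genes=30, n_informative=3,
                             effect_sizes=(1.5, 1.5, 1.5), base_sd_range=(0.5, 0.5),
                             seed=13)
        ds = generate_dataset(spec)
        _, selected = ttest_screen(ds, alpha=0.05)
        assert set(informative_gene_ids(spec)) <= set(selected)

    def test_rows_in_input_order_and_flags_consistent(self, balanced_dataset):
        rows, selected = ttest_screen(balanced_dataset, alpha=0.05)
        assert [r.gene_id for r in rows] == balanced_dataset.gene_ids
        for row in rows:
            assert row.significant == (row.p_value < 0.05)
            assert 0 <= row.p_value <= 1
        assert selected == [r.gene_id for r in rows if r.significant]

    def test_selection_invariant_to_column_order(self, balanced_dataset):
        _, sel_fwd = ttest_screen(balanced_dataset)
        reversed_ds = balanced_dataset.select_genes(balanced_dataset.gene_ids[::-1])
        _, sel_rev = ttest_screen(reversed_ds)
        assert set(sel_fwd) == set(sel_rev)
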