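import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rotimb import (
    CVPlan,
    SyntheticSpec,
    average_ranks,
    fit_bagging,
    fit_c45_single,
    gen_gaussian,
    grid_to_table,
    make_folds,
    paired_t_test,
    render_summary,
    run_benchmark,
    significance_marks,
    summarize,
)
from rotimb.evaluation import A_BETTER, B_BETTER, NOT_SIG


@pytest.fixture
def cv_ds():
    return gen_gaussian(SyntheticSpec(30, 120, 4, separation=2.0, seed=21))


@pytest.fixture
def tiny_methods():
    return {
        "bagging": lambda tr, rng: fit_bagging(tr, M=5, rng=rng),
        "c45": lambda tr, rng: fit_c45_single(tr),
    }


class TestMakeFolds:
    def test_pairs_count_and_partition(self, cv_ds):
        plan = CVPlan(folds=10, repetitions=10, seed=0)
        pairs = make_folds(cv_ds, plan)
        assert len(pairs) == 100
        for rep in range(10):
            tests = np.concatenate([t for _, t in pairs[rep * 10 : (rep + 1) * 10]])
            np.testing.assert_array_equal(np.sort(tests), np.arange(cv_ds.n_examples))

    def test_train_test_disjoint_and_exhaustive(self, cv_ds):
        plan = CVPlan(folds=5, repetitions=2, seed=3)
        for train, test in make_folds(cv_ds, plan):
            assert set(train).isdisjoint(test)
            assert len(train) + len(test) == cv_ds.n_examples

    def test_stratified_proportions(self, cv_ds):
        plan = CVPlan(folds=10, repetitions=1, seed=1)
        expected_abnormal = cv_ds.n_abnormal / plan.folds
        for _, test in make_folds(cv_ds, plan):
            got = int(cv_ds.labels[test].sum())
            assert abs(got - expected_abnormal) <= 1

    def test_deterministic(self, cv_ds):
        plan = CVPlan(folds=10, repetitions=2, seed=5)
        a, b = make_folds(cv_ds, plan), make_folds(cv_ds, plan)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_too_few_examples_rejected(self, cv_ds):
        from rotimb import LabeledDataset

        tiny = LabeledDataset(
            features=np.zeros((5, 1)),
            labels=np.array([1, 0, 1, 0, 1]),
            feature_names=("x",),
        )
        with pytest.raises(ValueError):
            make_folds(tiny, CVPlan(folds=10, repetitions=1, seed=0))

    def test_small_minority_degrades_to_unstratified(self):
        ds = gen_gaussian(SyntheticSpec(4, 60, 3, separation=2.0, seed=2))
        with pytest.warns(UserWarning, match="unstratified"):
            pairs = make_folds(ds, CVPlan(folds=10, repetitions=1, seed=0))
        assert len(pairs) == 10


class TestRunBenchmark:
    def test_cardinality_and_ranges(self, cv_ds, tiny_methods):
        plan = CVPlan(folds=5, repetitions=2, seed=0)
        grid = run_benchmark(cv_ds, tiny_methods, plan)
        # 2 methods x 10 splits x 6 metrics
        assert len(grid) == 2 * 10 * 6
        values = grid["value"].dropna()
        assert ((values >= 0) & (values <= 1)).all()

    def test_bit_reproducible(self, cv_ds, tiny_methods):
        plan = CVPlan(folds=5, repetitions=2, seed=7)
        a = run_benchmark(cv_ds, tiny_methods, plan)
        b = run_benchmark(cv_ds, tiny_methods, plan)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_methods_rejected(self, cv_ds):
        with pytest.raises(ValueError):
            run_benchmark(cv_ds, {}, CVPlan(folds=5, repetitions=1, seed=0))


class TestPairedTTest:
    def test_identical_samples_not_significant(self):
        a = np.linspace(0, 1, 20)
        assert paired_t_test(a, a.copy()) == NOT_SIG

    def test_constant_offset_significant_by_convention(self):
        a = np.linspace(0, 0.4, 20)
        assert paired_t_test(a + 0.5, a) == A_BETTER
        assert paired_t_test(a, a + 0.5) == B_BETTER

    def test_textbook_decision_matches_t_distribution(self):
        # classic paired design: d has mean 1.0, sd ~1.15 over n=10
        b = np.array([12.1, 11.4, 13.2, 10.9, 12.8, 11.7, 12.4, 13.0, 11.2, 12.5])
        d = np.array([1.2, -0.4, 2.1, 0.8, 1.5, 0.3, 1.9, 2.2, -0.1, 0.5])
        a = b + d
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t_stat), df=len(d) - 1)
        expected = A_BETTER if p_ref < 0.05 else NOT_SIG
        assert paired_t_test(a, b) == expected
        assert p_ref < 0.05  # the fixture really is a significant case

    def test_direction_agrees_with_sign_flip_permutation(self):
        """The t decision should usually match an exact sign-flip test on the
        same paired differences (mean statistic, all 2^n assignments)."""
        rng = np.random.default_rng(404)
        n = 10
        signs = np.array(list(itertools.product([-1, 1], repeat=n)))
        agree = 0
        for _ in range(50):
            d = rng.normal(loc=rng.uniform(-0.5, 0.5), scale=1.0, size=n)
            a = rng.uniform(size=n)
            b = a - d
            outcome = paired_t_test(a, b)
            perm_means = (signs * d).mean(axis=1)
            perm_p = np.mean(np.abs(perm_means) >= abs(d.mean()) - 1e-12)
            perm_outcome = (
                (A_BETTER if d.mean() > 0 else B_BETTER) if perm_p < 0.05 else NOT_SIG
            )
            if outcome != NOT_SIG:
                # direction must always agree with the sign of the mean
                assert outcome == (A_BETTER if d.mean() > 0 else B_BETTER)
            agree += outcome == perm_outcome
        assert agree >= 45

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test(np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            paired_t_test(np.ones(3), np.ones(4))


class TestSignificanceMarks:
    def test_reference_excluded_and_identical_unmarked(self, cv_ds, tiny_methods):
        plan = CVPlan(folds=5, repetitions=2, seed=0)
        grid = run_benchmark(cv_ds, tiny_methods, plan)
        # duplicate one method's rows under a new name: identical values
        clone = grid[grid["method"] == "c45"].assign(method="c45_clone")
        marks = significance_marks(pd.concat([grid, clone]), reference="c45")
        assert not (marks["method"] == "c45").any()
        clone_marks = marks[marks["method"] == "c45_clone"]["mark"]
        assert (clone_marks == "none").all()

    def test_mark_count_bound(self, cv_ds, tiny_methods):
        plan = CVPlan(folds=5, repetitions=2, seed=0)
        grid = run_benchmark(cv_ds, tiny_methods, plan)
        marks = significance_marks(grid, reference="bagging")
        n_metrics = grid["metric"].nunique()
        assert len(marks) == 1 * n_metrics  # (#methods - 1) x #metrics x #datasets

    def test_unknown_reference_rejected(self, cv_ds, tiny_methods):
        grid = run_benchmark(cv_ds, tiny_methods, CVPlan(folds=5, repetitions=1, seed=0))
        with pytest.raises(ValueError):
            significance_marks(grid, reference="nope")


class TestAverageRanks:
    def test_benchmark_row_example(self):
        scores = pd.DataFrame(
            [[0.5917, 0.2975, 0.4476, 0.4522, 0.2433, 0.2471]],
            index=["d1"],
            columns=["ert", "rurf", "easyensemble", "balancecascade", "bagging", "c45"],
        )
        table = average_ranks(scores, higher_is_better=True)
        assert table.ranks.loc["d1"].tolist() == [1.0, 4.0, 3.0, 2.0, 6.0, 5.0]

    def test_ties_get_average_rank(self):
        scores = pd.DataFrame(
            [[0.5300, 0.2300, 0.3000, 0.3000, 0.2900, 0.2800]],
            index=["d5"],
            columns=list("abcdef"),
        )
        ranks = average_ranks(scores).ranks.loc["d5"]
        assert ranks["c"] == 2.5
        assert ranks["d"] == 2.5

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        n_datasets=st.integers(1, 6),
        n_methods=st.integers(2, 7),
        seed=st.integers(0, 10_000),
    )
    def test_ranks_sum_invariant(self, n_datasets, n_methods, seed):
        rng = np.random.default_rng(seed)
        # low-resolution values force frequent ties
        values = rng.integers(0, 4, size=(n_datasets, n_methods)) / 4.0
        table = average_ranks(pd.DataFrame(values))
        expected = n_methods * (n_methods + 1) / 2
        np.testing.assert_allclose(table.ranks.sum(axis=1), expected)

    def test_missing_values_rejected(self):
        values = pd.DataFrame([[0.1, np.nan]], columns=["a", "b"])
        with pytest.raises(ValueError):
            average_ranks(values)


class TestSummarize:
    def test_constant_grid(self):
        rows = [
            {"dataset": "d", "method": "m", "repetition": r, "fold": f,
             "metric": "recall", "value": 0.75}
            for r in range(2)
            for f in range(3)
        ]
        out = summarize(pd.DataFrame(rows))
        cell = out[(out["dataset"] == "d")].iloc[0]
        assert cell["mean"] == 0.75
        assert cell["sd"] == 0.0
        avg = out[out["dataset"] == "average"].iloc[0]
        assert avg["mean"] == 0.75

    def test_average_is_unweighted_over_datasets(self):
        rows = []
        for dataset, value in [("d1", 0.2), ("d2", 0.8)]:
            for f in range(2):
                rows.append(
                    {"dataset": dataset, "method": "m", "repetition": 0, "fold": f,
                     "metric": "recall", "value": value}
                )
        out = summarize(pd.DataFrame(rows))
        avg = out[out["dataset"] == "average"].iloc[0]
        assert avg["mean"] == pytest.approx(0.5)

    def test_grid_to_table_and_render(self, cv_ds, tiny_methods):
        grid = run_benchmark(cv_ds, tiny_methods, CVPlan(folds=5, repetitions=1, seed=0))
        table = grid_to_table(grid, "recall")
        assert set(table.columns) == {"bagging", "c45"}
        text = render_summary(grid, "recall", reference="bagging")
        assert "bagging" in text and "average" in text
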