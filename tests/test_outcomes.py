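"""Outcome definitions and performance metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pltrecon import (
    auroc,
    bootstrap_auroc_ci,
    classify_thrombocytopenia,
    crossvalidate,
    engraftment_day,
    mean_relative_deviation,
)


class TestThrombocytopenia:
    def test_all_below_threshold(self):
        t = np.arange(100.0, 112.0)
        assert classify_thrombocytopenia(t, np.full(12, 74.0)) is True

    def test_boundary_is_strict(self):
        t = np.arange(100.0, 112.0)
        assert classify_thrombocytopenia(t, np.full(12, 75.0)) is False

    def test_only_last_twelve_count(self):
        t = np.arange(50.0, 70.0)  # 20 in-window values
        v = np.concatenate([np.full(8, 40.0), np.full(12, 100.0)])
        assert classify_thrombocytopenia(t, v) is False

    def test_empty_window_is_undefined(self):
        assert classify_thrombocytopenia([5.0, 10.0], [50.0, 50.0]) is None

    def test_fewer_than_twelve_uses_available(self):
        assert classify_thrombocytopenia([40.0, 50.0], [60.0, 70.0]) is True

    def test_pre_window_values_ignored(self):
        t = np.array([10.0, 100.0])
        v = np.array([5.0, 200.0])
        assert classify_thrombocytopenia(t, v) is False


class TestEngraftment:
    def test_recovered_from_day_ten(self):
        days = np.arange(0, 30)
        v = np.where(days >= 10, 25.0, 5.0)
        assert engraftment_day(days, v) == 10

    def test_broken_run_postponed(self):
        """21, 19, 22, 23, 24 from day 5: the first sustained run starts day 7."""
        assert engraftment_day([5, 6, 7, 8, 9], [21, 19, 22, 23, 24]) == 7

    def test_never_engrafts(self):
        days = np.arange(0, 20)
        assert engraftment_day(days, np.full(20, 10.0)) is None

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        days = np.arange(0, 40)
        for _ in range(50):
            v = rng.uniform(0.0, 40.0, days.size)
            expected = None
            for i in range(days.size - 2):
                if v[i] >= 20 and v[i + 1] >= 20 and v[i + 2] >= 20:
                    expected = int(days[i])
                    break
            assert engraftment_day(days, v) == expected

    def test_gapped_series_rejected(self):
        with pytest.raises(ValueError):
            engraftment_day([0, 1, 3, 4, 5], [25, 25, 25, 25, 25])

    def test_start_day_restricts_scan(self):
        days = np.arange(0, 10)
        v = np.array([30, 30, 30, 5, 5, 5, 25, 25, 25, 25.0])
        assert engraftment_day(days, v) == 0
        assert engraftment_day(days, v, start_day=3) == 6


class TestMeanRelativeDeviation:
    def test_perfect_prediction(self):
        assert mean_relative_deviation([10.0, 20.0], [10.0, 20.0]) == 0.0

    def test_double_prediction(self):
        assert mean_relative_deviation([20.0, 40.0], [10.0, 20.0]) == 1.0

    def test_hand_computed_mixture(self):
        assert mean_relative_deviation([50.0, 100.0], [100.0, 100.0]) == 0.25

    def test_zero_observed_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-valued"):
            v = mean_relative_deviation([50.0, 100.0], [0.0, 100.0])
        assert v == 0.0


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_uninformative_scores(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert auroc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_counting_oracle(self):
        """Exhaustive pair counting (ties = 1/2) on small random sets."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = 8
            scores = rng.integers(0, 4, n).astype(float)  # forces ties
            labels = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum(
                1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
            )
            oracle = wins / (pos.size * neg.size)
            assert auroc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1.0, 2.0], [1, 1])

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        if labels.all() or not labels.any():
            return
        transformed = np.exp(scale * scores) + shift
        assert auroc(transformed, labels) == pytest.approx(
            auroc(scores, labels), abs=1e-12
        )


class TestBootstrapCI:
    @pytest.fixture(scope="class")
    def scored(self):
        rng = np.random.default_rng(23)
        labels = rng.random(120) < 0.4
        scores = rng.normal(size=120) + labels  # informative but noisy
        return scores, labels

    def test_seed_reproducible(self, scored):
        scores, labels = scored
        a = bootstrap_auroc_ci(scores, labels, n_boot=200, seed=9)
        b = bootstrap_auroc_ci(scores, labels, n_boot=200, seed=9)
        assert a == b

    def test_contains_point_estimate(self, scored):
        scores, labels = scored
        lo, hi = bootstrap_auroc_ci(scores, labels, n_boot=500, seed=1)
        assert lo <= auroc(scores, labels) <= hi

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(31)
        widths = []
        for n in (60, 600):
            labels = rng.random(n) < 0.4
            scores = rng.normal(size=n) + labels
            lo, hi = bootstrap_auroc_ci(scores, labels, n_boot=400, seed=2)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestCrossvalidation:
    def test_identical_subjects_identical_folds(self, pop, small_cohort):
        """Clones of one subject in every fold give identical fold metrics."""
        import copy

        base = small_cohort[0]
        clones = []
        for i in range(6):
            c = copy.copy(base)
            c.subject_id = f"C{i}"
            clones.append(c)
        # metric degenerate (single class) -> flagged NaN rows, same in each fold
        table = crossvalidate(clones, pop, n_folds=3, seed=0, cutoffs=(7,), n_boot=50)
        assert len(table) == 3
        assert table["n"].sum() == 6
        assert table["auroc"].isna().all()  # single-class folds are flagged

    def test_reseeding_preserves_pooled_counts(self, pop, small_cohort):
        t1 = crossvalidate(small_cohort, pop, n_folds=3, seed=1, cutoffs=(7,), n_boot=20)
        t2 = crossvalidate(small_cohort, pop, n_folds=3, seed=2, cutoffs=(7,), n_boot=20)
        assert t1["n"].sum() == t2["n"].sum()
        assert (
            t1["n_thrombocytopenia"].sum() == t2["n_thrombocytopenia"].sum()
        )
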