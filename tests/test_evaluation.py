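"""Cross-validation design, classification metrics, and paired testing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from era3d import evaluation as ev
from era3d.annotator import CONTROL, PAF


def toy_subjects(n_control=55, n_paf=10):
    labels = {f"C{i}": CONTROL for i in range(n_control)}
    labels.update({f"P{i}": PAF for i in range(n_paf)})
    return labels


class TestStratifiedSplit:
    def test_default_cohort_leaves_7_and_3(self):
        cfg = ev.CVConfig(n_runs=1)
        train, test = ev.stratified_split(toy_subjects(), cfg, 0)
        assert len(train) == 55
        test_classes = [toy_subjects()[s] for s in test]
        assert test_classes.count(CONTROL) == 7
        assert test_classes.count(PAF) == 3

    def test_same_seed_same_split(self):
        cfg = ev.CVConfig(n_runs=1)
        assert ev.stratified_split(toy_subjects(), cfg, 42) == ev.stratified_split(
            toy_subjects(), cfg, 42
        )

    def test_partitions_disjoint_and_exhaustive(self):
        cfg = ev.CVConfig(n_runs=1)
        train, test = ev.stratified_split(toy_subjects(), cfg, 7)
        assert set(train) & set(test) == set()
        assert set(train) | set(test) == set(toy_subjects())

    def test_insufficient_cohort_rejected(self):
        cfg = ev.CVConfig(n_runs=1)
        with pytest.raises(ValueError):
            ev.stratified_split(toy_subjects(n_control=48, n_paf=10), cfg, 0)


class TestConfusionRates:
    def test_example(self):
        tpr, tnr = ev.confusion_rates(
            np.array([PAF, CONTROL, CONTROL, CONTROL], dtype=object),
            np.array([PAF, PAF, CONTROL, CONTROL], dtype=object),
        )
        assert (tpr, tnr) == (0.5, 1.0)

    def test_all_correct(self):
        y = np.array([PAF, CONTROL] * 3, dtype=object)
        assert ev.confusion_rates(y, y) == (1.0, 1.0)

    def test_absent_class_gives_nan(self):
        preds = np.array([PAF, PAF], dtype=object)
        truths = np.array([PAF, PAF], dtype=object)
        tpr, tnr = ev.confusion_rates(preds, truths)
        assert tpr == 1.0 and math.isnan(tnr)

    def test_matches_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            truths = rng.choice(np.array([CONTROL, PAF], dtype=object), size=n)
            preds = rng.choice(np.array([CONTROL, PAF], dtype=object), size=n)
            if len(np.unique(truths)) < 2:
                continue
            tp = np.sum((preds == PAF) & (truths == PAF))
            fn = np.sum((preds == CONTROL) & (truths == PAF))
            tn = np.sum((preds == CONTROL) & (truths == CONTROL))
            fp = np.sum((preds == PAF) & (truths == CONTROL))
            tpr, tnr = ev.confusion_rates(preds, truths)
            assert tpr == pytest.approx(tp / (tp + fn))
            assert tnr == pytest.approx(tn / (tn + fp))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        truths = np.array([PAF, PAF, CONTROL, CONTROL], dtype=object)
        assert ev.roc_auc(scores, truths) == 1.0

    def test_all_tied_scores(self):
        scores = np.full(6, 0.5)
        truths = np.array([PAF, CONTROL] * 3, dtype=object)
        assert ev.roc_auc(scores, truths) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc(np.array([0.1, 0.2]), np.array([PAF, PAF], dtype=object))

    def test_matches_pair_counting_oracle_and_sklearn(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            truths = rng.choice(np.array([CONTROL, PAF], dtype=object), size=n)
            if len(np.unique(truths)) < 2:
                continue
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)  # force ties
            pos, neg = scores[truths == PAF], scores[truths == CONTROL]
            pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
            expected = float(np.mean(pairs))
            assert ev.roc_auc(scores, truths) == pytest.approx(expected)
            assert ev.roc_auc(scores, truths) == pytest.approx(
                roc_auc_score((truths == PAF).astype(int), scores)
            )


class TestSummarize:
    def test_constant_values(self):
        s = ev.summarize([0.5] * 20)
        assert (s.mean, s.plus, s.minus) == (0.5, 0.0, 0.0)

    def test_uniform_grid_percentiles(self):
        s = ev.summarize(np.linspace(0, 1, 1001))
        assert s.p2_5 == pytest.approx(0.025)
        assert s.p97_5 == pytest.approx(0.975)

    def test_mean_of_extremes(self):
        assert ev.summarize([0.0, 1.0]).mean == 0.5

    def test_nans_excluded(self):
        s = ev.summarize([0.4, float("nan"), 0.6])
        assert s.mean == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.summarize([float("nan")])


def enumeration_p_value(d):
    """Literal 2^n sign-flip enumeration of the two-sided Wilcoxon p."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        np.sum(ranks[np.array(signs, dtype=bool)])
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    w_all = np.asarray(w_all)
    tol = 1e-9
    p_le = np.mean(w_all <= w_obs + tol)
    p_ge = np.mean(w_all >= w_obs - tol)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_six_positive_differences(self):
        a = np.arange(1.0, 7.0)
        b = a - np.array([0.3, 0.5, 0.9, 1.1, 2.0, 0.7])
        assert ev.wilcoxon_signed_rank(a, b) == pytest.approx(2 / 64)

    def test_identical_samples_degenerate(self):
        a = np.arange(10.0)
        with pytest.raises(ValueError):
            ev.wilcoxon_signed_rank(a, a)

    def test_too_few_nonzero_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, 4.5])
        with pytest.raises(ValueError):
            ev.wilcoxon_signed_rank(a, b)

    @pytest.mark.parametrize("n", [5, 6, 8, 10])
    def test_matches_full_enumeration(self, n, rng):
        for _ in range(20):
            d = np.round(rng.normal(size=n), 1)
            d[d == 0] = 0.1
            if rng.random() < 0.3:
                d[: n // 2] = np.abs(d[: n // 2])  # induce rank ties sometimes
            p = ev.wilcoxon_signed_rank(d, np.zeros(n))
            assert p == pytest.approx(enumeration_p_value(d), abs=1e-12)

    def test_exact_agrees_with_scipy(self, rng):
        d = rng.normal(size=20)
        p = ev.wilcoxon_signed_rank(d, np.zeros(20))
        p_scipy = sps.wilcoxon(d, alternative="two-sided", mode="exact").pvalue
        assert p == pytest.approx(p_scipy, rel=1e-9)

    def test_normal_approximation_close_to_scipy(self, rng):
        d = rng.normal(size=40)
        p = ev.wilcoxon_signed_rank(d, np.zeros(40))
        p_scipy = sps.wilcoxon(
            d, alternative="two-sided", mode="approx", correction=True
        ).pvalue
        assert p == pytest.approx(p_scipy, rel=0.05)


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "base, improved, expected", [(0.5, 0.6, 20.0), (0.7, 0.7, 0.0), (0.8, 0.72, -10.0)]
    )
    def test_examples(self, base, improved, expected):
        assert ev.percent_increase(base, improved) == pytest.approx(expected)

    def test_zero_baseline_missing(self):
        assert math.isnan(ev.percent_increase(0.0, 0.5))


@pytest.fixture(scope="module")
def toy_result(small_cohort):
    cfg = ev.CVConfig(
        n_runs=10, n_train_control=6, n_train_paf=2,
        k_grid=(3, 5), feature_sets=("RR_QT", "RR_QT_TQ"), master_seed=9,
    )
    return ev.run_cv(small_cohort, cfg, collect_subject_scores=True), cfg


class TestRunCV:
    def test_complete_metric_grid(self, toy_result):
        result, cfg = toy_result
        m = result.metrics
        expected = cfg.n_runs * len(cfg.k_grid) * len(cfg.feature_sets) * 2
        assert len(m) == expected
        combos = m.groupby(["run_id", "k", "feature_set", "level"]).size()
        assert (combos == 1).all()
        assert m[["tpr", "tnr", "auc"]].stack().dropna().between(0, 1).all()

    def test_subject_scores_cover_test_subjects(self, toy_result):
        result, cfg = toy_result
        scores = result.subject_scores
        per_run = scores.groupby(["run_id", "k", "feature_set"])["subject_id"].nunique()
        assert (per_run == 4).all()  # 2 held-out controls + 2 held-out PAF

    def test_too_many_runs_rejected(self, small_cohort):
        # C(8,6) * C(4,2) = 28 * 6 = 168 distinct training combinations
        cfg = ev.CVConfig(
            n_runs=169, n_train_control=6, n_train_paf=2,
            k_grid=(3,), feature_sets=("RR_QT",), master_seed=0,
        )
        with pytest.raises(ValueError, match="distinct"):
            ev.run_cv(small_cohort, cfg)

    def test_deterministic_given_master_seed(self, small_cohort):
        cfg = ev.CVConfig(
            n_runs=4, n_train_control=6, n_train_paf=2,
            k_grid=(3,), feature_sets=("RR_QT_TQ",), master_seed=77,
        )
        a = ev.run_cv(small_cohort, cfg).metrics
        b = ev.run_cv(small_cohort, cfg).metrics
        pd.testing.assert_frame_equal(a, b)


def test_summarize_runs_shape(small_cohort):
    cfg = ev.CVConfig(
        n_runs=5, n_train_control=6, n_train_paf=2,
        k_grid=(3, 5), feature_sets=("RR_QT",), master_seed=3,
    )
    summary = ev.summarize_runs(ev.run_cv(small_cohort, cfg).metrics)
    assert len(summary) == 2 * 2 * 3  # k x level x metric
    assert (summary["p2_5"] <= summary["mean"] + 1e-12).all()
    assert (summary["mean"] <= summary["p97_5"] + 1e-12).all()
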