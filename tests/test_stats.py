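"""ROC/Youden/contingency/correlation/regression statistics and the
over-optimism corrected AUROC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from cfscreen.reconstructed import TABLE_STRATA_COUNTS, cfdna_category_cohort, strata_cohort
from cfscreen.stats import (
    OptimismCorrectedAUC,
    YoudenCutoffClassifier,
    auroc,
    chi_square_2x2,
    cohort_frame,
    confusion_at_threshold,
    corrected_auroc,
    ols_regression,
    pearson_ci,
    pearson_ci_from_r,
    stratified_pv,
    youden_threshold,
)


def brute_force_auroc(scores, labels):
    """All-pairs concordance count: the independent oracle."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive scan over observed values and +inf (equivalent to -inf
    plus observed: the minimum observed cutoff already labels everyone
    positive)."""
    best = (-np.inf, np.inf)
    for cut in sorted(set(scores)) + [np.inf]:
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= cut)
        fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= cut)
        n1 = sum(labels)
        n0 = len(labels) - n1
        j = tp / n1 + (n0 - fp) / n0 - 1.0
        if j > best[0] + 1e-12:
            best = (j, cut)
    return best


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((1, 2, 3, 4), (0, 0, 1, 1), 1.0),
            ((1, 2, 3, 4), (0, 1, 0, 1), 0.75),
            ((1, 1), (0, 1), 0.5),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auroc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2, 3], [1, 1, 1])

    @given(
        scores=st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=50),
        data=st.data(),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_pair_counting(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels))

    def test_matches_reference_roc_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, size=60)
            if y.min() == y.max():
                continue
            s = rng.normal(size=60) + y
            assert auroc(s, y) == pytest.approx(roc_auc_score(y, s))

    @given(scores=st.lists(st.integers(min_value=-50, max_value=50), min_size=4, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, scores):
        labels = [i % 2 for i in range(len(scores))]
        transformed = [math.exp(s / 25.0) for s in scores]
        assert auroc(transformed, labels) == pytest.approx(auroc(scores, labels))


class TestYouden:
    def test_reconstructed_cohort_sensitivity_specificity(self):
        frame = cohort_frame(cfdna_category_cohort())
        perf = confusion_at_threshold(frame["cfdna_ng_ml"], frame["is_cancer"], 3.15)
        assert (perf.tp, perf.fn) == (23, 6)
        assert (perf.tn, perf.fp) == (71, 37)
        assert perf.sensitivity == pytest.approx(23 / 29)
        assert perf.specificity == pytest.approx(71 / 108)
        # and the scan itself selects the published cutoff
        chosen = youden_threshold(frame["cfdna_ng_ml"], frame["is_cancer"])
        assert chosen.cutoff == pytest.approx(3.15)

    def test_perfect_separation(self):
        perf = youden_threshold([1, 2, 10, 11], [0, 0, 1, 1])
        assert perf.youden_j == pytest.approx(1.0)
        assert perf.cutoff == pytest.approx(10)  # smallest positive-class score

    @given(
        scores=st.lists(st.integers(min_value=0, max_value=10), min_size=4, max_size=40),
        data=st.data(),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_exhaustive_scan(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        j_best, cut_best = brute_force_youden(scores, labels)
        perf = youden_threshold(scores, labels)
        assert perf.youden_j == pytest.approx(j_best)
        assert perf.cutoff == pytest.approx(cut_best)

    @given(
        scores=st.lists(
            st.floats(min_value=-100, max_value=100), min_size=6, max_size=30, unique=True
        ),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_j_invariant_under_label_swap_with_negated_scores(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        j_orig = youden_threshold(scores, labels).youden_j
        j_flip = youden_threshold([-s for s in scores], [1 - y for y in labels]).youden_j
        assert j_flip == pytest.approx(j_orig)

    def test_estimator_interface(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        est = YoudenCutoffClassifier().fit(X, y)
        assert est.cutoff_ == pytest.approx(3.0)
        assert list(est.predict(np.array([[2.9], [3.0]]))) == [0, 1]
        cloned = clone(est)  # sklearn contract: params survive cloning
        assert isinstance(cloned, YoudenCutoffClassifier)
        assert est.score(X, y) == pytest.approx(1.0)


class TestConfusionAtThreshold:
    def test_incident_group_sensitivity(self):
        scores = [5.0] * 4 + [3.15] * 5 + [2.0] * 3  # 9 of 12 at/above cut
        labels = [1] * 12
        pos = sum(s >= 3.15 for s in scores)
        assert pos / 12 == pytest.approx(0.75)
        # against benign controls the full confusion works out
        frame = cohort_frame(cfdna_category_cohort())
        inc = frame[frame["outcome"].isin(["benign", "incident_lc"])]
        perf = confusion_at_threshold(inc["cfdna_ng_ml"], inc["is_cancer"], 3.15)
        assert perf.sensitivity == pytest.approx(9 / 12)
        assert perf.fp / (perf.fp + perf.tn) == pytest.approx(37 / 108)

    def test_cutoff_below_minimum(self):
        perf = confusion_at_threshold([1, 2, 3, 4], [0, 1, 0, 1], 0.0)
        assert perf.sensitivity == 1.0
        assert perf.specificity == 0.0


class TestStratifiedPv:
    @pytest.mark.parametrize("stratifier", sorted(TABLE_STRATA_COUNTS))
    def test_published_counts_reproduced(self, stratifier):
        table = stratified_pv(strata_cohort(stratifier), stratifier)
        for stratum, (bb, cb, ba, ca) in TABLE_STRATA_COUNTS[stratifier].items():
            row = table.rows[stratum]
            assert (
                row["benign_below"],
                row["cancer_below"],
                row["benign_above"],
                row["cancer_above"],
            ) == (bb, cb, ba, ca)

    def test_published_size_npv_ppv(self):
        table = stratified_pv(strata_cohort("size_class"), "size_class")
        assert table.rows["<6"]["npv"] == pytest.approx(41 / 42)
        assert table.rows["<6"]["ppv"] == pytest.approx(5 / 24)
        assert table.rows[">=15"]["npv"] == pytest.approx(4 / 6)
        assert table.rows[">=15"]["ppv"] == pytest.approx(10 / 11)

    def test_margins_equal_whole_cohort_confusion(self):
        records = strata_cohort("size_class")
        frame = cohort_frame(records)
        perf = confusion_at_threshold(frame["cfdna_ng_ml"], frame["is_cancer"], 3.15)
        bb, cb, ba, ca = stratified_pv(records, "size_class").margin_counts()
        assert (bb, cb, ba, ca) == (perf.tn, perf.fn, perf.fp, perf.tp)

    def test_all_benign_stratum(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "cfdna_ng_ml": [1.0, 4.0, 4.5],
                "is_cancer": [0, 0, 0],
                "size_class": ["<6"] * 3,
            }
        )
        row = stratified_pv(frame, "size_class").rows["<6"]
        assert row["npv"] == 1.0
        assert row["ppv"] == 0.0

    def test_empty_stratum_reports_missing(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"cfdna_ng_ml": [1.0, 4.0], "is_cancer": [0, 1], "size_class": ["<6"] * 2}
        )
        row = stratified_pv(frame, "size_class").rows[">=15"]
        assert row["npv"] is None and row["ppv"] is None


class TestChiSquare:
    def test_published_incident_comparison(self):
        res = chi_square_2x2([[9, 3], [37, 71]])
        assert res.p_value == pytest.approx(0.006, abs=5e-4)

    def test_hand_computed_statistic(self):
        # independent evaluation of sum (O-E)^2/E without correction
        table = np.array([[9, 3], [37, 71]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert chi_square_2x2(table).chi2_stat == pytest.approx(chi2)
        assert chi2 == pytest.approx(7.583, abs=1e-3)

    def test_identical_proportions(self):
        res = chi_square_2x2([[10, 10], [20, 20]])
        assert res.chi2_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        t = [[5, 11], [19, 2]]
        tt = [list(row) for row in zip(*t)]
        assert chi_square_2x2(t).chi2_stat == pytest.approx(chi_square_2x2(tt).chi2_stat)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 7]])


class TestPearsonCi:
    def test_published_vdt_interval(self):
        ci = pearson_ci_from_r(-0.77, 14)
        assert round(ci.ci_lo, 2) == -0.92
        assert round(ci.ci_hi, 2) == -0.40

    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_ci(x, x).r == pytest.approx(1.0)
        assert pearson_ci(x, -x).r == pytest.approx(-1.0)

    def test_interval_shrinks_with_n(self):
        widths = [
            pearson_ci_from_r(0.5, n).ci_hi - pearson_ci_from_r(0.5, n).ci_lo
            for n in (5, 10, 50, 500)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci(np.ones(10), np.arange(10.0))


class TestOls:
    def test_exact_line(self):
        x = np.arange(6.0)
        res = ols_regression(2 * x + 1, x)
        assert res.params == pytest.approx([1.0, 2.0])
        assert np.abs(res.resid).max() < 1e-10

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        res = ols_regression(y, X)
        Xc = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        assert res.params == pytest.approx(beta)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            ols_regression(np.arange(10.0), X)

    def test_recovers_simulated_cfdna_effect(self):
        # vdt = a + b*ln(cfdna) + c*size + noise at n = 5000
        rng = np.random.default_rng(9)
        ln_cf = rng.normal(1.0, 1.0, size=5000)
        size = rng.uniform(4, 20, size=5000)
        true_b = -60.0
        y = 250.0 + true_b * ln_cf + 1.5 * size + rng.normal(0, 40, size=5000)
        res = ols_regression(y, np.column_stack([ln_cf, size]), names=("ln_cf", "size"))
        b_hat = res.params[1]
        se = res.bse[1]
        assert abs(b_hat - true_b) < 3 * se


class TestCorrectedAuroc:
    def test_perfect_separation_survives_any_split(self):
        s = np.concatenate([np.zeros(100), np.ones(100)])
        res = corrected_auroc(s, s.astype(int), seed=1)
        assert res.corrected_auc == pytest.approx(1.0)
        assert (res.interval_lo, res.interval_hi) == (1.0, 1.0)

    def test_null_scores_concentrate_at_half(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(400)
        y = np.repeat([0, 1], 200)
        res = corrected_auroc(x, y, seed=12)
        assert res.corrected_auc == pytest.approx(0.5, abs=0.03)

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(120) + np.repeat([0.0, 1.0], 60)
        res = corrected_auroc(x, np.repeat([0, 1], 60), seed=4)
        assert res.interval_lo <= res.corrected_auc <= res.interval_hi
        assert 0.0 <= res.interval_lo <= res.interval_hi <= 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(80)
        y = np.repeat([0, 1], 40)
        a = corrected_auroc(x, y, seed=99)
        b = corrected_auroc(x, y, seed=99)
        assert a == b

    def test_univariate_correction_invariant_to_affine_rescaling(self):
        # rescaling a single marker leaves the fitted linear predictor's
        # ranking unchanged, so every replicate AUROC is identical
        rng = np.random.default_rng(21)
        x = rng.standard_normal(60) + np.repeat([0.0, 0.8], 30)
        y = np.repeat([0, 1], 30)
        a = OptimismCorrectedAUC(n_replications=20, random_state=7).fit(x, y)
        b = OptimismCorrectedAUC(n_replications=20, random_state=7).fit(5.0 * x - 3.0, y)
        assert np.allclose(a.replicate_aucs_, b.replicate_aucs_)
        assert a.corrected_auc_ == pytest.approx(b.corrected_auc_)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            corrected_auroc(np.arange(5.0), [0, 0, 0, 0, 1], seed=0)

    def test_estimator_params_roundtrip(self):
        est = OptimismCorrectedAUC(n_replications=17, random_state=5)
        assert clone(est).get_params() == est.get_params()
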