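"""Frame-wise accuracy, concordance, interrater agreement, cohort statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from smmkit.inference import FrameScoreSeries
from smmkit.metrics import (
    ConfusionCounts,
    accuracy_from_confusion,
    aggregate_accuracy,
    agreement,
    concordance,
    framewise_confusion,
    lin_ccc,
    mann_whitney,
    pr_sweep,
    stratified_confusion_sample,
    two_sample_t,
    union_relabel,
    yates_chi_square,
)


class TestConfusion:
    def test_perfect_and_inverted_predictions(self):
        t = np.array([1, 1, 0, 0, 1], dtype=bool)
        perfect = framewise_confusion(t, t)
        assert perfect.fp == perfect.fn == 0
        inverted = framewise_confusion(~t, t)
        assert inverted.tp == inverted.tn == 0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(17)
        pred = rng.random(1000) < 0.3
        true = rng.random(1000) < 0.1
        c = framewise_confusion(pred, true)
        tp = fp = tn = fn = 0  # independent element-wise scan
        for p, t in zip(pred, true):
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert c.n == 1000

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            framewise_confusion(np.zeros(5, bool), np.zeros(6, bool))


class TestAccuracy:
    def test_direct_ratios(self):
        a = accuracy_from_confusion(ConfusionCounts(tp=90, fp=10, tn=880, fn=20))
        assert a.precision == pytest.approx(0.9)
        assert a.recall == pytest.approx(90 / 110)
        assert a.specificity == pytest.approx(880 / 890)
        assert a.npv == pytest.approx(880 / 900)

    def test_undefined_metrics_flagged_not_crashed(self):
        a = accuracy_from_confusion(ConfusionCounts(tp=0, fp=5, tn=10, fn=0))
        assert not a.defined("recall")
        assert a.defined("precision")

    def test_all_true_positives(self):
        a = accuracy_from_confusion(ConfusionCounts(tp=50, fp=0, tn=0, fn=0))
        assert a.precision == 1.0 and a.recall == 1.0

    def test_sem_ci_brackets_mean(self):
        per = [
            ConfusionCounts(90, 10, 880, 20),
            ConfusionCounts(80, 20, 890, 10),
            ConfusionCounts(85, 15, 885, 15),
        ]
        agg = aggregate_accuracy(per)
        lo, hi = agg.ci["precision"]
        vals = [accuracy_from_confusion(c).precision for c in per]
        assert lo <= np.mean(vals) <= hi


class TestPRSweep:
    def test_constant_scores_identical_across_grid(self):
        s = FrameScoreSeries(np.ones(100))
        true = np.zeros(100, bool)
        true[:40] = True
        results = pr_sweep(s, true, grid=[0.5, 0.7, 0.9])
        precisions = {round(a.precision, 12) for _, a in results}
        assert len(precisions) == 1

    def test_recall_non_increasing(self):
        rng = np.random.default_rng(18)
        scores = np.convolve(rng.uniform(0, 1, 3000), np.ones(30) / 30, mode="same")
        scores = (scores - scores.min()) / np.ptp(scores)
        true = scores > np.quantile(scores, 0.8)
        recalls = [a.recall for _, a in pr_sweep(FrameScoreSeries(scores), true)]
        assert all(b <= a + 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_hand_built_ten_frame_example(self):
        scores = np.array([0.1, 0.6, 0.6, 0.9, 0.9, 0.2, 0.7, 0.95, 0.95, 0.3])
        true = np.array([0, 0, 1, 1, 1, 0, 0, 1, 1, 0], dtype=bool)
        for theta, acc in pr_sweep(FrameScoreSeries(scores), true, grid=[0.5, 0.85]):
            pred = scores >= theta
            tp = int((pred & true).sum())
            assert acc.precision == pytest.approx(tp / pred.sum())
            assert acc.recall == pytest.approx(tp / true.sum())


class TestConcordance:
    def test_identity_gives_all_ones(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r = concordance(x, x, n_boot=50, seed=0)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.spearman_rho == pytest.approx(1.0)
        assert r.ccc == pytest.approx(1.0)

    def test_lin_formula_population_moments(self):
        r = concordance([1, 2, 3], [2, 4, 6], n_boot=50, seed=0)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.ccc == pytest.approx(8 / 22)

    def test_ccc_equals_moment_identity(self):
        # CCC = 2 r sx sy / (sx^2 + sy^2 + (mx - my)^2), an independent route
        rng = np.random.default_rng(19)
        for _ in range(50):
            x = rng.normal(size=12)
            y = 0.5 * x + rng.normal(size=12)
            r = sps.pearsonr(x, y).statistic
            sx, sy = x.std(), y.std()
            expected = 2 * r * sx * sy / (sx**2 + sy**2 + (x.mean() - y.mean()) ** 2)
            assert lin_ccc(x, y) == pytest.approx(expected)
            assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12  # Lin's inequality

    def test_shuffled_pairs_average_to_zero(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=30)
        rs = []
        for _ in range(100):
            y = rng.permutation(x)
            rs.append(concordance(x, y, n_boot=0, seed=0).pearson_r)
        assert abs(np.mean(rs)) <= 0.1

    def test_bootstrap_ci_brackets_r_and_is_seeded(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=24)
        y = x + rng.normal(scale=0.5, size=24)
        r1 = concordance(x, y, seed=5)
        r2 = concordance(x, y, seed=5)
        assert r1.r_ci == r2.r_ci
        assert r1.r_ci[0] <= r1.pearson_r <= r1.r_ci[1]

    def test_zero_variance_flagged(self):
        r = concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], n_boot=10, seed=0)
        assert np.isnan(r.pearson_r) and np.isnan(r.ccc)


class TestAgreement:
    def test_identical_raters(self):
        r = agreement([1, 0, 1, 0], [1, 0, 1, 0])
        assert r.percent_agreement == 100.0
        assert r.kappa == pytest.approx(1.0)

    def test_closed_form_balanced_table(self):
        # 2x2 agreement table (40, 10; 10, 40): p_o = 0.8, p_e = 0.5, kappa = 0.6
        r1 = [1] * 50 + [0] * 50
        r2 = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        r = agreement(r1, r2)
        assert r.percent_agreement == pytest.approx(80.0)
        assert r.kappa == pytest.approx(0.6)

    def test_chance_level_near_zero(self):
        rng = np.random.default_rng(22)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(agreement(a, b).kappa) <= 0.05

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(23)
        a = rng.integers(0, 2, 500)
        b = (a + (rng.random(500) < 0.3)) % 2
        assert agreement(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_both_raters_constant_and_equal_is_undefined(self):
        r = agreement([1, 1, 1], [1, 1, 1])
        assert r.percent_agreement == 100.0
        assert np.isnan(r.kappa)

    def test_kappa_never_exceeds_observed_agreement(self):
        rng = np.random.default_rng(24)
        for _ in range(100):
            a = rng.integers(0, 2, 60)
            b = rng.integers(0, 2, 60)
            res = agreement(a, b)
            if not np.isnan(res.kappa):
                assert res.kappa <= res.percent_agreement / 100 + 1e-12


class TestReannotationProtocol:
    def test_minimal_one_per_cell(self):
        items = ["a", "b", "c", "d"]
        cells = ["tp", "fp", "tn", "fn"]
        assert sorted(stratified_confusion_sample(items, cells, 1, seed=0)) == items

    def test_equal_cell_counts(self):
        rng = np.random.default_rng(25)
        cells = list(rng.choice(["tp", "fp", "tn", "fn"], size=2000))
        items = list(range(2000))
        sample = stratified_confusion_sample(items, cells, 100, seed=1)
        assert len(sample) == 400
        got = [cells[i] for i in sample]
        assert all(got.count(c) == 100 for c in ("tp", "fp", "tn", "fn"))

    def test_deterministic_and_without_replacement(self):
        cells = ["tp"] * 10 + ["fp"] * 10 + ["tn"] * 10 + ["fn"] * 10
        items = list(range(40))
        s1 = stratified_confusion_sample(items, cells, 5, seed=3)
        s2 = stratified_confusion_sample(items, cells, 5, seed=3)
        assert s1 == s2
        assert len(set(s1)) == len(s1)

    def test_short_cell_names_the_cell(self):
        cells = ["tp", "fp", "tn"]
        with pytest.raises(ValueError, match="fn"):
            stratified_confusion_sample(["a", "b", "c"], cells, 1, seed=0)

    def test_union_relabel_truth_table_and_monotonicity(self):
        np.testing.assert_array_equal(union_relabel([1, 0, 0, 1], [0, 0, 1, 1]), [1, 0, 1, 1])
        rng = np.random.default_rng(26)
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        u = union_relabel(a, b)
        np.testing.assert_array_equal(u, np.maximum(a, b))  # element-wise max oracle
        assert u.sum() >= max(a.sum(), b.sum())  # relabeling never loses positives


class TestCohortStatistics:
    def test_yates_reproduces_published_contingency_values(self):
        assert yates_chi_square([[172, 48], [15, 6]]) == pytest.approx(0.19, abs=0.005)
        assert yates_chi_square([[192, 28], [15, 6]]) == pytest.approx(2.77, abs=0.005)

    def test_null_table_clamped_to_zero(self):
        assert yates_chi_square([[10, 10], [10, 10]]) == 0.0

    def test_transpose_invariant(self):
        t = [[30, 10], [12, 28]]
        assert yates_chi_square(t) == pytest.approx(yates_chi_square(np.transpose(t)))

    def test_matches_scipy_when_clamp_inactive(self):
        t = [[30, 10], [12, 28]]
        expected = sps.chi2_contingency(t, correction=True).statistic
        assert yates_chi_square(t) == pytest.approx(expected)

    def test_zero_marginal_flagged(self):
        assert np.isnan(yates_chi_square([[0, 0], [5, 6]]))

    def test_t_null_and_antisymmetry(self):
        t, df = two_sample_t(5.0, 1.0, 10, 5.0, 1.2, 12)
        assert t == pytest.approx(0.0)
        assert df == 20
        t1, _ = two_sample_t(3.97, 1.30, 220, 4.32, 1.39, 21)
        t2, _ = two_sample_t(4.32, 1.39, 21, 3.97, 1.30, 220)
        assert t1 == pytest.approx(-t2)

    def test_t_on_summary_statistics(self):
        # age comparison from grouped summaries: t ~ -1.17 with df = 239
        t, df = two_sample_t(3.97, 1.30, 220, 4.32, 1.39, 21)
        assert df == 239
        assert t == pytest.approx(-1.17, abs=0.01)

    def test_mann_whitney_symmetric_case(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(x, list(x))
        assert u == pytest.approx(len(x) * len(x) / 2)

    def test_mann_whitney_extreme_separation(self):
        u, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0

    def test_mann_whitney_detects_shift(self):
        rng = np.random.default_rng(27)
        x = rng.normal(0, 1, 100)
        y = rng.normal(1.0, 1, 100)
        u, p = mann_whitney(x, y)
        assert u < 100 * 100 / 2
        assert p < 0.001
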