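"""ROC/AUC estimation, threshold rules, kappa and scenario reporting."""

import numpy as np
import pandas as pd
import pytest

from oracles import auc_pair_counting, best_threshold_scan
from radtex.evaluation import (cohens_kappa, evaluate_scenario,
                               evaluate_scenarios, find_perfect_threshold,
                               roc_auc)
from radtex.selection import SelectionResult


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.ci_low <= res.auc <= res.ci_high

    def test_small_worked_examples(self):
        assert roc_auc([1, 2, 3], [0, 1, 1]).auc == 1.0
        assert roc_auc([1, 2, 2], [0, 1, 0]).auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_exactly(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 8, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            expected = float(auc_pair_counting(scores, labels))
            got = roc_auc(scores, labels)
            oriented = expected if expected >= 0.5 else 1 - expected
            assert got.auc == pytest.approx(oriented, abs=1e-12)

    def test_orientation_is_recorded_and_auc_at_least_half(self, rng):
        res = roc_auc([10, 9, 8, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.direction == "less_is_tumor"

    def test_invariant_under_strictly_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_permutation_null_centres_on_half(self):
        within = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            scores = r.normal(size=400)
            labels = np.repeat([0, 1], 200)
            r.shuffle(labels)
            if abs(roc_auc(scores, labels).auc - 0.5) <= 0.1:
                within += 1
        assert within >= 95

    def test_all_tied_scores_degenerate_to_chance(self):
        res = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert res.auc == 0.5
        assert res.degenerate_ci

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_delong_ci_covers_on_repeated_sampling(self):
        # moderate-effect normal model; the 95% CI should cover the true
        # AUC in roughly 95% of draws (loose lower bound to stay cheap)
        from scipy.stats import norm

        true_auc = norm.cdf(1.0 / np.sqrt(2))  # shift 1, unit variances
        covered = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            scores = np.concatenate([r.normal(1, 1, 40), r.normal(0, 1, 40)])
            labels = np.repeat([1, 0], 40)
            res = roc_auc(scores, labels)
            covered += res.ci_low <= true_auc <= res.ci_high
        assert covered >= 180


class TestPerfectThreshold:
    def test_disjoint_low_tumor_gives_less_than_rule(self):
        rule = find_perfect_threshold([1, 2, 5, 6], [1, 1, 0, 0], "f")
        assert (rule.direction, rule.cut, rule.perfect) == ("<", 3.5, True)

    def test_disjoint_high_tumor_gives_greater_than_rule(self):
        rule = find_perfect_threshold([5, 6, 1, 2], [1, 1, 0, 0], "f")
        assert (rule.direction, rule.cut, rule.perfect) == (">", 3.5, True)

    def test_overlap_maximizes_accuracy_matching_exhaustive_scan(self, rng):
        for _ in range(50):
            values = rng.integers(0, 10, size=12).astype(float)
            labels = rng.integers(0, 2, size=12)
            if labels.min() == labels.max() or np.ptp(values) == 0:
                continue
            rule = find_perfect_threshold(values, labels, "f")
            direction, cut, acc, perfect = best_threshold_scan(values, labels)
            assert rule.accuracy == pytest.approx(acc, abs=1e-12)
            assert rule.perfect == perfect

    def test_perfect_iff_class_ranges_disjoint(self, rng):
        for _ in range(50):
            values = rng.normal(size=10)
            labels = np.array([1] * 5 + [0] * 5)
            rule = find_perfect_threshold(values, labels, "f")
            disjoint = (values[:5].max() < values[5:].min()
                        or values[:5].min() > values[5:].max())
            assert rule.perfect == disjoint

    def test_constant_feature_returns_none(self):
        assert find_perfect_threshold([3, 3, 3, 3], [0, 1, 0, 1], "f") is None


class TestCohensKappa:
    def test_identical_mixed_labels_give_one(self):
        assert cohens_kappa([0, 1, 1, 0, 1], [0, 1, 1, 0, 1]) == 1.0

    def test_worked_2x2_table_gives_exactly_0_4(self):
        # a=20 both-yes, b=5, c=10, d=15 both-no: p_o=0.7, p_e=0.5
        a = [1] * 20 + [1] * 5 + [0] * 10 + [0] * 15
        b = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_independent_random_labels_near_zero(self):
        r = np.random.default_rng(5)
        k = cohens_kappa(r.integers(0, 2, 1000), r.integers(0, 2, 1000))
        assert abs(k) < 0.1

    def test_single_shared_category_degenerates_to_one(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cohens_kappa([0, 1], [0, 1, 1])


def scenario_table(rng, n=12, reader="A"):
    y = np.repeat([1, 0], n // 2)
    table = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "sequence": "FLAIR",
        "tissue": np.where(y == 1, "tumor", "edema"),
        "reader": reader,
        "disease": "meningioma",
        "normalization": "none",
        "HIST_Percentile90": y * 10.0 + rng.normal(0, 0.5, n),
        "HIST_Mean": rng.normal(0, 1, n),
    })
    return table


class TestEvaluateScenarios:
    def test_single_consensus_feature_model_auc_equals_univariate(self, rng):
        t_a = scenario_table(rng, reader="A")
        t_b = scenario_table(rng, reader="B")
        sel = SelectionResult(
            per_reader={}, consensus={"HIST_Percentile90"}, status="ok")
        pooled = pd.concat([t_a, t_b], ignore_index=True)
        ev = evaluate_scenario(sel, pooled, {"A": t_a, "B": t_b})
        assert ev.model_auc == pytest.approx(
            ev.feature_rocs["HIST_Percentile90"].auc, abs=1e-12)

    def test_separated_feature_yields_perfect_rule_and_kappa_one(self, rng):
        t_a = scenario_table(rng, reader="A")
        t_b = t_a.copy()
        t_b["reader"] = "B"
        sel = SelectionResult(per_reader={}, consensus={"HIST_Percentile90"},
                              status="ok")
        pooled = pd.concat([t_a, t_b], ignore_index=True)
        ev = evaluate_scenario(sel, pooled, {"A": t_a, "B": t_b})
        rule = ev.rules["HIST_Percentile90"]
        assert rule.perfect and rule.direction == ">"
        assert ev.kappa == 1.0

    def test_no_agreement_row_renders_na(self, rng):
        t_a, t_b = scenario_table(rng), scenario_table(rng, reader="B")
        sel = SelectionResult(per_reader={}, consensus=set(),
                              status="no_agreement")
        key = ("meningioma", "none", "FLAIR")
        report = evaluate_scenarios({key: sel}, {key: {"A": t_a, "B": t_b}})
        row = report.iloc[0]
        assert row["parameters"] == "NA"
        assert row["most_useful"] == "NA"
        assert np.isnan(row["auc"])
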