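"""ROC analysis, perfect-classification thresholds and inter-rater agreement.

The discriminating power of a selected feature is summarized by the area
under the ROC curve, estimated as the Mann–Whitney statistic
P(score_tumor > score_edema) + ½·P(tie) over all positive × negative pairs,
with a 95% confidence interval from the DeLong structural-component
variance. Each AUC is oriented so that it is ≥ 0.5 and the direction
(whether larger values indicate tumor) is recorded.

Scenario-level evaluation reports, per consensus feature, the univariate
AUC; the "most useful parameter" (highest univariate AUC, ties reported
jointly); a multivariable AUC from an unpenalized logistic refit on the
consensus set; single-feature cut-offs that classify every ROI correctly
when the class ranges are disjoint; and Cohen's kappa between the two
readers' rule-based classifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score

from .selection import SelectionResult, binary_labels


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    direction: str  # greater_is_tumor | less_is_tumor
    degenerate_ci: bool = False


@dataclass
class ThresholdRule:
    feature: str
    direction: str  # "<" or ">", read as "tumor if value DIRECTION cut"
    cut: float
    perfect: bool
    accuracy: float

    def describe(self) -> str:
        flag = "perfectly classifies" if self.perfect else "best accuracy"
        return f"{self.feature} {self.direction} {self.cut:g} ({flag})"

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return (values < self.cut) if self.direction == "<" else (values > self.cut)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = _midranks(np.concatenate([pos, neg]))
    m = len(pos)
    return (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * len(neg))


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of a single AUC from the placement values."""
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - _midranks(pos)) / n          # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - _midranks(neg)) / m    # per-negative placements
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels) -> ROCResult:
    """Mann–Whitney AUC with a DeLong 95% CI, oriented so AUC ≥ 0.5.

    ``labels`` are 1/0 (or truthy) for tumor/edema. All scores tied yields
    the chance value 0.5 with a degenerate-CI flag. A perfectly separated
    sample has zero DeLong variance; its CI collapses onto the estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    if np.ptp(scores) == 0:
        return ROCResult(auc=0.5, ci_low=0.0, ci_high=1.0, n_pos=len(pos),
                         n_neg=len(neg), direction="greater_is_tumor",
                         degenerate_ci=True)

    auc = _auc_mann_whitney(pos, neg)
    direction = "greater_is_tumor"
    if auc < 0.5:
        pos, neg = -pos, -neg
        auc = 1.0 - auc
        direction = "less_is_tumor"
    var = _delong_variance(pos, neg, auc)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return ROCResult(auc=float(auc),
                     ci_low=float(np.clip(auc - half, 0.0, 1.0)),
                     ci_high=float(np.clip(auc + half, 0.0, 1.0)),
                     n_pos=len(pos), n_neg=len(neg), direction=direction,
                     degenerate_ci=bool(var == 0.0))


def find_perfect_threshold(values, labels, feature: str = "") -> ThresholdRule | None:
    """Single-feature cut-off, perfect when the class ranges are disjoint.

    If every tumor value lies below every edema value (or vice versa) the
    rule's cut is the midpoint between the two boundary observations and
    ``perfect`` is True. Otherwise the best-accuracy midpoint threshold is
    returned (ties broken toward the smaller cut). A constant feature has
    no usable threshold and returns None.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = values[labels], values[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    if np.ptp(values) == 0:
        return None

    if pos.max() < neg.min():
        cut = (pos.max() + neg.min()) / 2.0
        return ThresholdRule(feature=feature, direction="<", cut=float(cut),
                             perfect=True, accuracy=1.0)
    if pos.min() > neg.max():
        cut = (pos.min() + neg.max()) / 2.0
        return ThresholdRule(feature=feature, direction=">", cut=float(cut),
                             perfect=True, accuracy=1.0)

    uniq = np.unique(values)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    n = len(values)
    for cut in cuts:  # ascending, so ties keep the smaller cut
        for direction in ("<", ">"):
            pred = values < cut if direction == "<" else values > cut
            acc = (pred == labels).mean()
            if best is None or acc > best.accuracy + 1e-12:
                best = ThresholdRule(feature=feature, direction=direction,
                                     cut=float(cut), perfect=False,
                                     accuracy=float(acc))
    return best


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    When both raters use a single identical category throughout, the
    expected agreement is 1 and the ratio is indeterminate; perfect
    observed agreement is then reported as κ = 1 (documented degenerate
    rule).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label sequences differ in length")
    categories = np.unique(np.concatenate([a, b]))
    if len(categories) == 1:
        return 1.0
    return float(cohen_kappa_score(a, b))


@dataclass
class ScenarioEvaluation:
    scenario: tuple
    status: str
    feature_rocs: dict[str, ROCResult]
    most_useful: list[str]
    model_auc: float | None
    rules: dict[str, ThresholdRule]
    kappa: float | None

    def best_auc(self) -> float | None:
        if not self.most_useful:
            return None
        return self.feature_rocs[self.most_useful[0]].auc


def _model_auc(table: pd.DataFrame, features: list[str]) -> float:
    """In-sample AUC of an unpenalized logistic refit on the consensus set."""
    y = binary_labels(table)
    x = table[features].to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    model = LogisticRegression(C=np.inf, max_iter=5000)
    model.fit(x, y)
    return roc_auc(model.decision_function(x), y).auc


def evaluate_scenario(result: SelectionResult, pooled: pd.DataFrame,
                      by_reader: dict[str, pd.DataFrame],
                      scenario: tuple = ()) -> ScenarioEvaluation:
    """Evaluate one scenario's consensus selection.

    ``pooled`` is both readers' rows stacked (the evaluation unit); the
    per-reader tables feed the kappa computation, which compares the two
    readers' classifications of their own ROIs by the best single-feature
    rule.
    """
    if result.status != "ok" or not result.consensus:
        return ScenarioEvaluation(scenario=scenario, status=result.status,
                                  feature_rocs={}, most_useful=[],
                                  model_auc=None, rules={}, kappa=None)

    y = binary_labels(pooled)
    rocs = {f: roc_auc(pooled[f].to_numpy(dtype=float), y)
            for f in sorted(result.consensus)}
    best_auc = max(r.auc for r in rocs.values())
    most_useful = [f for f, r in rocs.items() if abs(r.auc - best_auc) < 1e-12]

    rules = {}
    for f in sorted(result.consensus):
        rule = find_perfect_threshold(pooled[f].to_numpy(dtype=float), y, feature=f)
        if rule is not None:
            rules[f] = rule

    model_auc = _model_auc(pooled, sorted(result.consensus))

    kappa = None
    best_feature = most_useful[0]
    if best_feature in rules and len(by_reader) == 2:
        rule = rules[best_feature]
        readers = sorted(by_reader)
        preds = []
        for r in readers:
            t = by_reader[r].sort_values(["patient_id", "sequence", "tissue"])
            preds.append(rule.apply(t[best_feature].to_numpy(dtype=float)))
        if len(preds[0]) == len(preds[1]):
            kappa = cohens_kappa(preds[0].astype(int), preds[1].astype(int))

    return ScenarioEvaluation(scenario=scenario, status=result.status,
                              feature_rocs=rocs, most_useful=most_useful,
                              model_auc=model_auc, rules=rules, kappa=kappa)


def evaluate_scenarios(selection_results: dict, tables: dict) -> pd.DataFrame:
    """Tabulate the evaluation over the whole scenario grid.

    One row per scenario, mirroring a study-style report: the consensus
    parameters, the most useful parameter with its AUC and 95% CI, the
    multivariable model AUC, any perfect-classification rule, the
    between-reader kappa, and "NA" markers for no-agreement scenarios.
    ``tables`` maps scenario → {reader: table}; rows are emitted for every
    scenario present in ``selection_results`` (no silent drops).
    """
    rows = []
    for scenario, result in selection_results.items():
        by_reader = tables[scenario]
        pooled = pd.concat(by_reader.values(), ignore_index=True)
        ev = evaluate_scenario(result, pooled, by_reader, scenario=scenario)
        row = {
            "disease": scenario[0] if len(scenario) > 0 else "",
            "normalization": scenario[1] if len(scenario) > 1 else "",
            "sequence": scenario[2] if len(scenario) > 2 else "",
            "status": ev.status,
        }
        if ev.status != "ok":
            label = "NA" if ev.status == "no_agreement" else "None Selected"
            row.update({"parameters": label, "most_useful": "NA", "auc": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan, "model_auc": np.nan,
                        "perfect_rule": "", "kappa": np.nan})
        else:
            best = ev.most_useful[0]
            roc = ev.feature_rocs[best]
            perfect = [r.describe() for r in ev.rules.values() if r.perfect]
            row.update({
                "parameters": "; ".join(sorted(ev.feature_rocs)),
                "most_useful": " or ".join(ev.most_useful),
                "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "model_auc": ev.model_auc,
                "perfect_rule": "; ".join(perfect),
                "kappa": ev.kappa if ev.kappa is not None else np.nan,
            })
        rows.append(row)
    return pd.DataFrame(rows)
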