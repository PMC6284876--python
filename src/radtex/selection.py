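"""Per-reader LASSO selection of tumor-vs-edema discriminators and consensus.

The selection stage mirrors a two-reader study design: each reader's ROIs
form one feature table per scenario (disease × normalization × sequence),
an L1-penalized logistic regression (binomial family, logit link) is fit
per reader over a path of penalties λ, λ is chosen by stratified
cross-validation as the value minimizing the mean predictive deviance, and
the features with nonzero coefficients at that λ form the reader's
selection. Because penalized selection is unstable across readers, only
features selected by *both* readers are kept (the consensus); an empty
intersection while at least one reader selected something is reported as
``no_agreement`` (the "NA" rows of the study-style report), and two empty
selections as ``none_selected``.

Features are z-standardized per column before penalization; coefficients
are reported on the standardized scale together with the chosen λ (glmnet
convention: the CV objective is the mean deviance, λ multiplies the L1
norm of the standardized coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import LABEL_COLUMN, feature_columns

DEFAULT_SEED = 20181008
DEFAULT_FOLDS = 10
N_LAMBDAS = 60
LAMBDA_MIN_RATIO = 1e-2   # the p > n convention of the reference R solver
DEV_RATIO_STOP = 0.999    # stop the path once the training fit saturates


class SingleClassError(ValueError):
    """Raised when a table contains only tumor or only edema rows."""


@dataclass
class ReaderSelection:
    reader: str
    selected: dict[str, float]  # feature name -> standardized coefficient
    lam: float                  # chosen penalty (mean-deviance scale)
    n_obs: int
    namespace: frozenset[str] = frozenset()  # candidate features fit over


@dataclass
class SelectionResult:
    per_reader: dict[str, ReaderSelection]
    consensus: set[str] = field(default_factory=set)
    status: str = "ok"  # ok | none_selected | no_agreement

    def to_dict(self) -> dict:
        return {
            "per_reader": {
                r: {"selected": sel.selected, "lambda": sel.lam, "n_obs": sel.n_obs}
                for r, sel in self.per_reader.items()
            },
            "consensus": sorted(self.consensus),
            "status": self.status,
        }


def binary_labels(table: pd.DataFrame) -> np.ndarray:
    """tissue column → 1 for tumor, 0 for edema."""
    return (table[LABEL_COLUMN].to_numpy() == "tumor").astype(int)


def usable_feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Feature columns with any NaN (undefined-flagged) or zero-variance
    column dropped — the conservative pre-selection cleaning rule."""
    feats = table[feature_columns(table)].apply(pd.to_numeric, errors="coerce")
    feats = feats.dropna(axis=1)
    variances = feats.var(axis=0, ddof=0)
    return feats.loc[:, variances > 0]


def _lambda_path(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """glmnet-style geometric λ path from the smallest all-zero λ downward."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(x.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return lam_max * np.logspace(0, np.log10(LAMBDA_MIN_RATIO), N_LAMBDAS)


_EPS = 1e-12


def _binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, _EPS, 1 - _EPS)
    return float(-2.0 * (y * np.log(prob) + (1 - y) * np.log(1 - prob)).sum())


def _truncated_path(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """λ path truncated where the full-data fit saturates.

    Following the reference coordinate-descent solver's convention, the
    descending path stops at the first λ whose full-data deviance ratio
    (1 − dev/null_dev) reaches ``DEV_RATIO_STOP``: beyond that point the
    training fit is essentially saturated and smaller penalties only
    accumulate coefficients without improving the fit. This keeps λ
    selection meaningful on separable scenario tables.
    """
    lambdas = _lambda_path(x, y)
    p_null = np.full_like(y, y.mean(), dtype=float)
    null_dev = _binomial_deviance(y, p_null)
    kept = []
    for lam in lambdas:
        kept.append(lam)
        model = _fit_l1(x, y, lam)
        dev = _binomial_deviance(y, model.predict_proba(x)[:, 1])
        if null_dev > 0 and 1.0 - dev / null_dev >= DEV_RATIO_STOP:
            break
    return np.asarray(kept)


def _fit_l1(x: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn's C is the inverse of the per-sample-summed penalty: λ·n = 1/C
    c = 1.0 / (lam * len(y))
    model = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                               max_iter=2000, tol=1e-7, random_state=0)
    model.fit(x, y)
    return model


def fit_lasso_logistic(table: pd.DataFrame, folds: int = DEFAULT_FOLDS,
                       seed: int = DEFAULT_SEED) -> ReaderSelection:
    """Cross-validated L1 logistic selection on one reader's scenario table.

    Returns the features with nonzero coefficients at the λ minimizing the
    cross-validated mean binomial deviance. Fold assignment is stratified
    and fixed by ``seed``, so the selected set is reproducible bit-for-bit.
    """
    y = binary_labels(table)
    if len(np.unique(y)) < 2:
        raise SingleClassError("both tumor and edema rows are required")
    feats = usable_feature_matrix(table)
    x = feats.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    x = (x - mu) / sd

    lambdas = _truncated_path(x, y)
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise SingleClassError("need at least 2 observations per class for CV")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    deviance = np.zeros(len(lambdas))
    for train, test in splitter.split(x, y):
        for k, lam in enumerate(lambdas):
            model = _fit_l1(x[train], y[train], lam)
            prob = np.clip(model.predict_proba(x[test])[:, 1], _EPS, 1 - _EPS)
            deviance[k] += -2.0 * (y[test] * np.log(prob)
                                   + (1 - y[test]) * np.log(1 - prob)).sum()
    # descending path: on ties argmin keeps the largest (most parsimonious) λ
    best = int(np.argmin(deviance))
    lam = float(lambdas[best])
    final = _fit_l1(x, y, lam)
    coefs = final.coef_.ravel()
    selected = {name: float(c) for name, c in zip(feats.columns, coefs) if c != 0.0}
    reader = str(table["reader"].iloc[0]) if "reader" in table else "?"
    return ReaderSelection(reader=reader, selected=selected, lam=lam, n_obs=len(y),
                           namespace=frozenset(feats.columns))


def consensus_selection(a: ReaderSelection, b: ReaderSelection) -> SelectionResult:
    """Intersect two readers' selections; record the agreement status.

    Both runs must have been fit over the same candidate feature namespace.
    """
    if a.namespace and b.namespace and a.namespace != b.namespace:
        raise ValueError("reader selections come from different feature namespaces")
    consensus = set(a.selected) & set(b.selected)
    if consensus:
        status = "ok"
    elif a.selected or b.selected:
        status = "no_agreement"
    else:
        status = "none_selected"
    return SelectionResult(per_reader={a.reader: a, b.reader: b},
                           consensus=consensus, status=status)


def select_per_scenario(tables: dict, folds: int = DEFAULT_FOLDS,
                        seed: int = DEFAULT_SEED,
                        log=None) -> dict:
    """Run the two-reader selection over a scenario grid.

    ``tables`` maps scenario key → {reader: FeatureTable}. Scenarios whose
    tables cannot support a stratified fit (a single class, or fewer than
    two observations per class) are skipped with a logged reason rather
    than failing the whole grid.
    """
    results: dict = {}
    for scenario, by_reader in tables.items():
        readers = sorted(by_reader)
        if len(readers) != 2:
            if log is not None:
                log(f"{scenario}: expected two readers, got {readers}; skipped")
            continue
        # both readers must be fit over one shared candidate namespace:
        # a feature undefined for either reader's ROIs is excluded for both
        shared = sorted(set(usable_feature_matrix(by_reader[readers[0]]).columns)
                        & set(usable_feature_matrix(by_reader[readers[1]]).columns))
        meta = [c for c in by_reader[readers[0]].columns
                if c not in feature_columns(by_reader[readers[0]])]
        try:
            parts = [fit_lasso_logistic(by_reader[r][meta + shared],
                                        folds=folds, seed=seed)
                     for r in readers]
        except SingleClassError as exc:
            if log is not None:
                log(f"{scenario}: {exc}; skipped")
            continue
        results[scenario] = consensus_selection(parts[0], parts[1])
    return results
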