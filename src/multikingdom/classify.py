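"""Disease-status classification from multikingdom signatures.

A bagged random forest (1,000 trees, sqrt-p features per split) is trained
on the relative abundances of the differential features; discrimination is
summarized by the area under the ROC curve computed from out-of-sample
scores (out-of-bag votes by default, stratified 5-fold cross-validation as
an alternative), with a stratified-bootstrap percentile confidence
interval and impurity-based feature importances.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = ["ClassifierReport", "roc_auc", "auc_ci", "train_evaluate"]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) statistic:
    ``P(score+ > score-) + 0.5 * P(tie)``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the AUC.

    Resampling is stratified: positive and negative samples are resampled
    within their class, so every resample contains both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 samples per class")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    y = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    for b in range(n_boot):
        s = np.concatenate(
            [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        )
        aucs[b] = roc_auc(s, y)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclasses.dataclass
class ClassifierReport:
    """AUC with confidence interval and ranked feature importances."""

    auc: float
    ci_lower: float
    ci_upper: float
    importances: pd.Series  # sorted descending, impurity-based
    scheme: str
    seed: int
    scores: np.ndarray = dataclasses.field(repr=False)

    def to_dict(self, top_k: int = 20) -> dict:
        return {
            "auc": self.auc,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "scheme": self.scheme,
            "seed": self.seed,
            "top_importances": self.importances.head(top_k).round(6).to_dict(),
        }


def train_evaluate(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    positive: str | int | None = None,
    n_trees: int = 1000,
    scheme: str = "oob",
    n_boot: int = 2000,
    seed: int = 0,
) -> ClassifierReport:
    """Train the random forest and report out-of-sample discrimination.

    ``features`` is samples x features; ``labels`` holds two classes
    (``positive`` names the class scored as positive; defaults to the
    lexicographically larger label). ``scheme`` selects the out-of-sample
    scores: ``"oob"`` (out-of-bag class votes, native to bagging) or
    ``"cv5"`` (stratified 5-fold cross-validated probabilities).
    """
    y_raw = pd.Series(np.asarray(labels), index=features.index)
    classes = sorted(y_raw.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive is None:
        positive = classes[-1]
    y = (y_raw == positive).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    x = features.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("feature matrix must be finite")

    def make_forest(oob: bool) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            oob_score=oob,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )

    if scheme == "oob":
        forest = make_forest(oob=True).fit(x, y)
        scores = forest.oob_decision_function_[:, list(forest.classes_).index(True)]
        scores = np.where(np.isfinite(scores), scores, 0.5)
        importances = forest.feature_importances_
    elif scheme == "cv5":
        scores = np.empty(len(y))
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        for train, test in cv.split(x, y):
            f = make_forest(oob=False).fit(x[train], y[train])
            scores[test] = f.predict_proba(x[test])[:, list(f.classes_).index(True)]
        importances = make_forest(oob=False).fit(x, y).feature_importances_
    else:
        raise ValueError(f"unknown scheme {scheme!r} (use 'oob' or 'cv5')")

    auc = roc_auc(scores, y)
    lo, hi = auc_ci(scores, y, n_boot=n_boot, seed=seed)
    ranked = pd.Series(importances, index=features.columns).sort_values(
        ascending=False, kind="mergesort"
    )
    return ClassifierReport(
        auc=auc,
        ci_lower=lo,
        ci_upper=hi,
        importances=ranked,
        scheme=scheme,
        seed=seed,
        scores=scores,
    )
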