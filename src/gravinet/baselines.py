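"""Comparator models: guideline risk-factor rule, supervised learners, PlGF.

The guideline (ACOG-style) rule flags a pregnancy as high risk when at
least one high-risk factor is present (previous preeclampsia, chronic
hypertension, pregestational diabetes, renal disease, autoimmune disease)
or at least two moderate-risk factors are (nulliparity, age >= 35,
BMI > 30).  Supervised comparators are ordinary logistic regression, SVM
and random forest fits with Youden-thresholded scores.  The placental
growth factor classifier scores patients by the negated biomarker level
(lower PlGF, higher risk).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort
from .metrics import confusion_at
from .ssl import youden_threshold

__all__ = [
    "HIGH_RISK_FACTORS",
    "MODERATE_RISK_FACTORS",
    "RiskFactorProfile",
    "BaselinePrediction",
    "acog_classify",
    "acog_classify_table",
    "acog_confusion",
    "SupervisedRiskModel",
    "fit_supervised",
    "plgf_classify",
]

HIGH_RISK_FACTORS = (
    "previous_preeclampsia",
    "chronic_htn",
    "pregestational_diabetes",
    "renal_disease",
    "autoimmune_disease",
)
MODERATE_RISK_FACTORS = ("nulliparity", "age_ge_35", "bmi_gt_30")


@dataclass(frozen=True)
class RiskFactorProfile:
    """Guideline risk factors for one singleton pregnancy.

    Multifetal gestation and ancestry-based factors are structurally
    absent: the modeled cohort is singleton and single-ethnicity.
    """

    previous_preeclampsia: bool = False
    chronic_htn: bool = False
    pregestational_diabetes: bool = False
    renal_disease: bool = False
    autoimmune_disease: bool = False
    nulliparity: bool = False
    age_ge_35: bool = False
    bmi_gt_30: bool = False


@dataclass
class BaselinePrediction:
    """Scores (or hard flags) of one comparator model."""

    model: str
    scores: np.ndarray | None = None
    hard: np.ndarray | None = None  # boolean high-risk flags for rule models
    threshold: float | None = None

    def predict(self) -> np.ndarray:
        if self.hard is not None:
            return np.where(self.hard, 1, -1)
        return np.where(self.scores > self.threshold, 1, -1)


def acog_classify(profile: RiskFactorProfile) -> bool:
    """High risk iff >=1 high-risk factor or >=2 moderate-risk factors."""
    high = any(getattr(profile, f) for f in HIGH_RISK_FACTORS)
    moderate = sum(bool(getattr(profile, f)) for f in MODERATE_RISK_FACTORS)
    return bool(high or moderate >= 2)


def acog_classify_table(flags: pd.DataFrame) -> np.ndarray:
    """Vectorized guideline rule over a risk-flag table."""
    missing = [c for c in HIGH_RISK_FACTORS + MODERATE_RISK_FACTORS if c not in flags]
    if missing:
        raise ValueError(f"risk-flag table lacks columns {missing}")
    high = flags[list(HIGH_RISK_FACTORS)].any(axis=1).to_numpy()
    moderate = flags[list(MODERATE_RISK_FACTORS)].sum(axis=1).to_numpy() >= 2
    return high | moderate


def acog_confusion(cohort: Cohort):
    """(sensitivity, specificity, PPV, NPV) of the guideline rule on labeled patients."""
    if cohort.risk_flags is None:
        raise ValueError("cohort has no risk-factor flags")
    lab = cohort.labeled()
    if (lab.y == 1).sum() == 0:
        raise ValueError("no positive labels; sensitivity undefined")
    pred = acog_classify_table(lab.risk_flags)
    # booleans as 0/1 scores with cut at 0.5 reuse the shared confusion code
    return confusion_at(pred.astype(float), lab.y, 0.5)


# ---------------------------------------------------------------------------
# Supervised comparators


class SupervisedRiskModel(ClassifierMixin, BaseEstimator):
    """Off-the-shelf supervised comparator with a Youden-placed threshold.

    ``model`` is one of ``"lr"`` (logistic regression), ``"svm"`` (support
    vector machine, decision-function scores) or ``"rf"`` (random forest
    of 500 trees, probability scores).  LR and SVM standardize their
    inputs; the forest is scale-invariant and takes them raw.  These are
    comparator scaffolding, deliberately left at library defaults.
    """

    def __init__(self, model: str = "lr", seed: int = 0):
        self.model = model
        self.seed = seed

    def _build(self):
        if self.model == "lr":
            return make_pipeline(
                StandardScaler(), LogisticRegression(max_iter=2000, random_state=self.seed)
            )
        if self.model == "svm":
            return make_pipeline(StandardScaler(), SVC(kernel="linear", random_state=self.seed))
        if self.model == "rf":
            return RandomForestClassifier(n_estimators=500, random_state=self.seed)
        raise ValueError(f"unknown model {self.model!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y[y != 0])) < 2:
            raise ValueError("both outcome classes must be present in training labels")
        mask = y != 0
        self.estimator_ = self._build().fit(X[mask], y[mask])
        self.classes_ = np.array([-1, 1])
        train_scores = self._scores(X[mask])
        self.threshold_ = youden_threshold(train_scores, y[mask])
        self.n_features_in_ = X.shape[1]
        return self

    def _scores(self, X) -> np.ndarray:
        if self.model == "rf":
            return self.estimator_.predict_proba(X)[:, 1]
        return self.estimator_.decision_function(X)

    def decision_function(self, X):
        check_is_fitted(self)
        return self._scores(np.asarray(X, dtype=float))

    def predict(self, X):
        return np.where(self.decision_function(X) > self.threshold_, 1, -1)


def fit_supervised(
    train: Cohort, variables: list[str], model: str, seed: int = 0
) -> SupervisedRiskModel:
    """Fit a supervised comparator on the labeled training patients."""
    sub = train.select_variables(variables)
    return SupervisedRiskModel(model=model, seed=seed).fit(
        sub.X.to_numpy(dtype=float), sub.y
    )


def predict_baseline(
    model: SupervisedRiskModel, cohort: Cohort, variables: list[str]
) -> BaselinePrediction:
    sub = cohort.select_variables(variables)
    return BaselinePrediction(
        model=model.model,
        scores=model.decision_function(sub.X.to_numpy(dtype=float)),
        threshold=model.threshold_,
    )


# ---------------------------------------------------------------------------
# PlGF biomarker classifier


def plgf_classify(cohort: Cohort) -> BaselinePrediction:
    """Score patients by negated PlGF (lower biomarker level = higher risk).

    The threshold maximizes Youden's J on the labeled training patients
    when any exist, otherwise on all labeled patients.
    """
    if cohort.plgf is None:
        raise ValueError("cohort has no PlGF column")
    scores = -cohort.plgf
    ref = (cohort.split == "train") & (cohort.y != 0)
    if not ref.any() or len(np.unique(cohort.y[ref])) < 2:
        ref = cohort.y != 0
    threshold = None
    if ref.any() and len(np.unique(cohort.y[ref])) == 2:
        threshold = youden_threshold(scores[ref], cohort.y[ref])
    return BaselinePrediction(model="plgf", scores=scores, threshold=threshold)
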