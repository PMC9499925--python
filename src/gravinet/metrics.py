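"""ROC metrics, paired comparisons and group-difference tests.

AUROC uses the Mann-Whitney formulation (ties count one half), confusion
metrics follow the strict-``>`` threshold convention, paired ROC curves
are compared with the DeLong placement-value test, repeated-CV results
with a paired t-test, and descriptive group tables with Welch's t /
chi-squared / Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .cohort import Cohort

__all__ = [
    "auroc",
    "confusion_at",
    "roc_table",
    "delong_test",
    "relative_improvement",
    "paired_repeat_ttest",
    "compare_groups",
    "EvalReport",
]


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0 or (labels == -1).sum() == 0:
        raise ValueError("both classes must be present")


def auroc(scores, labels) -> float:
    """Probability that a random case outscores a random control (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels == 1, scores))


def confusion_at(scores, labels, threshold: float):
    """(sensitivity, specificity, PPV, NPV) at a threshold; positive iff score > threshold.

    PPV (resp. NPV) is NaN with a warning when there are no predicted
    positives (resp. negatives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pred = scores > threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("no predicted positives; PPV undefined", stacklevel=2)
        ppv = np.nan
    else:
        ppv = tp / (tp + fp)
    if tn + fn == 0:
        warnings.warn("no predicted negatives; NPV undefined", stacklevel=2)
        npv = np.nan
    else:
        npv = tn / (tn + fn)
    return sens, spec, ppv, npv


def roc_table(scores, labels) -> pd.DataFrame:
    """(FPR, TPR, threshold) table of the ROC curve, for plotting/export."""
    fpr, tpr, thr = roc_curve(np.asarray(labels) == 1, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUROCs


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # V10[i]: fraction of controls scored below case i (ties 1/2); V01[j] dual.
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    mat = gt + 0.5 * eq
    return mat.mean(axis=1), mat.mean(axis=0)


def delong_test(scores_a, scores_b, labels):
    """Compare two paired AUROCs on the same patients (DeLong).

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.
    Identical (or rank-identical) classifiers have zero difference
    variance and are reported as z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores must align with labels")
    _check_two_classes(labels)
    pos = labels == 1
    v10 = np.empty((2, int(pos.sum())))
    v01 = np.empty((2, int((~pos).sum())))
    for k, s in enumerate((scores_a, scores_b)):
        v10[k], v01[k] = _placements(s[pos], s[~pos])
    aucs = v10.mean(axis=1)
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_delta <= np.finfo(float).eps:
        return float(aucs[0]), float(aucs[1]), 0.0, 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var_delta)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(z), float(p)


# ---------------------------------------------------------------------------
# Scalar comparisons


def relative_improvement(auc_new: float, auc_ref: float) -> float:
    """Percent change (auc_new - auc_ref) / auc_ref * 100."""
    if auc_ref <= 0:
        raise ValueError("reference AUROC must be positive")
    return (auc_new - auc_ref) / auc_ref * 100.0


def paired_repeat_ttest(cv_a, cv_b):
    """Paired t-test on per-repeat AUROC differences of two models.

    The two vectors must come from the same CV seeds, one entry per
    repeat.  A zero-variance difference (e.g. identical vectors) is
    reported as (0.0, 1.0) with a warning rather than a division by zero.
    """
    a = np.asarray(cv_a, dtype=float)
    b = np.asarray(cv_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("repeat vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two repeats for a paired t-test")
    d = a - b
    if np.std(d, ddof=1) == 0:
        warnings.warn("zero-variance paired differences; reporting p = 1", stacklevel=2)
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def compare_groups(cohort: Cohort, variable: str):
    """Case-vs-control descriptive test for one variable.

    Continuous variables use Welch's t-test; binary variables use the
    chi-squared test of the 2x2 table, switching to Fisher's exact test
    whenever any expected cell count falls below 5.  Returns
    ``(statistic, p, test_name)``.
    """
    lab = cohort.labeled()
    spec = {v.name: v for v in lab.variables}.get(variable)
    if spec is None:
        raise ValueError(f"unknown variable {variable!r}")
    x = lab.X[variable].to_numpy(dtype=float)
    case = x[lab.y == 1]
    ctrl = x[lab.y == -1]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both outcome groups must be non-empty")
    if spec.kind == "continuous":
        t, p = stats.ttest_ind(case, ctrl, equal_var=False)
        return float(t), float(p), "welch_t"
    table = np.array(
        [
            [(ctrl == 1).sum(), (ctrl == 0).sum()],
            [(case == 1).sum(), (case == 0).sum()],
        ]
    )
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        res = stats.fisher_exact(table)
        return float(res[0]), float(res[1]), "fisher_exact"
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p), "chi2"


# ---------------------------------------------------------------------------
# Report container


@dataclass
class EvalReport:
    """Evaluation summary for one model on one variable set."""

    model: str
    variable_set: str  # {"a" guideline, "b" selected, "c" all}
    auroc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    cv_aurocs: np.ndarray | None = None
    comparisons: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0 <= v <= 1):
                raise ValueError(f"{name} out of [0,1]")
        if not (np.isnan(self.auroc) or 0 <= self.auroc <= 1):
            raise ValueError("AUROC out of [0,1]")

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "variable_set": self.variable_set,
            "auroc": self.auroc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }

    @staticmethod
    def table(reports: list["EvalReport"]) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in reports])
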