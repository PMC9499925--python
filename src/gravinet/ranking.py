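"""Multi-method feature ranking, geometric-mean aggregation, backward elimination.

Variables are ranked by four multivariate methods — recursive feature
elimination wrapped around a linear SVM and around logistic regression,
and random-forest impurity importance under the Gini and entropy
criteria — and the four rankings are combined into one integrated ranking
by the element-wise geometric mean (prod_i r_i)^(1/n).  The final model
subset is then chosen by backward elimination: starting from all
variables, the worst integrated-rank variable is removed one at a time
and the subset with the best cross-validated AUROC wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "RANKING_METHODS",
    "RankTable",
    "SelectionTrace",
    "rank_features",
    "rank_table",
    "aggregate_ranks",
    "backward_eliminate",
]

RANKING_METHODS = ("svm_rfe", "lr_rfe", "rf_gini", "rf_entropy")


def _validate_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    if X.shape[1] < 2:
        raise ValueError("need at least two variables to rank")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to rank features")
    return y


def _importance_ranks(importance: np.ndarray, names: Sequence[str]) -> np.ndarray:
    # rank 1 = most important; ties broken by variable name for reproducibility
    order = sorted(range(len(names)), key=lambda i: (-importance[i], names[i]))
    ranks = np.empty(len(names), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def rank_features(
    X: pd.DataFrame, y: np.ndarray, method: str, seed: int = 0
) -> pd.Series:
    """Rank variables by one method; rank 1 is the most important.

    RFE methods retrain after discarding the weakest variable one per
    iteration, so the rank equals the reverse elimination order.  Forest
    methods rank impurity importances in descending order.  Linear models
    see standardized inputs; forests take them raw (scale-invariant).
    """
    y = _validate_xy(X, y)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if method == "svm_rfe":
        est = SVC(kernel="linear", C=1.0)
        rfe = RFE(est, n_features_to_select=1, step=1)
        rfe.fit(StandardScaler().fit_transform(Xv), y)
        ranks = rfe.ranking_
    elif method == "lr_rfe":
        est = LogisticRegression(C=1000.0, max_iter=5000)
        rfe = RFE(est, n_features_to_select=1, step=1)
        rfe.fit(StandardScaler().fit_transform(Xv), y)
        ranks = rfe.ranking_
    elif method in ("rf_gini", "rf_entropy"):
        crit = "gini" if method == "rf_gini" else "entropy"
        rf = RandomForestClassifier(
            n_estimators=500, criterion=crit, random_state=seed
        ).fit(Xv, y)
        ranks = _importance_ranks(rf.feature_importances_, names)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    return pd.Series(ranks, index=names, name=method)


def aggregate_ranks(ranks: pd.DataFrame) -> pd.Series:
    """Integrated ranking: element-wise geometric mean across methods.

    Column order is irrelevant and the result is strictly monotone in
    every entry; each row's value lies between its smallest and largest
    rank.
    """
    vals = ranks.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("ranks must be positive integers")
    return pd.Series(gmean(vals, axis=1), index=ranks.index, name="integrated")


@dataclass
class RankTable:
    """Per-method ranks plus the geometric-mean integrated ranking."""

    ranks: pd.DataFrame  # (n_variables, n_methods), each column a permutation
    integrated: pd.Series

    def __post_init__(self) -> None:
        p = len(self.ranks)
        for col in self.ranks.columns:
            if sorted(self.ranks[col]) != list(range(1, p + 1)):
                raise ValueError(f"column {col!r} is not a permutation of 1..{p}")

    def order(self) -> list[str]:
        """Variables from best to worst integrated rank (name-tiebroken)."""
        df = self.integrated.to_frame()
        df["name"] = df.index
        return list(df.sort_values(["integrated", "name"]).index)

    def to_frame(self) -> pd.DataFrame:
        out = self.ranks.copy()
        out["integrated"] = self.integrated
        return out.loc[self.order()]

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("variable").to_csv(path)


def rank_table(X: pd.DataFrame, y: np.ndarray, seed: int = 0) -> RankTable:
    """Rank by all four methods and aggregate."""
    ranks = pd.concat(
        [rank_features(X, y, m, seed=seed) for m in RANKING_METHODS], axis=1
    )
    return RankTable(ranks=ranks, integrated=aggregate_ranks(ranks))


@dataclass
class SelectionTrace:
    """Backward-elimination log: (removed variable, AUROC of remaining set)."""

    steps: list[tuple[str | None, float]]  # step 0 removes nothing
    selected: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["removed", "cv_auroc"])


def backward_eliminate(
    order: Sequence[str],
    evaluator: Callable[[list[str]], float],
) -> SelectionTrace:
    """Remove the worst-ranked remaining variable one by one.

    ``order`` lists variables best-first (the integrated ranking);
    ``evaluator`` maps a variable subset to its mean CV AUROC.  The
    selected subset is the remaining set with the highest AUROC, the
    first (largest) such set on ties.
    """
    remaining = list(order)
    try:
        trace: list[tuple[str | None, float]] = [(None, float(evaluator(remaining)))]
    except Exception as exc:  # name the offending subset for diagnosis
        raise RuntimeError(f"evaluator failed on subset {remaining}") from exc
    best_auc, best_set = trace[0][1], list(remaining)
    while len(remaining) > 1:
        removed = remaining.pop()  # worst integrated rank is last
        try:
            auc = float(evaluator(remaining))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed on subset {remaining}") from exc
        trace.append((removed, auc))
        if auc > best_auc:
            best_auc, best_set = auc, list(remaining)
    return SelectionTrace(steps=trace, selected=best_set)
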