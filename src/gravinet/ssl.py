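"""Graph-based semi-supervised label propagation with a closed-form solve.

Given a patient network with Laplacian L and a label vector y with entries
+1 (case), -1 (control) and 0 (unknown outcome), the propagated score
vector f minimizes the quadratic objective

    min_f  (f - y)^T (f - y) + mu * f^T L f

whose closed form is f = (I + mu*L)^{-1} y.  The first term keeps scores
near the observed labels, the second smooths scores across strongly
connected patients, and mu > 0 trades the two off.  Since (I + mu*L) is a
symmetric positive-definite M-matrix with unit row sums, every f_i is a
convex combination of label values: min(y) <= f_i <= max(y).

The model is transductive: scoring new patients requires rebuilding the
network over the union of fitted and new nodes, which is exactly what
:meth:`GraphSSLClassifier.decision_function` does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, fit_standardizer
from .graph import GraphConfig, PatientGraph, build_graph, pairwise_distances

__all__ = [
    "propagate",
    "youden_threshold",
    "GraphSSLClassifier",
    "SSLFit",
    "fit_predict",
    "TuningResult",
    "tune_hyperparameters",
    "default_sigma_grid",
    "default_mu_grid",
]


def propagate(graph: PatientGraph | np.ndarray, y: np.ndarray, mu: float) -> np.ndarray:
    """Solve (I + mu*L) f = y by a symmetric positive-definite factorization.

    ``y`` may be a vector or an (n, k) matrix of k label columns sharing
    the same graph, in which case all k systems are solved from one
    factorization.  No explicit matrix inverse is formed.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    L = graph.laplacian if isinstance(graph, PatientGraph) else np.asarray(graph)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != L.shape[0]:
        raise ValueError("label vector length does not match graph order")
    A = mu * L
    A[np.diag_indices_from(A)] += 1.0
    return cho_solve(cho_factor(A, lower=True), y)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cut point maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive sorted unique scores;
    a prediction is positive when the score is strictly above the
    threshold.  On ties the smallest maximizing midpoint is returned
    (J values within 1e-12 of the maximum count as tied, so floating-point
    noise cannot flip the tie-break).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to place a threshold")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    sens = (pos[None, :] > mids[:, None]).mean(axis=1)
    spec = (neg[None, :] <= mids[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    first_max = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return float(mids[first_max])


def _balanced_labels(y: np.ndarray) -> np.ndarray:
    """Class-mass normalization of the +/-1 label vector (optional)."""
    y = np.asarray(y, dtype=float)
    n_pos = (y > 0).sum()
    n_neg = (y < 0).sum()
    n_l = n_pos + n_neg
    out = y.copy()
    out[y > 0] = n_l / (2.0 * n_pos)
    out[y < 0] = -n_l / (2.0 * n_neg)
    return out


class GraphSSLClassifier(ClassifierMixin, BaseEstimator):
    """Transductive patient-network label-propagation classifier.

    Parameters
    ----------
    sigma : float
        Kernel width of the patient similarity graph.
    mu : float
        Smoothness weight of the propagation objective.
    distance_mode : {"linear", "squared"}
        Form of the distance term inside the Gaussian kernel.
    sparsify_k : int or None
        Optional symmetric k-nearest-neighbour sparsification.
    balance_classes : bool
        If True, rescale the +/-1 labels so both classes carry equal total
        mass before propagation (off by default).

    Notes
    -----
    ``fit`` accepts labels in {+1, -1, 0}; rows with label 0 (patients lost
    to follow-up) join the network and receive propagated scores without
    contributing label information.  ``decision_function(X)`` rebuilds the
    network over the fitted rows plus ``X`` (labels 0) and returns the new
    rows' scores, which is the transductive analogue of inductive
    prediction.  A score of exactly 0 (e.g. an isolated node) classifies
    negative, since predictions are positive only strictly above the
    threshold.
    """

    def __init__(
        self,
        sigma: float = 1.0,
        mu: float = 1.0,
        distance_mode: str = "linear",
        sparsify_k: int | None = None,
        balance_classes: bool = False,
    ):
        self.sigma = sigma
        self.mu = mu
        self.distance_mode = distance_mode
        self.sparsify_k = sparsify_k
        self.balance_classes = balance_classes

    def _graph_config(self) -> GraphConfig:
        return GraphConfig(
            sigma=self.sigma,
            distance_mode=self.distance_mode,
            sparsify_k=self.sparsify_k,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-d with one row per label")
        if not np.isin(y, (-1, 0, 1)).all():
            raise ValueError("labels must be in {+1, -1, 0}")
        if (y == 1).sum() == 0 or (y == -1).sum() == 0:
            raise ValueError("both outcome classes must be present among labels")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.array([-1, 1])
        graph = build_graph(X, self._graph_config())
        y_prop = _balanced_labels(y) if self.balance_classes else y.astype(float)
        self.scores_ = propagate(graph, y_prop, self.mu)
        labeled = y != 0
        self.threshold_ = youden_threshold(self.scores_[labeled], y[labeled])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X=None):
        check_is_fitted(self)
        if X is None:
            return self.scores_
        X = np.asarray(X, dtype=float)
        X_all = np.vstack([self.X_, X])
        graph = build_graph(X_all, self._graph_config())
        y_fit = (
            _balanced_labels(self.y_) if self.balance_classes else self.y_.astype(float)
        )
        y_aug = np.concatenate([y_fit, np.zeros(len(X))])
        f = propagate(graph, y_aug, self.mu)
        return f[len(self.X_):]

    def predict(self, X=None):
        f = self.decision_function(X)
        return np.where(f > self.threshold_, 1, -1)


# ---------------------------------------------------------------------------
# Cohort-level fit


@dataclass
class SSLFit:
    """Propagated scores over a cohort's patient network."""

    scores: pd.Series  # indexed by patient id
    threshold: float
    sigma: float
    mu: float
    distance_mode: str
    include_unlabeled: bool

    def predict(self) -> pd.Series:
        return pd.Series(
            np.where(self.scores.to_numpy() > self.threshold, 1, -1),
            index=self.scores.index,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "predicted": self.predict()},
        )


def fit_predict(
    cohort: Cohort,
    variables: list[str],
    sigma: float,
    mu: float,
    distance_mode: str = "linear",
    include_unlabeled: bool = True,
    sparsify_k: int | None = None,
) -> SSLFit:
    """Fit the transductive model over a cohort and score every node.

    The network is built over all patients (or, with
    ``include_unlabeled=False``, over the labeled patients only — the
    labeled-data-only variant of the model).  Only *training* labels feed
    the propagation: test-era patients join the network with label 0, so
    their outcomes never influence their own scores.  Variables are
    standardized with the location/scale of the labeled training patients,
    and the decision threshold maximizes Youden's J on those same
    patients.
    """
    sub = cohort.select_variables(variables)
    std = fit_standardizer(sub)
    if include_unlabeled:
        nodes = sub
    else:
        nodes = sub.subset(sub.y != 0)
    Xs = std.transform(nodes.X.to_numpy(dtype=float))
    y_prop = np.where((nodes.split == "train") & (nodes.y != 0), nodes.y, 0)
    if (y_prop == 1).sum() == 0 or (y_prop == -1).sum() == 0:
        raise ValueError("training labels must contain both classes")
    graph = build_graph(
        Xs,
        GraphConfig(sigma=sigma, distance_mode=distance_mode, sparsify_k=sparsify_k),
        node_ids=nodes.patient_ids.to_numpy(),
    )
    f = propagate(graph, y_prop, mu)
    train_labeled = y_prop != 0
    threshold = youden_threshold(f[train_labeled], y_prop[train_labeled])
    return SSLFit(
        scores=pd.Series(f, index=nodes.patient_ids, name="score"),
        threshold=threshold,
        sigma=sigma,
        mu=mu,
        distance_mode=distance_mode,
        include_unlabeled=include_unlabeled,
    )


# ---------------------------------------------------------------------------
# Hyper-parameter tuning by repeated stratified CV with label masking


def default_sigma_grid(dist: np.ndarray, distance_mode: str = "linear") -> np.ndarray:
    """Scale-adaptive kernel-width grid.

    sigma^2 runs over {0.25, 0.5, 1, 2, 4} times the median pairwise
    squared distance, so the grid covers sharply local to nearly flat
    kernels regardless of the dimensionality of the variable set.
    """
    off = dist[np.triu_indices_from(dist, k=1)]
    med = float(np.median(off**2))
    if med <= 0:
        med = 1.0
    return np.sqrt(np.array([0.25, 0.5, 1.0, 2.0, 4.0]) * med)


def default_mu_grid() -> np.ndarray:
    """Seven log-spaced smoothness weights covering 1e-3 .. 1e3."""
    return np.logspace(-3, 3, 7)


@dataclass
class TuningResult:
    sigma: float
    mu: float
    table: pd.DataFrame  # columns: sigma, mu, mean_auroc, n_folds

    def __iter__(self):
        yield self.sigma
        yield self.mu
        yield self.table


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    sigma_grid=None,
    mu_grid=None,
    distance_mode: str = "linear",
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int = 0,
    balance_classes: bool = False,
) -> TuningResult:
    """Select (sigma, mu) by repeated stratified k-fold CV with label masking.

    ``X`` holds the standardized features of *all* training patients
    (labeled and unlabeled); ``y`` their labels in {+1, -1, 0}.  For every
    grid point, each repeat stratifies the labeled patients into
    ``cv_folds`` folds; per fold the validation labels are masked to 0,
    scores are propagated over the full training network, and the AUROC of
    the masked fold's scores against its true labels is recorded.  The
    grid point with the highest mean AUROC wins (first on ties).  Repeat
    ``r`` uses stratification seed ``seed + r``, so runs are reproducible.

    The network depends only on sigma, and the linear system only on
    (sigma, mu) — not on the fold — so each grid point factorizes its
    system once and back-solves all masked label vectors in one batch.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    dist = pairwise_distances(X)
    if sigma_grid is None:
        sigma_grid = default_sigma_grid(dist, distance_mode)
    if mu_grid is None:
        mu_grid = default_mu_grid()

    labeled_idx = np.flatnonzero(y != 0)
    y_lab = y[labeled_idx]
    if (y_lab == 1).sum() < cv_folds:
        warnings.warn(
            "fewer cases than folds; some folds may lack a class and be skipped",
            stacklevel=2,
        )

    # Pre-build every masked label column and its validation indices.
    y_prop = _balanced_labels(y) if balance_classes else y.astype(float)
    columns: list[np.ndarray] = []
    val_sets: list[np.ndarray] = []
    for r in range(cv_repeats):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + r)
        for _, val in skf.split(labeled_idx.reshape(-1, 1), y_lab):
            val_global = labeled_idx[val]
            col = y_prop.copy()
            col[val_global] = 0.0
            columns.append(col)
            val_sets.append(val_global)
    Y = np.column_stack(columns)

    rows = []
    best = None
    for sigma in np.asarray(sigma_grid, dtype=float):
        graph = build_graph(X, GraphConfig(sigma=float(sigma), distance_mode=distance_mode), dist=dist)
        L = graph.laplacian
        for mu in np.asarray(mu_grid, dtype=float):
            F = propagate(L, Y, float(mu))
            aucs = []
            for k, val_global in enumerate(val_sets):
                fold_y = y[val_global]
                if len(np.unique(fold_y)) < 2:
                    warnings.warn("skipping single-class validation fold", stacklevel=2)
                    continue
                aucs.append(roc_auc_score(fold_y == 1, F[val_global, k]))
            mean_auc = float(np.mean(aucs)) if aucs else np.nan
            rows.append(
                {"sigma": float(sigma), "mu": float(mu), "mean_auroc": mean_auc,
                 "n_folds": len(aucs)}
            )
            if aucs and (best is None or mean_auc > best[0]):
                best = (mean_auc, float(sigma), float(mu))
    if best is None:
        raise ValueError("no grid point produced a scoreable fold")
    table = pd.DataFrame(rows)
    return TuningResult(sigma=best[1], mu=best[2], table=table)
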