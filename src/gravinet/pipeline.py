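"""End-to-end orchestration: generate -> rank -> select -> tune -> fit -> evaluate.

The pipeline mirrors the study design: a chronological train/test split,
feature ranking and backward elimination on the training set, kernel and
smoothness hyper-parameters tuned by repeated stratified masked CV,
transductive fits with and without the unlabeled patients, supervised and
guideline comparators, and a test-set comparison table.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .baselines import (
    acog_confusion,
    fit_supervised,
    plgf_classify,
    predict_baseline,
)
from .cohort import (
    Cohort,
    fit_standardizer,
    read_cohort_csv,
    split_by_enrollment,
    write_cohort_csv,
    write_schema_yaml,
)
from .graph import GraphConfig, build_graph, pairwise_distances
from .metrics import EvalReport, auroc, confusion_at, delong_test, paired_repeat_ttest
from .ranking import backward_eliminate, rank_table
from .simulate import (
    GeneratorParams,
    default_params,
    generate_cohort,
    generate_risk_flags,
    params_to_yaml,
)
from .ssl import (
    default_sigma_grid,
    fit_predict,
    propagate,
    tune_hyperparameters,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "run_plgf_experiment",
    "ssl_cv_evaluator",
    "cv_repeat_aurocs_ssl",
    "GUIDELINE_VARIABLES",
]

#: Clinical-guideline variable set "[a]": the factors a guideline rule uses.
GUIDELINE_VARIABLES = [
    "history_preeclampsia",
    "maternal_age",
    "bmi_before_pregnancy",
]


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializes into the run manifest."""

    cohort_csv: str | None = None  # read this cohort instead of generating
    n_patients: int = 1404
    n_distractors: int = 0
    variable_set: str = "b"  # {"a": guideline, "b": selected, "c": all}
    models: tuple[str, ...] = ("ssl_lu", "ssl_l", "lr", "svm", "rf", "acog")
    distance_mode: str = "linear"
    cv_folds: int = 5
    cv_repeats: int = 10
    elimination_cv_repeats: int = 3
    mu: float = 1.0  # used during backward elimination (tuning happens after)
    seed: int = 0
    outdir: str = "gravinet_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "models" in doc:
            doc["models"] = tuple(doc["models"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d


def _train_label_vector(cohort: Cohort) -> np.ndarray:
    """Labels visible to any model: training-era known outcomes; 0 elsewhere."""
    return np.where((cohort.split == "train") & (cohort.y != 0), cohort.y, 0)


def ssl_cv_evaluator(
    train: Cohort,
    mu: float,
    cv_folds: int,
    cv_repeats: int,
    seed: int,
    distance_mode: str = "linear",
):
    """Build the CV-AUROC callable that drives backward elimination.

    For a variable subset it standardizes the training patients, places
    the kernel width at the median pairwise squared distance, and returns
    the mean masked-fold AUROC of repeated stratified CV at the given mu.
    """

    def evaluate(variables: list[str]) -> float:
        sub = train.select_variables(list(variables))
        std = fit_standardizer(sub)
        Xs = std.transform(sub.X.to_numpy(dtype=float))
        dist = pairwise_distances(Xs)
        sigma = float(default_sigma_grid(dist, distance_mode)[2])  # 1x median d^2
        res = tune_hyperparameters(
            Xs,
            sub.y,
            sigma_grid=[sigma],
            mu_grid=[mu],
            distance_mode=distance_mode,
            cv_folds=cv_folds,
            cv_repeats=cv_repeats,
            seed=seed,
        )
        return float(res.table["mean_auroc"].iloc[0])

    return evaluate


def cv_repeat_aurocs_ssl(
    train: Cohort,
    variables: list[str],
    sigma: float,
    mu: float,
    cv_folds: int,
    cv_repeats: int,
    seed: int,
    distance_mode: str = "linear",
    include_unlabeled: bool = True,
) -> np.ndarray:
    """Per-repeat mean masked-fold AUROC of the transductive model."""
    sub = train.select_variables(variables)
    if not include_unlabeled:
        sub = sub.subset(sub.y != 0)
    std = fit_standardizer(sub)
    Xs = std.transform(sub.X.to_numpy(dtype=float))
    graph = build_graph(Xs, GraphConfig(sigma=sigma, distance_mode=distance_mode))
    L = graph.laplacian
    y = sub.y
    labeled_idx = np.flatnonzero(y != 0)
    out = []
    for r in range(cv_repeats):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + r)
        cols, vals = [], []
        for _, val in skf.split(labeled_idx.reshape(-1, 1), y[labeled_idx]):
            vg = labeled_idx[val]
            col = y.astype(float).copy()
            col[vg] = 0.0
            cols.append(col)
            vals.append(vg)
        F = propagate(L, np.column_stack(cols), mu)
        fold_aucs = [
            auroc(F[vg, k], y[vg]) for k, vg in enumerate(vals)
            if len(np.unique(y[vg])) == 2
        ]
        out.append(float(np.mean(fold_aucs)))
    return np.asarray(out)


def _cv_repeat_aurocs_supervised(
    train: Cohort,
    variables: list[str],
    model: str,
    cv_folds: int,
    cv_repeats: int,
    seed: int,
) -> np.ndarray:
    """Per-repeat CV AUROC of a supervised comparator on the same fold seeds."""
    sub = train.select_variables(variables).labeled()
    X = sub.X
    y = sub.y
    out = []
    for r in range(cv_repeats):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + r)
        fold_aucs = []
        for tr, val in skf.split(X, y):
            if len(np.unique(y[val])) < 2:
                continue
            fitted = fit_supervised(sub.subset(tr), variables, model, seed=seed)
            scores = fitted.decision_function(X.iloc[val].to_numpy(dtype=float))
            fold_aucs.append(auroc(scores, y[val]))
        out.append(float(np.mean(fold_aucs)))
    return np.asarray(out)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write its artifacts; returns the output dir."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    # ---- cohort ---------------------------------------------------------
    t = time.time()
    if config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv)
        truth = None
        params = None
    else:
        params = default_params(
            n_patients=config.n_patients,
            n_distractors=config.n_distractors,
            seed=config.seed,
        )
        cohort, truth = generate_cohort(params)
        cohort = generate_risk_flags(cohort, truth, params, seed=config.seed + 1)
        write_cohort_csv(cohort, outdir / "cohort.csv")
        truth.to_frame(cohort.patient_ids).to_csv(outdir / "ground_truth.csv")
        params_to_yaml(params, outdir / "generator_params.yaml")
    write_schema_yaml(cohort.variables, outdir / "schema.yaml")
    train, test = split_by_enrollment(cohort)
    stage_times["cohort"] = time.time() - t

    # ---- feature ranking & selection ------------------------------------
    t = time.time()
    train_labeled = train.labeled()
    rt = rank_table(train_labeled.X, train_labeled.y, seed=config.seed)
    rt.to_csv(outdir / "rank_table.csv")
    evaluator = ssl_cv_evaluator(
        train,
        mu=config.mu,
        cv_folds=config.cv_folds,
        cv_repeats=config.elimination_cv_repeats,
        seed=config.seed,
        distance_mode=config.distance_mode,
    )
    trace = backward_eliminate(rt.order(), evaluator)
    trace.to_frame().to_csv(outdir / "selection_trace.csv", index=False)
    stage_times["selection"] = time.time() - t

    variable_sets = {
        "a": [v for v in GUIDELINE_VARIABLES if v in cohort.variable_names],
        "b": trace.selected,
        "c": cohort.variable_names,
    }
    variables = variable_sets[config.variable_set]

    # ---- hyper-parameter tuning ------------------------------------------
    t = time.time()
    sub = train.select_variables(variables)
    std = fit_standardizer(sub)
    Xs = std.transform(sub.X.to_numpy(dtype=float))
    tuning = tune_hyperparameters(
        Xs,
        sub.y,
        distance_mode=config.distance_mode,
        cv_folds=config.cv_folds,
        cv_repeats=config.cv_repeats,
        seed=config.seed,
    )
    tuning.table.to_csv(outdir / "tuning_table.csv", index=False)
    with open(outdir / "hyperparameters.yaml", "w") as fh:
        yaml.safe_dump(
            {"sigma": tuning.sigma, "mu": tuning.mu,
             "distance_mode": config.distance_mode,
             "variables": list(variables)},
            fh,
        )
    stage_times["tuning"] = time.time() - t

    # ---- model fits and evaluation ---------------------------------------
    t = time.time()
    test_labeled_mask = (cohort.split == "test") & (cohort.y != 0)
    reports: list[EvalReport] = []
    test_scores: dict[str, np.ndarray] = {}
    cv_curves: dict[str, np.ndarray] = {}
    y_test = cohort.y[test_labeled_mask]

    for model in config.models:
        if model in ("ssl_lu", "ssl_l"):
            include_u = model == "ssl_lu"
            fit = fit_predict(
                cohort,
                variables,
                sigma=tuning.sigma,
                mu=tuning.mu,
                distance_mode=config.distance_mode,
                include_unlabeled=include_u,
            )
            fit.to_frame().to_csv(outdir / f"scores_{model}.csv")
            scores = fit.scores.loc[cohort.patient_ids[test_labeled_mask]].to_numpy()
            sens, spec, ppv, npv = confusion_at(scores, y_test, fit.threshold)
            cv_curves[model] = cv_repeat_aurocs_ssl(
                train,
                variables,
                tuning.sigma,
                tuning.mu,
                config.cv_folds,
                config.cv_repeats,
                config.seed,
                config.distance_mode,
                include_unlabeled=include_u,
            )
        elif model in ("lr", "svm", "rf"):
            fitted = fit_supervised(train, variables, model, seed=config.seed)
            pred = predict_baseline(fitted, cohort.subset(test_labeled_mask), variables)
            scores = pred.scores
            sens, spec, ppv, npv = confusion_at(scores, y_test, fitted.threshold_)
            cv_curves[model] = _cv_repeat_aurocs_supervised(
                train, variables, model, config.cv_folds, config.cv_repeats, config.seed
            )
        elif model == "acog":
            if cohort.risk_flags is None:
                continue
            sens, spec, ppv, npv = acog_confusion(cohort.subset(test_labeled_mask))
            reports.append(
                EvalReport(model="acog", variable_set=config.variable_set,
                           auroc=np.nan, sensitivity=sens, specificity=spec,
                           ppv=ppv, npv=npv)
            )
            continue
        elif model == "plgf":
            if cohort.plgf is None:
                continue
            pred = plgf_classify(cohort)
            scores = pred.scores[test_labeled_mask]
            sens, spec, ppv, npv = confusion_at(scores, y_test, pred.threshold)
        else:
            raise ValueError(f"unknown model {model!r}")
        test_scores[model] = scores
        reports.append(
            EvalReport(
                model=model,
                variable_set=config.variable_set,
                auroc=auroc(scores, y_test),
                sensitivity=sens,
                specificity=spec,
                ppv=ppv,
                npv=npv,
                cv_aurocs=cv_curves.get(model),
            )
        )
    EvalReport.table(reports).to_csv(outdir / "comparison.csv", index=False)

    comparisons = []
    if "ssl_lu" in test_scores:
        ref = test_scores["ssl_lu"]
        for model, scores in test_scores.items():
            if model == "ssl_lu":
                continue
            a, b, z, p = delong_test(ref, scores, y_test)
            row = {"model": model, "auroc_ssl_lu": a, "auroc_other": b,
                   "delong_z": z, "delong_p": p}
            if model in cv_curves and "ssl_lu" in cv_curves:
                tstat, tp = paired_repeat_ttest(cv_curves["ssl_lu"], cv_curves[model])
                row.update({"paired_t": tstat, "paired_t_p": tp})
            comparisons.append(row)
    pd.DataFrame(comparisons).to_csv(outdir / "pairwise_tests.csv", index=False)
    stage_times["evaluation"] = time.time() - t

    # ---- patient-network export (k-NN pruned to keep the file small) -----
    t = time.time()
    sub_all = cohort.select_variables(variables)
    Xs_all = std.transform(sub_all.X.to_numpy(dtype=float))
    g = build_graph(
        Xs_all,
        GraphConfig(sigma=tuning.sigma, distance_mode=config.distance_mode,
                    sparsify_k=min(10, cohort.n - 1)),
        node_ids=cohort.patient_ids.to_numpy(),
    )
    g.edge_list().to_csv(outdir / "network_edges.csv", index=False)
    stage_times["network_export"] = time.time() - t

    # ---- manifest ---------------------------------------------------------
    cfg = config.to_dict()
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "cv_seeds": [config.seed + r for r in range(config.cv_repeats)],
        "selected_variables": list(trace.selected),
        "hyperparameters": {"sigma": tuning.sigma, "mu": tuning.mu},
        "stage_seconds": stage_times,
        "total_seconds": time.time() - t0,
        "artifact_sha256": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


# ---------------------------------------------------------------------------
# PlGF external comparison


def run_plgf_experiment(
    cohort: Cohort,
    n_labeled: int = 92,
    n_labeled_cases: int | None = 2,
    sigma: float | None = None,
    mu: float = 1.0,
    distance_mode: str = "linear",
    variables: list[str] | None = None,
    seed: int = 0,
) -> dict:
    """Small-label transductive run compared against the PlGF classifier.

    Labels are kept for only ``n_labeled`` randomly chosen labeled
    patients (optionally forcing ``n_labeled_cases`` of them to be cases,
    mirroring a cohort where the unmeasured-biomarker subgroup happened to
    contain two cases); scores are propagated to everyone else, and the
    propagated scores are compared with the negated-PlGF scores on the
    evaluation set by the DeLong test.
    """
    if cohort.plgf is None:
        raise ValueError("cohort has no PlGF column")
    labeled_idx = np.flatnonzero(cohort.y != 0)
    if n_labeled >= len(labeled_idx):
        raise ValueError("evaluation set would be empty; use fewer retained labels")
    rng = np.random.default_rng(seed)
    if n_labeled_cases is not None:
        cases = labeled_idx[cohort.y[labeled_idx] == 1]
        ctrls = labeled_idx[cohort.y[labeled_idx] == -1]
        if n_labeled_cases > len(cases) or n_labeled - n_labeled_cases > len(ctrls):
            raise ValueError("not enough patients of each class to retain")
        keep = np.concatenate(
            [
                rng.choice(cases, size=n_labeled_cases, replace=False),
                rng.choice(ctrls, size=n_labeled - n_labeled_cases, replace=False),
            ]
        )
    else:
        keep = rng.choice(labeled_idx, size=n_labeled, replace=False)
    y_run = np.zeros(cohort.n, dtype=int)
    y_run[keep] = cohort.y[keep]
    if (y_run == 1).sum() == 0 or (y_run == -1).sum() == 0:
        raise ValueError("retained labeled subset lacks both classes")

    variables = variables or cohort.variable_names
    sub = cohort.select_variables(variables)
    # scale on the whole node set: with ~90 reference patients a rare binary
    # flag is often constant there, and scaling uses no outcome information
    std = fit_standardizer(sub, reference=np.ones(cohort.n, dtype=bool))
    Xs = std.transform(sub.X.to_numpy(dtype=float))
    if sigma is None:
        dist = pairwise_distances(Xs)
        sigma = float(default_sigma_grid(dist, distance_mode)[2])
        graph = build_graph(
            Xs, GraphConfig(sigma=sigma, distance_mode=distance_mode), dist=dist
        )
    else:
        graph = build_graph(Xs, GraphConfig(sigma=sigma, distance_mode=distance_mode))
    f = propagate(graph, y_run, mu)

    eval_mask = (cohort.y != 0) & (y_run == 0)
    y_eval = cohort.y[eval_mask]
    ssl_scores = f[eval_mask]
    plgf_scores = -cohort.plgf[eval_mask]
    a, b, z, p = delong_test(ssl_scores, plgf_scores, y_eval)
    return {
        "n_labeled": int(n_labeled),
        "n_eval": int(eval_mask.sum()),
        "auroc_ssl": a,
        "auroc_plgf": b,
        "delong_z": z,
        "delong_p": p,
        "sigma": float(sigma),
        "mu": float(mu),
        "seed": int(seed),
    }
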