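"""Synthetic cohort generator.

Emulates the statistical structure of a prospective first-trimester cohort
of healthy pregnant women followed for pregnancy-associated hypertension:
group-conditional Gaussian clinical variables, ~2.4% outcome prevalence,
a small missing-completely-at-random lost-to-follow-up fraction (masked
labels), guideline risk-factor flags, an optional placental growth factor
(PlGF) biomarker, and optional pure-noise distractor variables to exercise
feature selection.

The generator's defaults are the study conditions: per-group (mean, SD)
pairs of the 11 clinical variables in the training population, the
risk-factor prevalences of the baseline table, prevalence 33/1347 and
unlabeled fraction 57/1404.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cohort import CLINICAL_VARIABLES, Cohort, VariableSpec

__all__ = [
    "GroupStat",
    "GeneratorParams",
    "GroundTruth",
    "default_params",
    "generate_cohort",
    "generate_risk_flags",
    "params_to_yaml",
    "params_from_yaml",
]


@dataclass(frozen=True)
class GroupStat:
    """Per-outcome-group sampling parameters for one variable.

    For a continuous variable, ``control``/``case`` are (mean, SD) pairs;
    for a binary variable they are event probabilities.
    """

    control: tuple[float, float] | float
    case: tuple[float, float] | float


# Training-population group-conditional statistics of the 11 variables
# (control group n=949, case group n=22): mean ± SD for continuous
# variables, event probability for the binary history flag.
_GROUP_STATS: dict[str, GroupStat] = {
    "diastolic_bp_early": GroupStat((67.3, 8.4), (80.5, 10.8)),
    "systolic_bp_early": GroupStat((113.3, 11.4), (132.7, 17.2)),
    "diastolic_bp_late": GroupStat((67.6, 8.6), (77.9, 9.8)),
    "hemoglobin_first_trimester": GroupStat((12.6, 1.0), (13.6, 1.0)),
    "systolic_bp_late": GroupStat((112.6, 11.4), (126.3, 14.4)),
    "bmi_before_pregnancy": GroupStat((22.2, 3.6), (26.2, 5.2)),
    "maternal_age": GroupStat((32.2, 3.9), (33.3, 4.9)),
    "bmi_late_first_trimester": GroupStat((22.5, 3.6), (26.4, 5.2)),
    "history_preeclampsia": GroupStat(7 / 949, 2 / 22),
    "weight_late_first_trimester": GroupStat((58.8, 10.1), (69.7, 14.0)),
    "weight_before_pregnancy": GroupStat((57.9, 10.1), (69.0, 13.9)),
}

# Guideline risk-factor prevalences by outcome group (control n=1314,
# case n=33).  previous_preeclampsia is taken from the generated history
# column; age>=35 and BMI>30 are derived from the age and BMI columns.
_RISK_FLAG_STATS: dict[str, GroupStat] = {
    "chronic_htn": GroupStat(7 / 1314, 4 / 33),
    "pregestational_diabetes": GroupStat(15 / 1314, 2 / 33),
    "renal_disease": GroupStat(2 / 1314, 0.0),
    "autoimmune_disease": GroupStat(1 / 1314, 0.0),
    "nulliparity": GroupStat(671 / 1314, 21 / 33),
}

# Clinically coherent default dependence: the four blood-pressure measures
# are pairwise correlated, as are the weight/BMI measures across eras.
_DEFAULT_CORRELATION: tuple[tuple[tuple[str, ...], float], ...] = (
    (
        (
            "systolic_bp_early",
            "diastolic_bp_early",
            "systolic_bp_late",
            "diastolic_bp_late",
        ),
        0.7,
    ),
    (
        (
            "weight_before_pregnancy",
            "weight_late_first_trimester",
            "bmi_before_pregnancy",
            "bmi_late_first_trimester",
        ),
        0.9,
    ),
)


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic cohort generator (defaults = study conditions)."""

    n_patients: int = 1404
    prevalence: float = 33 / 1347
    unlabeled_fraction: float = 57 / 1404
    # fraction of the whole cohort enrolled in the training era; labeled
    # training patients then number 971 out of 1347 in expectation
    train_fraction: float = 971 / 1347
    group_stats: dict[str, GroupStat] = field(default_factory=lambda: dict(_GROUP_STATS))
    risk_flag_stats: dict[str, GroupStat] = field(
        default_factory=lambda: dict(_RISK_FLAG_STATS)
    )
    correlation_spec: tuple[tuple[tuple[str, ...], float], ...] | None = (
        _DEFAULT_CORRELATION
    )
    n_distractors: int = 0
    plgf_effect: tuple[float, float, float] | None = (
        float(np.log(350.0)),
        float(np.log(350.0)) - 0.3,
        0.6,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0,1)")
        if not 0 <= self.unlabeled_fraction < 1:
            raise ValueError("unlabeled_fraction must lie in [0,1)")
        if self.n_distractors < 0:
            raise ValueError("n_distractors must be nonnegative")
        for name, gs in self.group_stats.items():
            for grp in (gs.control, gs.case):
                if isinstance(grp, tuple):
                    if grp[1] <= 0:
                        raise ValueError(f"SD must be positive for {name!r}")
                elif not 0 <= grp <= 1:
                    raise ValueError(f"probability out of [0,1] for {name!r}")


@dataclass
class GroundTruth:
    """True (pre-masking) outcomes and the informative/distractor bookkeeping."""

    true_label: np.ndarray  # {+1,-1} per patient
    masked: np.ndarray  # bool per patient: label hidden (lost to follow-up)
    informative: list[str]
    distractors: list[str]

    def to_frame(self, patient_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {"true_label": self.true_label, "masked": self.masked},
            index=patient_ids,
        )


def default_params(**overrides) -> GeneratorParams:
    """Generator parameters matching the study's printed statistics."""
    return GeneratorParams(**overrides)


def _correlation_matrix(names: list[str], spec) -> np.ndarray:
    C = np.eye(len(names))
    if spec is None:
        return C
    pos = {n: i for i, n in enumerate(names)}
    for group, r in spec:
        idx = [pos[g] for g in group if g in pos]
        for a in idx:
            for b in idx:
                if a != b:
                    C[a, b] = r
    eigmin = np.linalg.eigvalsh(C).min()
    if eigmin < -1e-8:
        raise ValueError("correlation specification is not positive semi-definite")
    return C


def generate_cohort(
    params: GeneratorParams, seed: int | None = None
) -> tuple[Cohort, GroundTruth]:
    """Draw a synthetic cohort; deterministic given (params, seed).

    Outcomes are Bernoulli(prevalence); continuous variables come from the
    group-conditional (optionally correlated) Gaussian, truncated at the
    physiologic floor 0 by marginal redraws; the binary history flag is
    Bernoulli per group.  A uniformly random ``unlabeled_fraction`` of
    patients has its label masked to 0, independently of the outcome
    (missing completely at random).  The first ``train_fraction`` of rows
    is tagged ``train`` (earlier enrollment era), the rest ``test``.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n = params.n_patients
    true = np.where(rng.random(n) < params.prevalence, 1, -1)

    names = [v.name for v in CLINICAL_VARIABLES]
    cont = [v.name for v in CLINICAL_VARIABLES if v.kind == "continuous"]
    binary = [v.name for v in CLINICAL_VARIABLES if v.kind == "binary"]
    C = _correlation_matrix(cont, params.correlation_spec)
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(len(cont)))

    X = pd.DataFrame(index=pd.RangeIndex(n), columns=names, dtype=float)
    for grp_label, grp_key in ((-1, "control"), (1, "case")):
        mask = true == grp_label
        m = int(mask.sum())
        if m == 0:
            continue
        Z = rng.standard_normal((m, len(cont))) @ chol.T
        means = np.array([getattr(params.group_stats[c], grp_key)[0] for c in cont])
        sds = np.array([getattr(params.group_stats[c], grp_key)[1] for c in cont])
        vals = means + sds * Z
        # physiologic floor: redraw the rare negative values from the marginal
        for j in range(len(cont)):
            bad = vals[:, j] < 0
            while bad.any():
                vals[bad, j] = means[j] + sds[j] * rng.standard_normal(int(bad.sum()))
                bad = vals[:, j] < 0
        X.loc[mask, cont] = vals
        for b in binary:
            p = getattr(params.group_stats[b], grp_key)
            X.loc[mask, b] = (rng.random(m) < p).astype(float)

    variables = list(CLINICAL_VARIABLES)
    distractors = []
    for k in range(params.n_distractors):
        name = f"distractor_{k + 1}"
        X[name] = rng.standard_normal(n)
        variables.append(VariableSpec(name, "continuous", "", "pre-pregnancy"))
        distractors.append(name)

    n_u = int(round(params.unlabeled_fraction * n))
    masked = np.zeros(n, dtype=bool)
    masked[rng.choice(n, size=n_u, replace=False)] = True
    y = np.where(masked, 0, true)

    n_train = int(round(params.train_fraction * n))
    split = np.where(np.arange(n) < n_train, "train", "test")

    plgf = None
    if params.plgf_effect is not None:
        mu0, mu1, s = params.plgf_effect
        logmu = np.where(true == 1, mu1, mu0)
        plgf = np.exp(logmu + s * rng.standard_normal(n))

    ids = pd.Index([f"P{i + 1:06d}" for i in range(n)], name="patient_id")
    X.index = ids
    cohort = Cohort(
        X=X, y=y, split=split, variables=tuple(variables), plgf=plgf
    )
    truth = GroundTruth(
        true_label=true,
        masked=masked,
        informative=names,
        distractors=distractors,
    )
    return cohort, truth


def generate_risk_flags(
    cohort: Cohort,
    truth: GroundTruth,
    params: GeneratorParams,
    seed: int = 0,
) -> Cohort:
    """Attach guideline risk-factor booleans to a generated cohort.

    Sampled flags (chronic hypertension, pregestational diabetes, renal
    and autoimmune disease, nulliparity) use the group-conditional
    prevalences of the baseline table; ``previous_preeclampsia`` mirrors
    the generated history column, and ``age_ge_35``/``bmi_gt_30`` are
    thresholded from the generated age and pre-pregnancy BMI, not sampled
    independently.
    """
    rng = np.random.default_rng(seed)
    n = cohort.n
    flags = pd.DataFrame(index=cohort.patient_ids)
    flags["previous_preeclampsia"] = cohort.X["history_preeclampsia"].to_numpy() > 0.5
    for name, gs in params.risk_flag_stats.items():
        p = np.where(truth.true_label == 1, gs.case, gs.control)
        flags[name] = rng.random(n) < p
    flags["age_ge_35"] = cohort.X["maternal_age"].to_numpy() >= 35.0
    flags["bmi_gt_30"] = cohort.X["bmi_before_pregnancy"].to_numpy() > 30.0
    return replace(cohort, risk_flags=flags)


# ---------------------------------------------------------------------------
# YAML round-trip for run manifests


def params_to_yaml(params: GeneratorParams, path) -> None:
    doc = {
        "n_patients": params.n_patients,
        "prevalence": params.prevalence,
        "unlabeled_fraction": params.unlabeled_fraction,
        "train_fraction": params.train_fraction,
        "n_distractors": params.n_distractors,
        "seed": params.seed,
        "plgf_effect": list(params.plgf_effect) if params.plgf_effect else None,
        "group_stats": {
            k: {"control": [float(x) for x in np.atleast_1d(v.control)],
                "case": [float(x) for x in np.atleast_1d(v.case)]}
            for k, v in params.group_stats.items()
        },
        "correlation_spec": (
            [[list(g), r] for g, r in params.correlation_spec]
            if params.correlation_spec
            else None
        ),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def params_from_yaml(path) -> GeneratorParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def _stat(v):
        c, k = v["control"], v["case"]
        c = tuple(c) if len(c) == 2 else float(c[0])
        k = tuple(k) if len(k) == 2 else float(k[0])
        return GroupStat(c, k)

    return GeneratorParams(
        n_patients=doc["n_patients"],
        prevalence=doc["prevalence"],
        unlabeled_fraction=doc["unlabeled_fraction"],
        train_fraction=doc["train_fraction"],
        n_distractors=doc["n_distractors"],
        seed=doc["seed"],
        plgf_effect=tuple(doc["plgf_effect"]) if doc.get("plgf_effect") else None,
        group_stats={k: _stat(v) for k, v in doc["group_stats"].items()},
        correlation_spec=(
            tuple((tuple(g), r) for g, r in doc["correlation_spec"])
            if doc.get("correlation_spec")
            else None
        ),
    )
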