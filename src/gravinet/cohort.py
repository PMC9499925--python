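"""Cohort data model, CSV I/O, standardization and the chronological split.

A cohort is a per-patient table of first-trimester clinical variables with a
three-state outcome label: ``+1`` (developed pregnancy-associated
hypertension), ``-1`` (completed follow-up without the outcome), ``0``
(lost to follow-up; outcome unknown).  Patients are tagged ``train`` or
``test`` according to their enrollment era, so the test set is
chronologically independent of the training set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "VariableSpec",
    "Cohort",
    "Standardizer",
    "CLINICAL_VARIABLES",
    "LABEL_TO_CODE",
    "CODE_TO_LABEL",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_schema_yaml",
    "write_schema_yaml",
    "fit_standardizer",
    "split_by_enrollment",
]

LABEL_TO_CODE = {"case": 1, "control": -1, "unknown": 0}
CODE_TO_LABEL = {v: k for k, v in LABEL_TO_CODE.items()}


@dataclass(frozen=True)
class VariableSpec:
    """Description of one clinical variable.

    Parameters
    ----------
    name : str
        Canonical snake_case identifier, unique within a cohort.
    kind : {"continuous", "binary"}
        Binary variables take values in {0, 1}.
    units : str
        Free-text units (kg, kg/m², mmHg, g/dL, years, flag).
    era : {"pre-pregnancy", "early-first-trimester", "late-first-trimester"}
        When the measurement is taken: before conception, at the early
        first-trimester visit (~7.7 weeks) or the late first-trimester
        visit (~12.4 weeks).
    """

    name: str
    kind: str
    units: str = ""
    era: str = "pre-pregnancy"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.era not in (
            "pre-pregnancy",
            "early-first-trimester",
            "late-first-trimester",
        ):
            raise ValueError(f"unknown era {self.era!r}")


#: The 11 routinely collected variables used by the risk model, in their
#: integrated-importance order.
CLINICAL_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("diastolic_bp_early", "continuous", "mmHg", "early-first-trimester"),
    VariableSpec("systolic_bp_early", "continuous", "mmHg", "early-first-trimester"),
    VariableSpec("diastolic_bp_late", "continuous", "mmHg", "late-first-trimester"),
    VariableSpec("hemoglobin_first_trimester", "continuous", "g/dL", "early-first-trimester"),
    VariableSpec("systolic_bp_late", "continuous", "mmHg", "late-first-trimester"),
    VariableSpec("bmi_before_pregnancy", "continuous", "kg/m²", "pre-pregnancy"),
    VariableSpec("maternal_age", "continuous", "years", "pre-pregnancy"),
    VariableSpec("bmi_late_first_trimester", "continuous", "kg/m²", "late-first-trimester"),
    VariableSpec("history_preeclampsia", "binary", "flag", "pre-pregnancy"),
    VariableSpec("weight_late_first_trimester", "continuous", "kg", "late-first-trimester"),
    VariableSpec("weight_before_pregnancy", "continuous", "kg", "pre-pregnancy"),
)

_RESERVED = {"patient_id", "label", "split", "plgf"}


class CohortValidationError(ValueError):
    """Raised when a cohort file or cohort object violates its invariants."""


@dataclass
class Cohort:
    """A per-patient feature matrix with outcome labels and split tags.

    Attributes
    ----------
    X : pandas.DataFrame
        (n_patients, n_variables) feature matrix indexed by patient id.
    y : numpy.ndarray
        Outcome codes in {+1, -1, 0}; 0 marks unknown outcome.
    split : numpy.ndarray of str
        Per-patient tag, ``"train"`` or ``"test"``.
    variables : tuple of VariableSpec
        Schema for the columns of ``X`` (same order).
    risk_flags : pandas.DataFrame or None
        Optional guideline risk-factor booleans (ACOG high/moderate factors).
    plgf : numpy.ndarray or None
        Optional placental growth factor level (pg/mL scale), nonnegative.
    """

    X: pd.DataFrame
    y: np.ndarray
    split: np.ndarray
    variables: tuple[VariableSpec, ...] = CLINICAL_VARIABLES
    risk_flags: pd.DataFrame | None = None
    plgf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.split = np.asarray(self.split, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate variable names in schema")
        if list(self.X.columns) != names:
            raise CohortValidationError(
                f"cohort columns {list(self.X.columns)} do not match schema {names}"
            )
        if not np.isfinite(self.X.to_numpy(dtype=float)).all():
            bad = np.argwhere(~np.isfinite(self.X.to_numpy(dtype=float)))
            r, c = bad[0]
            raise CohortValidationError(
                f"non-finite value at patient {self.X.index[r]!r}, "
                f"variable {self.X.columns[c]!r} (patients with missing "
                "variables must be excluded before analysis)"
            )
        for spec in self.variables:
            if spec.kind == "binary":
                vals = set(np.unique(self.X[spec.name].to_numpy()))
                if not vals <= {0.0, 1.0}:
                    raise CohortValidationError(
                        f"binary variable {spec.name!r} has values outside {{0,1}}"
                    )
        if self.y.shape != (len(self.X),):
            raise CohortValidationError("label vector length mismatch")
        if not np.isin(self.y, (-1, 0, 1)).all():
            raise CohortValidationError("labels must be in {+1, -1, 0}")
        if self.split.shape != (len(self.X),):
            raise CohortValidationError("split tag length mismatch")
        if not np.isin(self.split, ("train", "test")).all():
            raise CohortValidationError("split tags must be 'train' or 'test'")
        if self.risk_flags is not None and len(self.risk_flags) != len(self.X):
            raise CohortValidationError("risk_flags length mismatch")
        if self.plgf is not None:
            self.plgf = np.asarray(self.plgf, dtype=float)
            if self.plgf.shape != (len(self.X),) or (self.plgf < 0).any():
                raise CohortValidationError("plgf must be nonnegative, one per patient")

    # -- basic accessors -------------------------------------------------
    @property
    def patient_ids(self) -> pd.Index:
        return self.X.index

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def n_labeled(self) -> int:
        return int((self.y != 0).sum())

    @property
    def n_unlabeled(self) -> int:
        return int((self.y == 0).sum())

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row-subset view (boolean mask or integer positions)."""
        mask = np.asarray(mask)
        return Cohort(
            X=self.X.iloc[mask] if mask.dtype.kind in "iu" else self.X.loc[mask],
            y=self.y[mask],
            split=self.split[mask],
            variables=self.variables,
            risk_flags=None if self.risk_flags is None else (
                self.risk_flags.iloc[mask] if mask.dtype.kind in "iu" else self.risk_flags.loc[mask]
            ),
            plgf=None if self.plgf is None else self.plgf[mask],
        )

    def labeled(self) -> "Cohort":
        """Patients with known outcome (y != 0)."""
        return self.subset(self.y != 0)

    def select_variables(self, names: list[str]) -> "Cohort":
        """Column-subset cohort restricted to the named variables."""
        specs = {v.name: v for v in self.variables}
        missing = [n for n in names if n not in specs]
        if missing:
            raise CohortValidationError(f"unknown variables {missing}")
        return replace(
            self,
            X=self.X[names],
            variables=tuple(specs[n] for n in names),
        )


def split_by_enrollment(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Split a cohort into its (train, test) enrollment-era views.

    The two views are disjoint and together cover every patient.
    """
    train = cohort.subset(cohort.split == "train")
    test = cohort.subset(cohort.split == "test")
    return train, test


# ---------------------------------------------------------------------------
# CSV / YAML I/O


def read_cohort_csv(path: str | Path | io.IOBase, schema=CLINICAL_VARIABLES) -> Cohort:
    """Read a cohort CSV (comma-separated, UTF-8, header row, '.' decimal).

    Required columns: ``patient_id``, every schema variable, ``label``
    (case/control/unknown) and ``split`` (train/test).  Optional columns:
    ``plgf`` and any number of boolean risk-factor flags.

    Raises
    ------
    CohortValidationError
        If a required column is missing, a label value is unrecognized, or a
        cell is missing/non-numeric (the analysis excludes patients with
        missing variables, so such rows are rejected, not imputed).
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    names = [v.name for v in schema]
    required = ["patient_id", *names, "label", "split"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort file lacks required columns {missing}")
    bad_labels = set(df["label"]) - set(LABEL_TO_CODE)
    if bad_labels:
        raise CohortValidationError(f"unrecognized label values {sorted(bad_labels)}")
    X = df[names].copy()
    for col in names:
        numeric = pd.to_numeric(X[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise CohortValidationError(
                f"missing or non-numeric value at row {row}, column {col!r}"
            )
        X[col] = numeric.astype(float)
    X.index = pd.Index(df["patient_id"], name="patient_id")
    flag_cols = [c for c in df.columns if c not in required and c != "plgf"]
    risk_flags = None
    if flag_cols:
        risk_flags = df[flag_cols].astype(bool)
        risk_flags.index = X.index
    plgf = df["plgf"].to_numpy(dtype=float) if "plgf" in df.columns else None
    return Cohort(
        X=X,
        y=df["label"].map(LABEL_TO_CODE).to_numpy(),
        split=df["split"].to_numpy(),
        variables=tuple(schema),
        risk_flags=risk_flags,
        plgf=plgf,
    )


def write_cohort_csv(cohort: Cohort, path: str | Path | io.IOBase) -> None:
    """Write a cohort in the CSV dialect that :func:`read_cohort_csv` reads."""
    df = cohort.X.reset_index()
    df["label"] = [CODE_TO_LABEL[c] for c in cohort.y]
    df["split"] = cohort.split
    if cohort.risk_flags is not None:
        for col in cohort.risk_flags.columns:
            df[col] = cohort.risk_flags[col].to_numpy()
    if cohort.plgf is not None:
        df["plgf"] = cohort.plgf
    df.to_csv(path, index=False)


def read_schema_yaml(path: str | Path) -> tuple[VariableSpec, ...]:
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return tuple(VariableSpec(**e) for e in entries)


def write_schema_yaml(schema, path: str | Path) -> None:
    entries = [
        {"name": v.name, "kind": v.kind, "units": v.units, "era": v.era}
        for v in schema
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Standardization


class Standardizer(TransformerMixin, BaseEstimator):
    """Per-variable location/scale transform fitted on a reference subset.

    Location is the reference mean and scale the reference population
    standard deviation (``ddof=0``).  Fit on the labeled training patients
    and applied to everyone (unlabeled and test included), so nothing about
    the test era leaks into the scaling.  Degenerate (zero-spread) columns
    are rejected rather than silently passed through.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("reference subset must be a non-empty 2-d array")
        self.location_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        if np.any(self.scale_ <= 0):
            j = int(np.argmin(self.scale_))
            raise ValueError(f"degenerate (zero-variance) column at position {j}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return (X - self.location_) / self.scale_

    def inverse_transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return X * self.scale_ + self.location_


def fit_standardizer(cohort: Cohort, reference: np.ndarray | None = None) -> Standardizer:
    """Fit a :class:`Standardizer` on a reference subset of a cohort.

    By default the reference is the labeled training patients, the only
    rows whose distribution the model is allowed to see during fitting.
    """
    if reference is None:
        reference = (cohort.split == "train") & (cohort.y != 0)
    ref = cohort.X.to_numpy(dtype=float)[np.asarray(reference)]
    if len(ref) == 0:
        raise ValueError("reference subset is empty")
    return Standardizer().fit(ref)
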