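import numpy as np
import pandas as pd
import pytest

from gravinet import default_params, generate_cohort, generate_risk_flags
from gravinet.cohort import CLINICAL_VARIABLES, Cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-patient synthetic cohort with risk flags and PlGF."""
    params = default_params(n_patients=600, seed=11)
    cohort, truth = generate_cohort(params)
    cohort = generate_risk_flags(cohort, truth, params, seed=12)
    return cohort, truth, params


def make_cohort(X, y, split=None, variables=None, **kw) -> Cohort:
    """Hand-build a cohort from raw arrays for small deterministic tests."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if variables is None:
        variables = CLINICAL_VARIABLES[:p]
    names = [v.name for v in variables]
    df = pd.DataFrame(X, columns=names,
                      index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"))
    if split is None:
        split = np.full(n, "train")
    return Cohort(X=df, y=np.asarray(y), split=np.asarray(split),
                  variables=tuple(variables), **kw)
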