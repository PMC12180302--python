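import numpy as np
import pandas as pd
import pytest

from multimorbid.pipeline import synthetic_study, two_stage_cluster
from multimorbid.synthetic import default_config, generate


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic cohort (n=2,000) with its preprocessing outputs."""
    synth, prep = synthetic_study(n_subjects=2000, seed=7)
    return synth, prep


@pytest.fixture(scope="session")
def full_run():
    """Full-scale end-to-end run: default cohort, 30x30 SOM, weighted
    k-means at k=4. Shared across the slower integration checks."""
    synth, prep = synthetic_study(n_subjects=8911, seed=11)
    result = two_stage_cluster(prep.matrix, k=4, seed=11, scan_k=None)
    return synth, prep, result


@pytest.fixture()
def toy_cohort():
    """A hand-built 6-row raw cohort with known exclusions and flags."""
    base = {
        "subject_id": [f"T{i}" for i in range(6)],
        "sex": ["male", "female", "male", "female", "male", "other"],
        "age": [60, 75, 80, 66, 92, 70],
        "bmi": [22.0, 27.5, 31.0, 18.4, np.nan, 24.0],
        "education": ["junior_high"] * 6,
        "smoke": [0, 1, 0, 0, 1, 0],
        "drink": [0, 0, 1, 0, 0, 0],
        "uric_acid": [430.0, 360.0, 300.0, np.nan, 421.0, 400.0],
    }
    df = pd.DataFrame(base)
    from multimorbid.diseases import REPORTED_DISEASES

    for d in REPORTED_DISEASES:
        df[d] = 0
    df.loc[0, "hypertension"] = 1
    df.loc[0, "diabetes"] = 1
    df.loc[1, "hypertension"] = 1
    df.loc[1, "arthritis"] = 1
    df.loc[2, "stroke"] = 1
    return df
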