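import numpy as np
import pandas as pd
import pytest

from sonotexture.synthetic import CohortSpec, simulate_cohort, cohort_frames
from sonotexture.texture import extract_features
from sonotexture.types import OUTCOME_COL


@pytest.fixture(scope="session")
def default_cohort():
    """One rendered default cohort (107 subjects, images included)."""
    spec = CohortSpec(seed=0)
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_tables(default_cohort):
    """Feature table (with outcome) and clinical covariates for the cohort."""
    _, subjects = default_cohort
    feats = pd.DataFrame({s.subject_id: extract_features(s.patches) for s in subjects}).T
    feats.index.name = "subject_id"
    cov, _ = cohort_frames(subjects)
    feats[OUTCOME_COL] = cov[OUTCOME_COL]
    return feats, cov.drop(columns=[OUTCOME_COL])


def planted_feature_table(n=300, p_noise=30, beta=0.8, shape=3.0, seed=0):
    """Gaussian features, one of which drives a Gamma outcome."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p_noise + 1))
    names = ["signal"] + [f"noise{i:02d}" for i in range(p_noise)]
    mean = np.exp(np.log(500.0) + beta * X[:, 0])
    y = rng.gamma(shape, mean / shape)
    df = pd.DataFrame(X, columns=names)
    df[OUTCOME_COL] = y
    return df
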