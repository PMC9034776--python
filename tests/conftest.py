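import warnings

import numpy as np
import pandas as pd
import pytest

from errtsem.cohort import CohortConfig, generate_ratings, sample_demographics

warnings.filterwarnings("ignore", message="df = 0")


@pytest.fixture(scope="session")
def default_cohort():
    """One default cohort at the study size (n=249), with ground truth."""
    cfg = CohortConfig(n_subjects=249, seed=20240)
    demo = sample_demographics(cfg)
    ratings, truth = generate_ratings(demo, cfg)
    return cfg, demo, ratings, truth


@pytest.fixture(scope="session")
def one_factor_data():
    """Normal one-factor data for engine cross-checks (n=600, p=5)."""
    rng = np.random.default_rng(42)
    lam = np.array([0.8, 0.7, 0.9, 0.6, 0.5])
    theta = 1 - lam**2
    f = rng.normal(size=600)
    X = f[:, None] * lam + rng.normal(size=(600, 5)) * np.sqrt(theta)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(1, 6)]), lam, theta
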