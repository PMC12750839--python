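import numpy as np
import pandas as pd
import pytest

from coda24.coda import CANONICAL_PARTS, close
from coda24.simulate import GeneratorConfig, generate_analysis_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def random_compositions(rng):
    """1000 random strictly positive 4-part compositions."""
    vals = np.exp(rng.normal(np.log([470, 680, 250, 35]), 0.5, size=(1000, 4)))
    return [close(v) for v in vals]


@pytest.fixture(scope="session")
def study_dataset():
    """Default synthetic cohort (n=124, 7 schools) with its ground truth."""
    return generate_analysis_dataset(GeneratorConfig(seed=3))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero-noise cohort: fits must reproduce the truth exactly."""
    cfg = GeneratorConfig(seed=5, n_participants=300, noise_sd=0.0, school_sd=0.0)
    return generate_analysis_dataset(cfg)


@pytest.fixture(scope="session")
def small_fixture(rng):
    """30-row fixture for hand-rolled estimation oracles."""
    n = 30
    vals = np.exp(rng.normal(np.log([470, 680, 250, 35]), 0.3, size=(n, 4)))
    df = pd.DataFrame(vals, columns=list(CANONICAL_PARTS))
    df["age"] = rng.uniform(13, 17, n).round(1)
    df["gender"] = np.where(rng.random(n) < 0.5, "male", "female")
    df["school"] = [f"S{i % 7}" for i in range(n)]
    df["happiness"] = rng.normal(3.9, 0.7, n)
    return df
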