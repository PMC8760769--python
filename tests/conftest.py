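from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import repeatkit as rk
from repeatkit.pipeline import PipelineConfig, _analysis_frames

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_path() -> Path:
    return DATA_DIR / "synthetic_study_seed42.tsv"


@pytest.fixture(scope="session")
def fixture_dataset(fixture_path) -> rk.StudyDataset:
    return rk.read_dataset(fixture_path)


@pytest.fixture(scope="session")
def fixture_frames(fixture_dataset):
    """(per_test, long) analysis frames of the committed fixture study."""
    return _analysis_frames(fixture_dataset, PipelineConfig())


@pytest.fixture(scope="session")
def small_study():
    """A default-parameter synthetic study with its ground truth."""
    return rk.generate_study(rk.SyntheticParams(seed=7))


def make_grouped_data(n_groups: int, n_per: int, v_between: float,
                      v_within: float, seed: int, mu: float = 0.0
                      ) -> pd.DataFrame:
    """Plain one-way grouped Gaussian data for generic LMM tests."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(v_between), size=n_groups)
    e = rng.normal(0.0, np.sqrt(v_within), size=n_groups * n_per)
    g = np.repeat(np.arange(n_groups), n_per)
    return pd.DataFrame({
        "individual_id": [f"id{i:03d}" for i in g],
        "y": mu + u[g] + e,
    })
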