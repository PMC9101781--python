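import dataclasses

import numpy as np
import pandas as pd
import pytest

from raman_rice.pipeline import PipelineConfig, feature_table_from_spectra
from raman_rice.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    """The study-design generator configuration (4 varieties x 39 grains)."""
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_spectra(default_config):
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def default_table(default_config, default_spectra) -> pd.DataFrame:
    """The 156 x 31 feature table of the default synthetic dataset."""
    cfg = PipelineConfig(synthetic=default_config)
    return feature_table_from_spectra(default_spectra, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_feature_frame(X: np.ndarray, y: np.ndarray, columns: list[str]) -> pd.DataFrame:
    """Wrap a plain matrix as a feature table with metadata columns."""
    frame = pd.DataFrame(X, columns=columns)
    frame.insert(0, "sample_number", np.arange(1, len(frame) + 1))
    frame.insert(0, "variety_label", y)
    frame.insert(0, "sample_name", [f"s{i}" for i in range(len(frame))])
    return frame


@pytest.fixture()
def small_config() -> SyntheticConfig:
    """A light two-variety design for fast end-to-end checks."""
    base = SyntheticConfig()
    return dataclasses.replace(
        base,
        class_amplitudes={
            "TOL": base.class_amplitudes["BD6"],
            "SEN": base.class_amplitudes["KD42"],
        },
        variety_labels={"TOL": 1, "SEN": 0},
        n_per_class=8,
        seed=11,
    )
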