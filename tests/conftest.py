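import numpy as np
import pandas as pd
import pytest

from exoquality import StudyDataset, default_config, simulate_study


def make_dataset(
    rng: np.random.Generator,
    n_samples: int = 2,
    n_methods: int = 2,
    n_assays: int = 2,
    n_replicates: int = 3,
) -> StudyDataset:
    """A small random crossed dataset with positive continuous values."""
    rows = []
    for s in range(n_samples):
        group = "tumor" if s % 2 == 0 else "healthy"
        for m in range(n_methods):
            for a in range(n_assays):
                for r in range(n_replicates):
                    rows.append(
                        (f"s{s}", group, f"m{m}", f"a{a}", r + 1,
                         float(rng.lognormal(2.0, 0.8)))
                    )
    return StudyDataset(
        pd.DataFrame(
            rows,
            columns=["sample_id", "group", "method", "assay",
                     "replicate", "value"],
        )
    )


@pytest.fixture(scope="session")
def study_dataset() -> StudyDataset:
    """The default simulated study: 11 samples x 4 methods x 5 assays x 4
    replicates."""
    dataset, _ = simulate_study(default_config(seed=42))
    return dataset


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
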