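import dataclasses

import numpy as np
import pandas as pd
import pytest

from truealarms.cohort import CohortTable, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A quick-to-generate cohort configuration used across tests."""
    return dataclasses.replace(
        GeneratorConfig(), n_subjects=2000, missing_rate=0.0, seed=1234
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> CohortTable:
    return generate_cohort(small_config)


def toy_cohort(
    y1: list[int],
    t2: list[int],
    y2: list,
    features: dict[str, list[float]] | None = None,
) -> CohortTable:
    """Hand-built cohort from explicit label vectors (y2 entries may be None)."""
    n = len(y1)
    features = features or {"scale_1": list(np.linspace(0.0, 1.0, n))}
    data = pd.DataFrame({"subject_id": np.arange(n)})
    data["y1"] = np.asarray(y1, dtype=np.int8)
    data["t2_responded"] = np.asarray(t2, dtype=np.int8)
    data["y2_first"] = pd.array(
        [pd.NA if v is None else v for v in y2], dtype="Int8"
    )
    for name, vals in features.items():
        data[name] = vals
    return CohortTable(data=data, feature_names=list(features))
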