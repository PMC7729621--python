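import numpy as np
import pandas as pd
import pytest

from sigfall import GaitFeatureTable, default_schema, generate_cohort
from sigfall.cohort import CohortConfig, default_effect_profile
from sigfall.table import FALLER, NON_FALLER


def table_from_arrays(X, labels, schema=None) -> GaitFeatureTable:
    """Build a feature table from a raw matrix and 0/1 labels."""
    schema = schema or default_schema()
    X = np.asarray(X, dtype=float)
    frame = pd.DataFrame(X, columns=list(schema.names))
    frame.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(frame))])
    frame.insert(1, "label", [FALLER if y else NON_FALLER for y in np.asarray(labels)])
    return GaitFeatureTable(frame, schema)


@pytest.fixture
def make_table():
    return table_from_arrays


@pytest.fixture(scope="session")
def default_cohort() -> GaitFeatureTable:
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def null_cohort() -> GaitFeatureTable:
    cfg = CohortConfig(
        effect_profile=default_effect_profile(magnitude=0.0), seed=7, with_demographics=False
    )
    return generate_cohort(cfg)
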