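from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cohortval.cohort import (
    CONTINUOUS,
    DISCRETE,
    TIME_TO_EVENT,
    Cohort,
    VariableSpec,
)


def continuous_cohort(provenance: str = "unspecified", **columns) -> Cohort:
    """Build a cohort of continuous variables from keyword arrays."""
    data = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    variables = [VariableSpec(name, CONTINUOUS) for name in columns]
    return Cohort(data=data, variables=variables, provenance=provenance)


def tte_cohort(times, events, name: str = "t", event_name: str = "e") -> Cohort:
    data = pd.DataFrame(
        {
            name: np.asarray(times, dtype=float),
            event_name: np.asarray(events, dtype=float),
        }
    )
    return Cohort(
        data=data,
        variables=[VariableSpec(name, TIME_TO_EVENT, event_name)],
    )


def discrete_cohort(values, name: str = "g") -> Cohort:
    data = pd.DataFrame({name: pd.Series(list(values), dtype=object)})
    return Cohort(data=data, variables=[VariableSpec(name, DISCRETE)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
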