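import numpy as np
import pandas as pd
import pytest

from mprsurv.cohort import (
    default_full_config,
    default_treatment_only_config,
    generate_cohort,
)
from mprsurv.design import FACTOR_LEVELS


@pytest.fixture(scope="session")
def treatment_cohort() -> pd.DataFrame:
    """One default treatment-only cohort (n=855)."""
    return generate_cohort(default_treatment_only_config(seed=3))


@pytest.fixture(scope="session")
def full_cohort() -> pd.DataFrame:
    """One default full-mode cohort (n=855, allocation model active)."""
    return generate_cohort(default_full_config(seed=5))


def make_cohort(times, events, **factor_values) -> pd.DataFrame:
    """Minimal schema-complete cohort around given times/events.

    Unspecified factors sit at their reference level.
    """
    n = len(times)
    data = {
        "id": np.arange(1, n + 1),
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
    }
    for factor, levels in FACTOR_LEVELS.items():
        data[factor] = np.asarray(factor_values.get(factor, [levels[0]] * n), dtype=object)
    frame = pd.DataFrame(data)
    frame["treated"] = (frame["treatment"] != "palliative").astype(int)
    return frame
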