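import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from greyrank import Sequence, SyntheticSpec, simulate_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_seq(values, name="s", start_year=2001):
    values = list(values)
    years = np.arange(start_year, start_year + len(values))
    return Sequence(name, years, np.asarray(values, dtype=float))


@pytest.fixture
def seq_factory():
    return make_seq


@pytest.fixture
def default_panel():
    """One default synthetic panel, fixed seed."""
    return simulate_panel(SyntheticSpec(seed=42))


@pytest.fixture
def wide_csv(tmp_path):
    """Well-formed wide-dialect CSV: 20 years, female mortality + smoking."""
    years = np.arange(2001, 2021)
    df = pd.DataFrame(
        {
            "year": years,
            "mortality_f": 50.0 - 0.4 * (years - 2001),
            "smoking_f": 2.6 - 0.05 * (years - 2001),
            "income": 150.0 * np.exp(0.07 * (years - 2001)),
        }
    )
    path = tmp_path / "panel.csv"
    df.to_csv(path, index=False)
    return path
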