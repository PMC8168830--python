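import numpy as np
import pandas as pd
import pytest

from mimosa import StudyTable, Variable, alspac_like_preset, default_spec


@pytest.fixture(scope="session")
def preset_small():
    """n=2000 cohort with the standard missingness mechanisms (delta_true=0)."""
    table, config, mechanism = alspac_like_preset(2000, seed=42)
    return table, config, mechanism


@pytest.fixture(scope="session")
def preset_large():
    """n=20000 cohort for calibration-band checks."""
    table, config, mechanism = alspac_like_preset(20000, seed=7)
    return table, config, mechanism


@pytest.fixture()
def toy_table():
    """4 records; outcome missing in row 0, exposure missing in rows 0 and 2.

    By hand: outcome missing 1/4, exposure 2/4, complete records 2/4, three
    distinct patterns with counts {2, 1, 1}.
    """
    data = pd.DataFrame(
        {
            "score": [np.nan, 70.0, 55.0, 80.0],
            "smoke": [np.nan, 0.0, np.nan, 1.0],
            "sex": [1.0, 0.0, 1.0, 0.0],
        }
    )
    variables = [
        Variable("score", "outcome", "continuous"),
        Variable("smoke", "exposure", "binary"),
        Variable("sex", "confounder", "binary"),
    ]
    return StudyTable(data, variables)


@pytest.fixture()
def single_missing_table():
    """Continuous outcome partially missing; all predictors complete."""
    rng = np.random.default_rng(5)
    n = 400
    x = rng.binomial(1, 0.4, n).astype(float)
    c = rng.standard_normal(n)
    y = 3.0 - 2.0 * x + 1.5 * c + rng.standard_normal(n)
    data = pd.DataFrame({"y": y, "x": x, "c": c})
    data.loc[rng.random(n) < 0.3, "y"] = np.nan
    variables = [
        Variable("y", "outcome", "continuous"),
        Variable("x", "exposure", "binary"),
        Variable("c", "confounder", "continuous"),
    ]
    return StudyTable(data, variables)


@pytest.fixture()
def small_spec(preset_small):
    table, _, _ = preset_small
    return default_spec(table, m=4, cycles=4, seed=9)
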