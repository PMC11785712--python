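import numpy as np
import pandas as pd
import pytest

from vinoclim import synthetic_data as sd


@pytest.fixture(scope="session")
def default_weather():
    """25 years of default synthetic daily weather (1993-2017)."""
    return sd.generate_daily_weather(sd.WeatherGenConfig(), seed=1234)


@pytest.fixture(scope="session")
def default_vintages(default_weather):
    table, truth = sd.generate_wine_table(default_weather, seed=99)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_monthly_series(values: np.ndarray, years) -> pd.Series:
    """(n_years, 12) array -> Series indexed by (year, month)."""
    idx = pd.MultiIndex.from_product([list(years), range(1, 13)],
                                     names=["year", "month"])
    return pd.Series(np.asarray(values, dtype=float).ravel(), index=idx)
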