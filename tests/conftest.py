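import numpy as np
import pandas as pd
import pytest

from salesgap.synthetic import SyntheticConfig, default_anomalies, generate_panel, province_names


@pytest.fixture(scope="session")
def small_config():
    """A desk-size clean generator config (8 provinces, 6 years)."""
    return SyntheticConfig(n_provinces=8, year_start=2002, year_end=2007, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = generate_panel(small_config)
    return panel


@pytest.fixture(scope="session")
def anomalous_config():
    """Desk-size config with the default excess/deficit injection."""
    names = province_names(10)
    return SyntheticConfig(
        n_provinces=10,
        year_start=2002,
        year_end=2009,
        anomalies=default_anomalies(names),
        seed=11,
    )


@pytest.fixture()
def toy_classified():
    """Hand-built classified intervals covering all three statuses."""
    return pd.DataFrame(
        {
            "province": ["A", "B", "C", "D"],
            "year": [2002] * 4,
            "p_l": [100.0, 100.0, 100.0, 100.0],
            "q50": [150.0, 150.0, 150.0, 150.0],
            "p_u": [200.0, 200.0, 200.0, 200.0],
            "observed": [280.0, 80.0, 150.0, 320.0],
            "status": ["upper", "lower", "none", "upper"],
        }
    )


def exact_panel(n_provinces=4, n_years=4, duplicate_pair=None):
    """Noise-free log-log panel built by hand: sales = exp(4 - 0.5 log p + 0.4 log g).

    ``duplicate_pair`` makes two provinces share identical features.
    """
    rows = []
    rng = np.random.default_rng(3)
    gdps = rng.uniform(17, 36, n_provinces)
    if duplicate_pair:
        i, j = duplicate_pair
        gdps[j] = gdps[i]
    prices = np.linspace(1.5, 4.5, n_years)
    for p in range(n_provinces):
        for t in range(n_years):
            sales = np.exp(4.0 - 0.5 * np.log(prices[t]) + 0.4 * np.log(gdps[p]))
            rows.append(
                {
                    "province": f"P{p + 1:02d}",
                    "year": 2002 + t,
                    "sales_pc": sales,
                    "price": prices[t],
                    "gdp_pc": gdps[p],
                }
            )
    return pd.DataFrame(rows)
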