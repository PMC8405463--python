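import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bcfkit as bk
from bcfkit.series import ConcentrationSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_series(analyte, medium, times, values, replicate="r1", censoring=None,
                n_pooled=1):
    """Build a ConcentrationSeries from parallel arrays."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    df = pd.DataFrame({
        "time_h": times,
        "replicate": replicate,
        "value": values,
        "censoring": censoring if censoring is not None else "none",
        "n_pooled": n_pooled,
    })
    return ConcentrationSeries(analyte=analyte, medium=medium, data=df)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def panel():
    return bk.ssri_panel()


@pytest.fixture
def noise_free_pair(series_factory):
    """Noise-free uptake data generated by the closed form (k1=20, k2=0.1, cw=80)."""
    t = np.array([0.0, 6.0, 24.0, 45.0, 48.0])
    y = bk.predict_uptake(20.0, 0.1, 80.0, t)
    body = series_factory("probe", "organism", t, y)
    water = series_factory("probe", "water", [0.0, 24.0, 48.0], [80.0, 80.0, 80.0])
    return body, water


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded synthetic SSRI-panel experiment at the high exposure level."""
    return bk.generate_dataset(bk.default_config(nominal_cw=300.0, seed=7))
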