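import numpy as np
import pytest

from traitsync import (
    DistanceMatrix,
    SimulationScenario,
    SynchronyParams,
    TraitPanel,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """One fixed small simulated study: 20 sites, 25 complete years."""
    scenario = SimulationScenario(
        n_sites=20, n_years=25, truth=SynchronyParams(0.7, 0.1, 500.0), seed=42
    )
    return simulate_study(scenario)


@pytest.fixture()
def two_site_distance():
    return DistanceMatrix(["a", "b"], np.array([[0.0, 300.0], [300.0, 0.0]]))


def make_panel(values, years=None, name="trait", populations=None):
    """Small helper: full-mask panel from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    return TraitPanel(
        name=name,
        populations=populations or [f"p{i}" for i in range(n)],
        years=years or list(range(2000, 2000 + t)),
        values=values,
        mask=~np.isnan(values),
    )
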