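import numpy as np
import pandas as pd
import pytest

from u5mort.lifetable import N_AGES
from u5mort.synthetic import SurveyDesign, TrueSurface, TrueSurfaceParams, make_true_surface


@pytest.fixture
def default_surface() -> TrueSurface:
    return make_true_surface(TrueSurfaceParams(seed=42))


@pytest.fixture
def noise_free_params() -> TrueSurfaceParams:
    return TrueSurfaceParams(k_sigma=0.0, e_sigma=0.0, seed=0)


def constant_surface(q_monthly: float, years=(1993, 2017)) -> TrueSurface:
    """Surface with the same monthly death probability in every cell."""
    from u5mort.lifetable import q_to_m

    yrs = np.arange(years[0], years[1] + 1)
    m = q_to_m(q_monthly)
    grid = pd.DataFrame(
        np.full((N_AGES, len(yrs)), m),
        index=pd.Index(np.arange(N_AGES), name="age_month"),
        columns=pd.Index(yrs, name="year"),
    )
    params = TrueSurfaceParams(years=years, k_drift=0.0, k_sigma=0.0, e_sigma=0.0)
    return TrueSurface(m=grid, k=pd.Series(0.0, index=grid.columns), params=params)


@pytest.fixture
def small_design() -> SurveyDesign:
    return SurveyDesign(n_women=500, window_years=10)
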