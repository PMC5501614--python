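import numpy as np
import pytest

from fadspread.inference import FitConfig
from fadspread.model_core import ComplexDynParams, SimpleDynParams
from fadspread.synthetic_data import GeneratorSpec, generate_series
from fadspread.trajectory import ObsParams


@pytest.fixture(scope="session")
def fast_cfg():
    """Minimal-effort fit configuration for smoke tests."""
    return FitConfig(seed=0, tau_grid=(2,), n_restarts=2, n_restarts_simple=4,
                     coarse_restarts=1, maxfev_coarse=60, maxfev_refine=200,
                     maxfev_polish=400, top_k=1, allow_two_pop=False,
                     enforce_filter=False)


@pytest.fixture(scope="session")
def simple_params():
    return SimpleDynParams(beta_i=1.0, beta_j=0.3, gamma=0.25, epsilon=0.4,
                           I0=1e-3)


@pytest.fixture(scope="session")
def complex_params():
    return ComplexDynParams(beta=4.0, tau_i=2, tau_j=2, tau_r=2,
                            epsilon=0.5, I0=1e-3)


@pytest.fixture(scope="session")
def simple_series(simple_params):
    spec = GeneratorSpec(mechanism="simple", dyn=(simple_params,),
                         obs=(ObsParams(A=100.0, delta_t=1.0, r=100.0),),
                         T=40, seed=42)
    series, truth = generate_series(spec)
    return series, truth


@pytest.fixture(scope="session")
def complex_series(complex_params):
    spec = GeneratorSpec(mechanism="complex", dyn=(complex_params,),
                         obs=(ObsParams(A=100.0, delta_t=1.0, r=100.0),),
                         T=40, seed=43)
    series, truth = generate_series(spec)
    return series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
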