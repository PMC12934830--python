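import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from logddg import DDParams, StopCondition, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


# Three 3-region parameter sets, one per equilibrium solver regime;
# all target a local equilibrium diversity near 19 species per region.
@pytest.fixture(scope="session")
def params_unconstrained():
    return DDParams(
        rho_w=15.0, rho_e=0.03, rho_d=0.05, rho_b=1.0,
        w_D=-0.5, b_D=-1.0, d_D_dest=-2.0, d_D_src=-1.0, e_D=4.0,
        n_regions=3,
    )


@pytest.fixture(scope="session")
def params_closed_form():
    return DDParams(
        rho_w=0.610047, rho_e=0.01, rho_d=0.01, rho_b=1.0,
        w_D=-1.0, d_D_dest=-1.0, d_D_src=0.0, b_D=0.0, e_D=2.0,
        n_regions=3,
    )


@pytest.fixture(scope="session")
def params_fixed_point():
    return DDParams(
        rho_w=3.730315, rho_e=0.03, rho_d=0.04, rho_b=1.0,
        w_D=-0.5, d_D_dest=-0.5, d_D_src=-0.5, b_D=0.0, e_D=3.0,
        n_regions=3,
    )


@pytest.fixture(scope="session")
def small_sim(params_closed_form):
    """One moderately sized simulated tree with extinction events."""
    return simulate(
        params_closed_form,
        StopCondition(max_time=150.0),
        root_range={0},
        seed=20240915,
    )


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def rng():
    return np.random.default_rng(777)
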