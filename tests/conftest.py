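import numpy as np
import pytest

from chainlfa import (MembraneModelParams, MicroModelParams,
                      build_chain_grid, generate_fixtures, generate_grid,
                      solve_flow)


@pytest.fixture(scope="session")
def micro_params():
    return MicroModelParams()


@pytest.fixture(scope="session")
def membrane_params():
    return MembraneModelParams()


@pytest.fixture(scope="session")
def ci_bundle():
    """Coarse CI-scale fixture bundle (t_end = 36 s, coarse grids)."""
    return generate_fixtures("ci")


@pytest.fixture(scope="session")
def coarse_grid(ci_bundle):
    return ci_bundle.micro_grid


@pytest.fixture(scope="session")
def static_flow(ci_bundle, coarse_grid):
    return solve_flow(coarse_grid, ci_bundle.micro, 0.0)


@pytest.fixture(scope="session")
def base_flow_coarse(ci_bundle, coarse_grid):
    """Stokes solution at omega = 1 rad/s, rescalable to any frequency."""
    return solve_flow(coarse_grid, ci_bundle.micro, 1.0)
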