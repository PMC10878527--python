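import numpy as np
import pytest

from vegfr_trafficking import (
    expand_reactions,
    reference_parameters,
    solve_production_rates,
)


@pytest.fixture(scope="session")
def network():
    return expand_reactions()


@pytest.fixture(scope="session")
def reference_params(network):
    """Reference trafficking/coupling defaults with production rates solved
    so steady-state surface counts hit the published densities."""
    params = reference_parameters()
    production, state = solve_production_rates(params, network, return_state=True)
    return params.with_values(production)


@pytest.fixture(scope="session")
def reference_steady_state(network, reference_params):
    from vegfr_trafficking import steady_state

    return steady_state(reference_params, network)


def linear_trafficking_matrix(params, receptor: str) -> np.ndarray:
    """Independently assembled 3-compartment generator for one receptor's
    pooled counts (surface, Rab4, Rab11), straight from the trafficking
    topology: surface -> Rab4 (k_int); Rab4 -> surface (k_rec4), Rab4 ->
    Rab11 (k_4to11), Rab4 -> degraded (k_deg); Rab11 -> surface (k_rec11).
    """
    kint = params[f"k_int_{receptor}"]
    krec4 = params[f"k_rec4_{receptor}"]
    k411 = params[f"k_4to11_{receptor}"]
    krec11 = params[f"k_rec11_{receptor}"]
    kdeg = params[f"k_deg_{receptor}"]
    return np.array(
        [
            [-kint, krec4, krec11],
            [kint, -(krec4 + k411 + kdeg), 0.0],
            [0.0, k411, -krec11],
        ]
    )
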