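import numpy as np
import pytest
from hypothesis import settings

from isd3.config import (
    GridSpec,
    InitialDistribution,
    MediaSpec,
    ParticleSpec,
    SystemConfig,
)
from isd3.presets import preset
from isd3.solver import simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_runs():
    """The four calibrated silver scenarios, run once for the whole suite."""
    return {
        name: simulate(preset(name))
        for name in ("ag20_1", "ag20_12.5", "ag110_0.7", "ag110_9.15")
    }


@pytest.fixture()
def small_cfg():
    """Fast, geometrically consistent column (V = L*A exactly): 1 mm deep,
    200 cells, 20 nm protein-coated silver."""
    return SystemConfig(
        media=MediaSpec(L=1e-3, V=0.1, T=310.0, mu=7.4e-4, rho_f=1.0,
                        A=1e-4, P0=10.0),
        particle=ParticleSpec(Dp1=20.0, rho_p1=10.0, state="protein_coated",
                              dRc=12.0, rho_pc=1.583, Dmin=10.0, C0=1.0),
        grid=GridSpec(dx=1e-3 / 200, dDp=1.0, t_max=10.0,
                      output_times=[5.0, 10.0]),
        init=InitialDistribution(kind="delta"),
    )


@pytest.fixture()
def frozen_coeffs():
    """Factory for overridden transport coefficients."""
    from isd3.transport import TransportCoefficients

    def make(dp_nodes, D=0.0, V=0.0):
        dp_nodes = np.asarray(dp_nodes, dtype=float)
        return TransportCoefficients(
            dp_nodes=dp_nodes,
            dpc_nodes=dp_nodes,
            D_diff=np.full(dp_nodes.size, float(D)),
            V_t=np.full(dp_nodes.size, float(V)),
            Pe=np.zeros(dp_nodes.size),
        )

    return make
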