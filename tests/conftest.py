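import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cestarex.bmc import build_generator, equilibrium_magnetization
from cestarex.pools import Pool, PoolSystem, SaturationProtocol


def ode_zvalue(system, protocol, offset, rtol=1e-9, atol=1e-11, t=None):
    """Independent oracle: adaptive-step integration of the affine system."""
    A, b = build_generator(system, protocol, offset)
    m0 = equilibrium_magnetization(system)
    t_end = protocol.t_sat if t is None else t
    sol = solve_ivp(
        lambda _, y: A @ y + b,
        (0.0, t_end),
        m0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        jac=lambda _, y: A,
    )
    assert sol.success
    return float(sol.y[2, -1])


def random_system_and_protocol(rng):
    """One random physiological pool system + CW protocol draw."""
    n_solutes = int(rng.integers(1, 4))
    pools = [Pool("water", 0.0, 1.0, 0.0, rng.uniform(1, 3), rng.uniform(0.03, 1))]
    for j in range(n_solutes):
        pools.append(
            Pool(
                f"p{j}",
                rng.uniform(-4, 4),
                rng.uniform(1e-4, 5e-3),
                rng.uniform(10, 6000),
                rng.uniform(0.5, 2),
                rng.uniform(1e-5, 0.05),
            )
        )
    protocol = SaturationProtocol(
        b1_amp=rng.uniform(0.5, 8.5),
        t_sat=rng.uniform(0.5, 6.1),
        tr=8.0,
        offsets=(0.0,),
    )
    return PoolSystem(tuple(pools)), protocol, float(rng.uniform(-8, 8))


@pytest.fixture
def water_only():
    return PoolSystem((Pool("water", 0.0, 1.0, 0.0, 2.0, 0.05),))


@pytest.fixture
def two_pool():
    return PoolSystem(
        (
            Pool("water", 0.0, 1.0, 0.0, 2.0, 0.05),
            Pool("amine", 3.0, 3e-4, 5500.0, 1.0, 0.01),
        )
    )


@pytest.fixture
def short_protocol():
    return SaturationProtocol(
        b1_amp=5.9, t_sat=1.0, tr=5.0, offsets=tuple(np.linspace(-8, 8, 17))
    )
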