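import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def change_study_result():
    """Shared non-penetration change-statistics ensemble (expensive)."""
    from fibergen.studies import nonpenetration_change_study

    return nonpenetration_change_study(seed=10)


@pytest.fixture(scope="session")
def pore_study_result():
    """Shared pore-scaling ensemble (expensive)."""
    from fibergen.studies import pore_scaling_study

    return pore_scaling_study(seed=20)


@pytest.fixture(scope="session")
def small_network():
    """A reusable ~50-fiber network with mild anisotropy and tortuosity."""
    import math

    from fibergen.distributions import (
        VPKernel,
        VPParams,
        lognormal_params_from_moments,
    )
    from fibergen.network import NetworkSpec, build_network

    df, lf, phi, nf = 1.0, 12.0, 0.15, 50
    L = (nf * math.pi * lf * df**2 / (4 * phi)) ** (1 / 3)
    spec = NetworkSpec(
        box_length=L,
        volume_fraction=phi,
        diameter_mean=df,
        diameter_std=0.12,
        length_mean=lf,
        length_std=1.5,
        orientation=VPParams((VPKernel([0.0, 0.0, 1.0], 3.0),)),
        tortuosity=lognormal_params_from_moments(1.25, 0.1),
        seed=42,
    )
    return build_network(spec)
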