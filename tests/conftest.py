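import numpy as np
import pytest

import predib as pb


@pytest.fixture(scope="session")
def sddho_half():
    """Reference oscillator joint: zeta = 1/2, dt = 1."""
    return pb.sddho_joint(pb.SDDHOParams(zeta=0.5, dt_pred=1.0))


@pytest.fixture(scope="session")
def wf_low():
    """Low-mutation Wright-Fisher joint (N=100, Nmu=0.2, Ns=0.001, dt=1)."""
    return pb.wf_joint(pb.WFParams(n_mu=0.2))


@pytest.fixture(scope="session")
def wf_high():
    """High-mutation Wright-Fisher joint (Nmu=20)."""
    return pb.wf_joint(pb.WFParams(n_mu=20.0))


@pytest.fixture(scope="session")
def scalar_joint():
    """1-D Gaussian pair with correlation rho = 0.8, unit variances."""
    return pb.JointGaussian(sigma_past=[[1.0]], sigma_future=[[1.0]],
                            sigma_cross=[[0.8]])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
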