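import pytest

from granulosim import DetailedParams, MinimalParams, default_reference_scales


@pytest.fixture(scope="session")
def base_detailed():
    return DetailedParams()


@pytest.fixture(scope="session")
def sarcoid_params():
    """Base table with the raised Treg IL-2 sensitivity used by the
    canonical switching protocol."""
    return DetailedParams().with_(k_2a=2.1)


@pytest.fixture(scope="session")
def fig1_params():
    """Minimal-model parameters of the published antigen-threshold panel."""
    return MinimalParams(theta_T=1.0, beta_T=0.02, eps_T=1.0,
                         eta1=1.0, eta2=1.0, c=3.0)


@pytest.fixture(scope="session")
def scales():
    return default_reference_scales()
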