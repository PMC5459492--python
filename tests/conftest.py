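import pytest

from cprsim import SchaeferParams


@pytest.fixture
def params() -> SchaeferParams:
    """Default bioeconomic parameters used throughout the suite.

    mu_R=0.1/s, K=100, q=0.01, p=1, c=0.1, E_max=10, N=5 — the reference
    configuration: MSY effort 5, MSY 2.5/s, half-capacity equilibrium 50.
    """
    return SchaeferParams()
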