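import numpy as np
import pytest

from gdeastem import (
    DMUPanel,
    GDEAConfig,
    hospital_panel,
    hospital_panel_normalized,
)


@pytest.fixture(scope="session")
def raw_hospitals() -> DMUPanel:
    return hospital_panel()


@pytest.fixture(scope="session")
def norm_hospitals() -> DMUPanel:
    return hospital_panel_normalized()


@pytest.fixture(scope="session")
def fdh_zero() -> GDEAConfig:
    """FDH preset under the convention that reproduces the published table."""
    return GDEAConfig.fdh(dtilde_convention="zero")


@pytest.fixture
def tiny_panel() -> DMUPanel:
    """Two units; unit 2 strictly dominates unit 1."""
    return DMUPanel(
        labels=("1", "2"),
        inputs=np.array([[4.0], [3.0]]),
        outputs=np.array([[3.0], [4.0]]),
    )
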