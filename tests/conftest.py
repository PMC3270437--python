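import numpy as np
import pytest

from lipidpbtk import (
    DEFAULT_CONGENERS,
    HierarchicalParams,
    InductionParams,
    RatCovariates,
    default_nle_physiology,
)


@pytest.fixture(scope="session")
def phys():
    return default_nle_physiology()


@pytest.fixture(scope="session")
def congeners():
    return DEFAULT_CONGENERS


@pytest.fixture(scope="session")
def v0_medians():
    return np.array([c.v0 for c in DEFAULT_CONGENERS])


@pytest.fixture(scope="session")
def induction():
    return InductionParams()


@pytest.fixture
def grown_rat():
    """Median rat growing 225 -> 360 g over 90 days."""
    return RatCovariates(
        initial_body_weight=225.0,
        final_body_weight=360.0,
        sacrifice_day=90,
        liver_weight_ratio=0.04,
    )


@pytest.fixture
def static_rat():
    """Constant-weight rat (keeps the disposition system time-invariant)."""
    return RatCovariates(
        initial_body_weight=225.0,
        final_body_weight=225.0,
        sacrifice_day=90,
        liver_weight_ratio=0.04,
    )


@pytest.fixture(scope="session")
def reference_pop():
    return HierarchicalParams.reference()
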