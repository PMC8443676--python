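import numpy as np
import pytest

from plasmidsim import (
    CommunityParams,
    ConjugationParams,
    EpistasisSpec,
    TransformationParams,
)


@pytest.fixture
def chemostat_conjugation():
    """Baseline conjugative chemostat (the main-text phase-diagram setting)."""
    return ConjugationParams(delta=0.1, S=1.0, alpha=1.0, p_ell=0.0)


@pytest.fixture
def chemostat_transformation():
    """Baseline transformative chemostat with sub-unity plasmid release."""
    return TransformationParams(
        delta=0.1, S=1.0, alpha=1.0, p_ell=0.0, n_eff=0.6, delta_p=0.3
    )


@pytest.fixture
def community_eight_types():
    """Eight identical conjugative plasmid types at unit death rate."""
    return CommunityParams(
        m=8, Delta=0.1, gamma_c=0.0, p_ell=0.05, delta=1.0, S=1.0, alpha=1.0
    )


@pytest.fixture
def positive_epistasis():
    return EpistasisSpec(form="positive", Delta=0.01)


@pytest.fixture
def no_epistasis():
    return EpistasisSpec(form="none", Delta=0.01)


@pytest.fixture
def negative_epistasis():
    return EpistasisSpec(form="negative", Delta=0.01)
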