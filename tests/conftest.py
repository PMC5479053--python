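import numpy as np
import pytest

import repfid as rf


@pytest.fixture
def identical_alleles():
    """Kinetically identical alleles with stationary mean 50 each."""
    return rf.AlleleKinetics.from_means(50.0, 50.0)


@pytest.fixture
def gamma_model(identical_alleles):
    """High-dispersion Gamma regulator (mean 1, Fano factor 0.5)."""
    return rf.JointCountModel(
        kinetics=identical_alleles, regulator=rf.RegulatorDistribution.gamma(2.0, 0.5)
    )


@pytest.fixture
def feedback_at_risk():
    """Kinetics realizing α = 0.02, γ_wt = 0.35 (H = 2): bistable wild type,
    monostable after the knock-in doubling of γ."""
    return rf.FeedbackParams(
        basal_rate=0.02, feedback_max_rate=1.0, decay_rate=1.0, half_max=0.7, hill_coeff=2
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
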