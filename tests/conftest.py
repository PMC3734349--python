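import numpy as np
import pytest

from rtdcm.models import attention_pair, validate
from rtdcm.synth import make_design


@pytest.fixture(scope="session")
def pair_skeletons():
    m_al, m_ar = attention_pair()
    return validate(m_al), validate(m_ar)


@pytest.fixture(scope="session")
def trial_design():
    """Single aL neurofeedback trial (155 scans, window = first 90)."""
    return make_design("neurofeedback", n_trials=1)


@pytest.fixture(scope="session")
def localizer_design():
    """Single-condition (aL) localizer run of 210 scans."""
    return make_design("localizer")
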