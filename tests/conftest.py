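import numpy as np
import pytest
from hypothesis import settings as hsettings

hsettings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
hsettings.load_profile("ci")


@pytest.fixture(scope="session")
def pk_dataset():
    from topaug.casestudies import pk_generate
    return pk_generate(seed=7)


@pytest.fixture(scope="session")
def gln_dataset():
    from topaug.casestudies import gln_generate
    return gln_generate(seed=7)


@pytest.fixture(scope="session")
def gln_opts():
    from topaug.ekf import EKFOptions
    return EKFOptions(max_step=1.0)
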