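import numpy as np
import pytest

from grnsets import default_true_params, named_models, wild_type_family
from grnsets.synth import DESIGN_TIMES


@pytest.fixture(scope="session")
def wt_family():
    return wild_type_family()


@pytest.fixture(scope="session")
def reference_models():
    return named_models()


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def design_times():
    return np.asarray(DESIGN_TIMES)
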