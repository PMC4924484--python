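import numpy as np
import pytest

from crykinetics.spectra import ExtinctionSet
from crykinetics.synthetic import SyntheticConfig


@pytest.fixture
def cry2_config():
    """Flagship in vitro condition: cry2 at pH 7.5, noiseless."""
    return SyntheticConfig()


@pytest.fixture
def cry2_eps():
    return ExtinctionSet.from_molar_cm(5094.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
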