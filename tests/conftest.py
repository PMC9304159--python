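import numpy as np
import pytest

from oxoscope.masses import ISOTOPES
from oxoscope.synthetic_data import HarmonicPrescription, gen_harmonic_system


@pytest.fixture(scope="session")
def feo_record():
    """Diatomic 56Fe-16O with its stretch tuned to 860 cm^-1."""
    presc = HarmonicPrescription(
        masses=[ISOTOPES["Fe56"], ISOTOPES["O16"]],
        wavenumbers=[860.0],
        elements=["Fe", "O"],
        label="FeO_860",
    )
    return gen_harmonic_system(presc, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
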