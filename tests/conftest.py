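import pytest

from fabsec.chromatogram import default_calibration
from fabsec.species import SpeciesClass
from fabsec.synth import GeneratorConfig


@pytest.fixture
def cfg():
    return GeneratorConfig(seed=7)


@pytest.fixture
def calibration():
    return default_calibration()


@pytest.fixture
def complex_window(calibration):
    return next(w for w in calibration if w.species_class == SpeciesClass.DRUG_FAB)
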