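import numpy as np
import pytest

from triquant.quantitation import build_calibration_lines
from triquant.simulate import default_library, make_pure_spectrum


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def lines(library):
    """Noiseless calibration lines at 359 / 315 / 260.5 nm."""
    return build_calibration_lines(library)


@pytest.fixture(scope="session")
def pure_aml_10(library):
    """Pure AML standard at 10 ug/mL, the ratio-subtraction divisor stock."""
    return make_pure_spectrum(library["AML"], 10.0)
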