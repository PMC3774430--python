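import pytest

from ehi import default_corrected_params
from ehi import reference as ref


@pytest.fixture(scope="session")
def params():
    """The built-in corrected calibration."""
    return default_corrected_params()


@pytest.fixture(scope="session")
def national_ehi():
    """The 25 published per-industry EHI statistics."""
    return [v for *_, v in ref.NATIONAL_INDUSTRIES]
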