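import pytest

from chocrisk import ToxicologyConstants
from chocrisk.synthetic import builtin_study_fixture


@pytest.fixture(scope="session")
def consts() -> ToxicologyConstants:
    return ToxicologyConstants()


@pytest.fixture(scope="session")
def study():
    """The built-in 150-sample synthetic study bundle at a fixed seed."""
    return builtin_study_fixture(seed=1)
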