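import pytest
from hypothesis import settings

from fractionato import parse_code_string, reduce_region

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")
from fractionato.datasets import WORKED_EXAMPLE_RAW_CODE


@pytest.fixture(scope="session")
def worked_region():
    """The published 13-gene worked-example stretch, parsed raw."""
    return parse_code_string(WORKED_EXAMPLE_RAW_CODE, region_id="Sb2-stretch")


@pytest.fixture(scope="session")
def worked_region_reduced(worked_region):
    return reduce_region(worked_region)
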