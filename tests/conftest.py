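import pytest

from rxnunify.examples import bundled_example_dumps
from rxnunify.merge_export import run_integration


@pytest.fixture(scope="session")
def example_dumps():
    return bundled_example_dumps()


@pytest.fixture(scope="session")
def example_result(example_dumps):
    return run_integration(example_dumps)
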