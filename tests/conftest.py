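import pytest

from oreganokg.manager import build_graph
from oreganokg.synth import FixtureConfig, generate_suite


@pytest.fixture(scope="session")
def suite(tmp_path_factory):
    """The default synthetic source suite (full hub density, no xref noise)."""
    out = tmp_path_factory.mktemp("suite")
    manifest, gt = generate_suite(FixtureConfig(seed=1), out)
    return manifest, gt


@pytest.fixture(scope="session")
def built(suite):
    """The suite run through the full wrapper -> binder -> manager pipeline."""
    manifest, gt = suite
    return build_graph(manifest), gt
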