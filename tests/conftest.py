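from pathlib import Path

import pytest

from rcdprofiler import parse_rules_config

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_rules():
    return parse_rules_config()


@pytest.fixture(scope="session")
def rules_by_id(default_rules):
    return {r.family_id: r for r in default_rules}


@pytest.fixture()
def toy_manifest_path():
    return DATA / "toy_manifest.tsv"
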