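import pytest
from importlib import resources

from fairledger.fixtures import FixtureSpec, generate_corpus
from fairledger.platform import Platform
from fairledger.schema import DUBLIN_CORE_ELEMENTS, MetadataRecord

TOPOLOGY_PATH = resources.files("fairledger") / "topologies" / "reference.yaml"

ALICE = ("alice", "alginate-fiber")  # admin, org-oslo
BOB = ("bob", "collagen-gel")  # org-london


@pytest.fixture
def platform() -> Platform:
    """Fresh reference consortium: 3 orgs, 2 EVC nodes each, 9 storage nodes."""
    return Platform.from_topology_file(TOPOLOGY_PATH)


@pytest.fixture
def corpus():
    """Ten valid fiber-experiment records with payloads, fixed seed."""
    return generate_corpus(FixtureSpec(seed=7, n_records=10))


def dublin_record(**overrides) -> MetadataRecord:
    """A fully populated base-template record; keyword args override fields."""
    values = {name: f"value of {name.lower()}" for name in DUBLIN_CORE_ELEMENTS}
    values["Date"] = "2021-06-15"
    values["Language"] = "en"
    values.update(overrides)
    for key in [k for k, v in values.items() if v is None]:
        del values[key]
    return MetadataRecord(template_id="dublin-core", values=values)
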