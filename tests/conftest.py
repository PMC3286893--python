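import pytest

from l1diversity.simulate import (
    ComponentSpec,
    SimulationConfig,
    SubfamilySpec,
    default_config,
    simulate_family,
)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down three-subfamily family for fast end-to-end tests."""
    components = [
        ComponentSpec("5UTR", 300, relative_rate=1.8, cpg_density=3.0),
        ComponentSpec("ORF1", 400, relative_rate=1.0, cpg_density=1.0),
        ComponentSpec("ORF2", 500, relative_rate=1.0, cpg_density=0.5),
        ComponentSpec("3UTR", 200, relative_rate=1.4, cpg_density=0.8),
    ]
    subfamilies = [
        SubfamilySpec("young", 20, 2.0, diagnostic_subs=[(800, "T")]),
        SubfamilySpec("mid", 25, 5.0, diagnostic_subs=[(800, "T"), (850, "A")]),
        SubfamilySpec("old", 30, 10.0, diagnostic_subs=[(800, "T"), (850, "A"), (900, "C")]),
    ]
    return SimulationConfig(
        components=components, subfamilies=subfamilies, cpg_rate_multiplier=1.0, seed=11
    )


@pytest.fixture(scope="session")
def small_family(small_config):
    return simulate_family(small_config)


@pytest.fixture(scope="session")
def default_family():
    """The full six-subfamily study configuration, CpG clock disabled."""
    return simulate_family(default_config(seed=5, cpg_rate_multiplier=1.0))
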