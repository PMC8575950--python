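import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ltmob import GenomeSpec, MarkerPlacement, ProphageModel, generate_toy_genome
from ltmob.fixture import paper_fixture


@pytest.fixture(scope="session")
def fixture_tables():
    return paper_fixture()


@pytest.fixture(scope="session")
def toy_spec():
    return GenomeSpec(
        length=60_000,
        n_orfs=30,
        accessory_fraction=0.3,
        attb_layout=[(0.2, +1), (0.7, -1)],
        markers=[
            MarkerPlacement("attB1", headful=3, offset=1000),
            MarkerPlacement("attB2", headful=2, offset=500),
        ],
        prophage=ProphageModel("toyphage", headful_size=8_000, n_max=5),
        seed=7,
        genome_id="toy60k",
    )


@pytest.fixture(scope="session")
def toy_genome(toy_spec):
    genome, _ = generate_toy_genome(toy_spec)
    return genome
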