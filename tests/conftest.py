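import pytest

from sparqlfed import TopologyConfig, generate, parse_query, worked_example_fixture
from sparqlfed.synthetic import WORKED_EXAMPLE_QUERY


@pytest.fixture(scope="session")
def worked_fed():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_query():
    return parse_query(WORKED_EXAMPLE_QUERY)


@pytest.fixture(scope="session")
def small_fed():
    """A compact generated federation (5 datasets) for fast per-test use."""
    return generate(TopologyConfig(n_datasets=5, instances_per_class=12, seed=11))


THREE_PATTERN_QUERY = """
PREFIX drugbank: <http://bio2rdf.example/ns/drugbank#>
PREFIX diseasome: <http://bio2rdf.example/ns/diseasome#>
SELECT ?drug ?name WHERE {
  ?drug drugbank:molecularWeightAverage ?weight .
  ?drug drugbank:possibleDiseaseTarget ?disease .
  ?disease diseasome:name ?name .
}
"""


@pytest.fixture(scope="session")
def three_pattern_query():
    return parse_query(THREE_PATTERN_QUERY)
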