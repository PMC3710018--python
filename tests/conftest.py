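import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from taxcomp import SpeciesPartition, SpecimenUniverse, TaxonomyCollection


def make_partition(name, clusters, universe=None):
    """Build a partition from {label: iterable of specimen ids}."""
    assignment = {s: lab for lab, members in clusters.items() for s in members}
    if universe is None:
        universe = SpecimenUniverse(tuple(assignment))
    return SpeciesPartition(method_name=name, universe=universe, assignment=assignment)


def cluster_sets(p):
    """Label-agnostic view of a partition: set of frozensets."""
    return set(p.cluster_sets())


@pytest.fixture
def abcd():
    """Shared 4-specimen universe used by the toy examples."""
    return SpecimenUniverse(("a", "b", "c", "d"))


@pytest.fixture
def fixture_bundle():
    from taxcomp import load_fixture

    return load_fixture("madascincus")
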