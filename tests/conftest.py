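import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from remhom import (
    DomainDatabase,
    DomainRecord,
    HierarchySpec,
    SignalSpec,
    generate_embeddings,
    generate_hierarchy,
    parse_sccs,
)


def make_record(domain_id: str, sccs: str, sequence: str = "MKVLA", **kwargs) -> DomainRecord:
    return DomainRecord(domain_id, parse_sccs(sccs), sequence, **kwargs)


@pytest.fixture
def enumeration_db() -> DomainDatabase:
    """Two superfamilies in one fold plus one in another fold.

    SF a.1.1 = {family a.1.1.1: query + 2 siblings, family a.1.1.2: 2 domains},
    SF b.2.1 = {family b.2.1.1: 4 domains}.  For the first query at
    superfamily level: 2 positives, 4 negatives, 2 excluded siblings.
    """
    records = [
        make_record("q0", "a.1.1.1"),
        make_record("s1", "a.1.1.1"),
        make_record("s2", "a.1.1.1"),
        make_record("p1", "a.1.1.2"),
        make_record("p2", "a.1.1.2"),
        make_record("n1", "b.2.1.1"),
        make_record("n2", "b.2.1.1"),
        make_record("n3", "b.2.1.1"),
        make_record("n4", "b.2.1.1"),
    ]
    return DomainDatabase(tuple(records))


@pytest.fixture(scope="session")
def toy_hierarchy() -> DomainDatabase:
    """Balanced 4 folds x 2 SFs x 2 families x 5 domains database (80 domains)."""
    return generate_hierarchy(HierarchySpec(4, 2, 2, 5, seed=11))


@pytest.fixture(scope="session")
def strong_signal_store(toy_hierarchy):
    return generate_embeddings(
        toy_hierarchy,
        SignalSpec(dim=16, superfamily_weight=1.0, noise_sd=0.1, seed=5),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)
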