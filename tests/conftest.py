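"""Shared fixtures: seeded synthetic databases and query bundles.

All randomness is seeded so the suite is deterministic; the heavier
fixture database is session-scoped because searches against it are
reused across modules.
"""

import pytest

from kscan import FixtureSpec, make_queries, make_reference
from kscan.simulate import make_controls


@pytest.fixture(scope="session")
def fixture_db():
    """Default-scale synthetic reference database (5 classes x 8)."""
    db, truth = make_reference(FixtureSpec(seed=11))
    return db, truth


@pytest.fixture(scope="session")
def small_db():
    """Compact database for fast per-module tests (3 classes x 4, ~120 aa)."""
    spec = FixtureSpec(
        n_classes=3,
        members_per_class=4,
        seq_length_mean=120,
        seq_length_sd=8,
        seed=7,
    )
    db, truth = make_reference(spec)
    return db, truth


@pytest.fixture(scope="session")
def query_bundle(fixture_db):
    db, _ = fixture_db
    return make_queries(db, seed=11)


@pytest.fixture(scope="session")
def control_sets(fixture_db):
    db, _ = fixture_db
    return make_controls(db, seed=11)
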