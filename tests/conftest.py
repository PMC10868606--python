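import numpy as np
import pytest

from bgcnovelty import MembershipMatrix, reference_fixture


@pytest.fixture(scope="session")
def fixture_data():
    """Deterministic 779-BGC benchmark collection (records, matrix,
    catalog, families)."""
    return reference_fixture()


@pytest.fixture
def small_matrix():
    """3 BGCs x 4 GCFs with known ranking structure."""
    return MembershipMatrix(
        ["b1", "b2", "b3"],
        ["g1", "g2", "g3", "g4"],
        np.array(
            [
                [500.0, 300.0, 900.0, 1200.0],
                [500.0, 500.0, 700.0, 100.0],
                [950.0, 1000.0, 1100.0, 1300.0],
            ]
        ),
    )


@pytest.fixture
def small_catalog():
    return {"g1": True, "g2": False, "g3": False, "g4": True}
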