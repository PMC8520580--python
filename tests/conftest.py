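import hypothesis
import pytest

from neutrokw.interval_data import GroupedNeutrosophicData, table1_fixture

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1() -> GroupedNeutrosophicData:
    return table1_fixture()


@pytest.fixture
def small_dataset() -> GroupedNeutrosophicData:
    """Three tiny groups with ties in both components."""
    return GroupedNeutrosophicData.from_items(
        [
            ("a", [(1.0, 2.0), (3.0, 3.0), (5.0, 6.0)]),
            ("b", [(2.0, 2.0), (3.0, 4.0)]),
            ("c", [(0.0, 1.0), (5.0, 5.0), (7.0, 9.0)]),
        ]
    )


def make_grouped(groups):
    """Shorthand: [(label, [(lo, up), ...]), ...] -> GroupedNeutrosophicData."""
    return GroupedNeutrosophicData.from_items(groups)
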