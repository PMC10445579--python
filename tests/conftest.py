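import pytest

from morphosex import builtin_study_tables, estimate_table


@pytest.fixture(scope="session")
def study():
    """(observer table, video table, recorded sexes) — the embedded study data."""
    return builtin_study_tables()


@pytest.fixture(scope="session")
def observer_table(study):
    return study[0]


@pytest.fixture(scope="session")
def video_table(study):
    return study[1]


@pytest.fixture(scope="session")
def recorded(study):
    return study[2]


@pytest.fixture(scope="session")
def observer_estimates(observer_table):
    return estimate_table(observer_table)


@pytest.fixture(scope="session")
def video_estimates(video_table):
    return estimate_table(video_table)
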