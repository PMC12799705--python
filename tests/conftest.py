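import pytest

import dentage as d


@pytest.fixture(scope="session")
def kosovo():
    return d.kosovo_tables()


@pytest.fixture(scope="session")
def score_table(kosovo):
    return kosovo.score_table


@pytest.fixture
def all_h_chart():
    return d.DentalChart.from_sequence(["H"] * 7)


def _subject(i, sex, age, stages):
    return d.Subject(
        id=f"s{i}", sex=sex, chronological_age=age,
        chart=d.DentalChart.from_sequence(stages),
    )


@pytest.fixture(scope="session")
def small_cohort(kosovo):
    """A modest synthetic cohort for calibration/evaluation machinery tests."""
    cfg = d.SimulationConfig(seed=1234, n_per_bin=30)
    return d.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_estimates(small_cohort, kosovo):
    return d.estimate_cohort(small_cohort, kosovo)


@pytest.fixture
def make_subject():
    return _subject
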