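import pytest
from hypothesis import HealthCheck, settings

from reportfit.corpus import Corpus, Report
from reportfit.synthetic import GeneratorConfig, load_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Hand-authored 6-report, 3-category corpus with known token counts."""
    return Corpus(
        [
            Report("f1", "fall", "Patient fell near the bed. Nurse notified."),
            Report("f2", "fall", "Pt fell twice this morning."),
            Report("m1", "med", "Wrong dose of heparin given."),
            Report("m2", "med", "Heparin drip was paused. Pharmacy called about the dose."),
            Report("s1", "skin", "Pressure ulcer noted on admission."),
            Report("s2", "skin", "Stage two ulcer on the left heel."),
        ]
    )


@pytest.fixture(scope="session")
def fixture_corpus():
    return load_fixture()


@pytest.fixture
def small_config() -> GeneratorConfig:
    """A fast generator config for tests that need fresh corpora."""
    return GeneratorConfig(reports_per_category=30, seed=7734)
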