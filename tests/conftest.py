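import numpy as np
import pytest

from hbqc import CorpusSpec, Group, generate_corpus, summarize_survey
from hbqc.distribution_stats import SurveyStats


@pytest.fixture(scope="session")
def small_corpus():
    """A seeded 40-site paired corpus (80 surveys) at the default
    hyper-parameters, shared across tests that only read it."""
    return generate_corpus(CorpusSpec(n_surveys=40, seed=11))


@pytest.fixture(scope="session")
def small_corpus_stats(small_corpus):
    return [summarize_survey(s) for s in small_corpus]


def make_stats(
    survey_id="S1",
    group=Group.CHILD,
    n=400,
    mean=11.1,
    median=11.2,
    sd=1.34,
    skew=-0.38,
    kurt=0.55,
    anemia=43.5,
    flag_pct=0.08,
    country="C00",
):
    """Hand-constructed survey summary for rule-engine and corpus tests."""
    return SurveyStats(
        survey_id=survey_id, group=group, n=n, mean_gdl=mean,
        median_gdl=median, sd_gdl=sd, skewness_g1=skew, kurtosis_g2=kurt,
        anemia_pct=anemia, flag_pct=flag_pct, country=country,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
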