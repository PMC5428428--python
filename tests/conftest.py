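import pytest

from glyhome import cohort as ch
from glyhome.fooddb import demo_catalog
from glyhome.pipeline import RunConfig, build_analysis_table


@pytest.fixture(scope="session")
def catalog():
    return demo_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """n=400 cohort at the default (calibrated) configuration."""
    return ch.generate(ch.CohortConfig(n=400), seed=7)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Analysis-ready table for the small cohort (tier-3 columns present)."""
    df, flow = build_analysis_table(small_cohort, RunConfig(tiers=(3,)))
    return df


@pytest.fixture(scope="session")
def medium_analysis():
    """n=1200 analysis table, for model tests needing more stability."""
    cohort = ch.generate(ch.CohortConfig(n=1200), seed=11)
    df, _ = build_analysis_table(cohort, RunConfig(tiers=(3,)))
    return df
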