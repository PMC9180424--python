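import pytest

from hazetol import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    """Desk-scale study conditions: 3 regions, 3 winters, 30 days each."""
    return sd.SimConfig(
        n_regions=3,
        years=(2013, 2014, 2015),
        season_days=30,
        pm25_region_means=(90.0, 75.0, 60.0),
        posts_per_day_base=4.0,
        n_train_docs=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> sd.SyntheticBundle:
    return sd.generate_bundle(small_config)
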