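import numpy as np
import pytest

from polythresh.simulate import archetype_config, generate_population


@pytest.fixture(scope="session")
def uncensored_twoclass_records():
    """One two-class site with every man past the completion age.

    theta=0.2, m_r=6 implies a completed-wealth Gini of 0.4 and proportion
    rich (phi=0.5) of 0.2; no age censoring, so observed == completed.
    """
    cfg = archetype_config(
        "horticulture",
        "tc_site",
        n_males=500,
        wealth=__import__("polythresh").TwoClassWealth(theta=0.2, m_r=6.0),
        age_min=60,
        age_max=80,
    )
    return generate_population(cfg, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
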