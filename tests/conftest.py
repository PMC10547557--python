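import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from reefnutro import simulate, survey, traits

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rni():
    return traits.default_rni()


@pytest.fixture(scope="session")
def small_study():
    """A compact multi-country synthetic study shared across tests."""
    cfg = simulate.SimulationConfig(
        seed=11, n_countries=3, sites_per_country=12, species_pool_size=120
    )
    return simulate.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_cleaned(small_study):
    cleaned, log = survey.ingest(
        small_study["survey"], small_study["sites"], small_study["traits"],
        small_study["transects"],
    )
    return cleaned, log


@pytest.fixture()
def toy_traits():
    """Six hand-written species covering the exclusion-filter taxa."""
    rows = []
    base = dict(l_max_cm=30.0, k_max=0.8, lw_a=0.01, lw_b=3.0,
                ca_mg=30.0, fe_mg=0.8, zn_mg=1.0, se_ug=40.0, vita_ug=25.0, om3_g=0.2,
                is_damselfish=False, is_elasmobranch=False)
    for sid, group, extra in [
        ("wrasse", "mobile_invertivore", {}),
        ("parrotfish", "herbivore_scraper_detritivore", {"l_max_cm": 45.0}),
        ("grouper", "piscivore", {"l_max_cm": 80.0, "k_max": 0.3}),
        ("damsel", "planktivore", {"l_max_cm": 10.0, "is_damselfish": True}),
        ("shark", "piscivore", {"l_max_cm": 200.0, "k_max": 0.1, "is_elasmobranch": True}),
        ("surgeonfish", "herbivore_browser", {"l_max_cm": 35.0}),
    ]:
        rows.append({"species_id": sid, "trophic_group": group, **{**base, **extra}})
    return traits.load_traits(pd.DataFrame(rows)[traits.TRAIT_COLUMNS])


@pytest.fixture()
def toy_survey():
    """Six observations: one per exclusion rule plus three valid rows."""
    return pd.DataFrame({
        "site_id": ["s1"] * 6,
        "transect_id": ["t1"] * 6,
        "species_id": ["wrasse", "damsel", "shark", "parrotfish", "grouper", "surgeonfish"],
        "length_cm": [4.0, 10.0, 80.0, 25.0, 60.0, 18.0],
        "length_is_binned": [False] * 6,
        "count": [1, 1, 1, 2, 1, 3],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
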