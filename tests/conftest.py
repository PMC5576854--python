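import numpy as np
import pandas as pd
import pytest

import tempdiv as td


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """Ten hand-written survey rows: 2 plots x 2 dates, mixed methods/levels."""
    rows = [
        # plot_id, treatment, year, jd, method, species_id, count, id_level
        ("P1", "reserve", 2011, 100, "bowl", "spA", 3, "species"),
        ("P1", "reserve", 2011, 100, "bowl", "spB", 1, "species"),
        ("P1", "reserve", 2011, 100, "net", "spC", 2, "species"),
        ("P1", "reserve", 2011, 130, "bowl", "spA", 2, "species"),
        ("P1", "reserve", 2011, 130, "bowl", "spD", 4, "morphospecies"),
        ("P2", "fragment", 2011, 100, "bowl", "spA", 5, "species"),
        ("P2", "fragment", 2011, 100, "bowl", "spE", 1, "genus_only"),
        ("P2", "fragment", 2011, 130, "bowl", "spB", 2, "species"),
        ("P2", "fragment", 2011, 130, "bowl", "spF", 6, "species"),
        ("P2", "fragment", 2011, 130, "net", "spG", 1, "genus_only"),
    ]
    return pd.DataFrame(rows, columns=td.data_model.SURVEY_COLUMNS)


@pytest.fixture
def toy_traits() -> pd.DataFrame:
    rows = [
        ("spA", "generalist", True, "gA"),
        ("spB", "specialist", True, "gA"),
        ("spC", "generalist", True, "gB"),
        ("spD", "parasitic", True, "gB"),
        ("spE", "unknown", True, "gC"),
        ("spF", "generalist", False, "gC"),
        ("spG", "unknown", True, "gD"),
    ]
    return pd.DataFrame(rows, columns=td.data_model.TRAIT_COLUMNS)


@pytest.fixture(scope="session")
def small_sim():
    """A small but full-featured simulated survey (6 plots x 6 samples)."""
    cfg = td.scenario_preset(
        "paper_like_2011", seed=42, n_plots_reserve=3, n_plots_fragment=3,
        n_samples=6, species_pool_size=80,
    )
    return td.simulate_survey(cfg)


@pytest.fixture(scope="session")
def sim_matrix():
    """Analysis-ready matrix for a neutral field-design preset (session cache)."""
    cfg = td.scenario_preset("paper_like_2011", seed=7)
    matrix, traits, truth = td.simulate_matrix(cfg)
    return matrix, traits, truth
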