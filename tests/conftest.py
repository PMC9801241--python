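import numpy as np
import pandas as pd
import pytest

from droughtmob.synth import (
    WeatherGenSpec,
    gen_adjacency,
    gen_daily_weather,
)
from droughtmob.weather import add_neighbor_dry, aggregate_all_seasons, classify_panel


@pytest.fixture(scope="session")
def mini_weather():
    """Small synthetic weather set: 5 communities, 3 states, 1980-2000."""
    spec = WeatherGenSpec(n_communities=5, n_states=3, years=(1980, 2000), seed=11)
    daily, communities = gen_daily_weather(spec)
    return daily, communities


@pytest.fixture(scope="session")
def mini_categories(mini_weather):
    daily, communities = mini_weather
    seasons = aggregate_all_seasons(
        daily, dict(zip(communities["community_id"], communities["state"]))
    )
    adjacency = gen_adjacency(5, seed=11, avg_neighbors=2.0)
    cats = add_neighbor_dry(classify_panel(seasons), adjacency)
    return seasons, cats, adjacency, communities
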