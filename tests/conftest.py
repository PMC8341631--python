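from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from odtcube import SourceRules, synth
from odtcube.cube import ODTCube


@pytest.fixture(scope="session")
def cfg():
    """Standing synthetic study conditions (60 walkers, 30 days, 12x12 grid)."""
    return synth.SynthConfig(seed=11)


@pytest.fixture(scope="session")
def geo(cfg):
    return synth.make_geography(cfg)


@pytest.fixture(scope="session")
def events_and_truth(cfg, geo):
    return synth.simulate_events(cfg, geo)


@pytest.fixture(scope="session")
def sdm_and_truth(cfg, geo):
    return synth.simulate_sdm(cfg, geo)


@pytest.fixture(scope="session")
def deny_bots(cfg):
    return SourceRules(deny=frozenset(cfg.bot_sources))


def make_random_cube(rng, n_places=8, n_days=6, n_cells=40, level="county", start=date(2020, 3, 1)):
    """Random sparse cube for oracle comparisons (unique cells, cnt >= 1)."""
    places = [f"{10 + i:02d}{i + 1:03d}" for i in range(n_places)]
    n_cells = min(n_cells, n_places * n_places * n_days)  # distinct keys available
    keys = set()
    while len(keys) < n_cells:
        keys.add(
            (
                places[int(rng.integers(n_places))],
                places[int(rng.integers(n_places))],
                start + timedelta(days=int(rng.integers(n_days))),
            )
        )
    rows = []
    for o, d, day in sorted(keys):
        rows.append(
            {
                "o_place": o,
                "d_place": d,
                "day": day,
                "cnt": float(rng.integers(1, 30)),
                "o_lat": 38.0 + float(rng.random()),
                "o_lon": -98.0 + float(rng.random()),
                "d_lat": 38.0 + float(rng.random()),
                "d_lon": -98.0 + float(rng.random()),
            }
        )
    return ODTCube(pd.DataFrame(rows), level=level, source="synthetic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
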