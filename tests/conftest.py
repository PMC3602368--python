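from __future__ import annotations

import numpy as np
import pytest

from reservenet import (
    DistanceMode,
    Site,
    build_graph,
    pairwise_distances,
    worked_fixture,
)


def make_sites(coords, areas=None, future=None, prefix="s"):
    """Build a Site list from (x, y) pairs; areas default to 100 ha."""
    n = len(coords)
    areas = areas if areas is not None else [100.0] * n
    future = future if future is not None else [True] * n
    return [
        Site(
            site_id=f"{prefix}{i}",
            x=float(x),
            y=float(y),
            area_ha=float(areas[i]),
            suitable_current=True,
            suitable_future=bool(future[i]),
        )
        for i, (x, y) in enumerate(coords)
    ]


def random_sites(rng, n, box_km=100.0, area_range=(10.0, 1000.0)):
    coords = rng.uniform(0.0, box_km, size=(n, 2))
    areas = rng.uniform(*area_range, size=n)
    return make_sites(coords, areas)


def graph_of(sites, threshold_km, mode=DistanceMode.CENTROID):
    return build_graph(sites, pairwise_distances(sites, mode), threshold_km)


@pytest.fixture
def fixture_sites():
    return worked_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
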