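"""Shared fixtures: small grids, distance models and toy landscapes."""

from __future__ import annotations

import numpy as np
import pytest

from paleoreef import (
    GreatCircleDistance,
    GridSpec,
    HabitatSlice,
    PaleoLandscape,
)


@pytest.fixture(scope="session")
def spec1() -> GridSpec:
    return GridSpec(1.0)


@pytest.fixture(scope="session")
def spec5() -> GridSpec:
    return GridSpec(5.0)


@pytest.fixture(scope="session")
def gc1(spec1) -> GreatCircleDistance:
    return GreatCircleDistance(spec1)


def box_cells(spec: GridSpec, lon_min, lon_max, lat_min, lat_max) -> np.ndarray:
    """Cell ids whose centroids fall inside the box (closed bounds)."""
    cells = np.arange(spec.n_cells)
    lon, lat = spec.centroids(cells)
    sel = (lon >= lon_min) & (lon <= lon_max) & (lat >= lat_min) & (lat <= lat_max)
    return cells[sel]


def make_slice(spec: GridSpec, age_ma: float, cells, land_cells=None) -> HabitatSlice:
    habitat = np.zeros(spec.n_cells, dtype=bool)
    habitat[np.asarray(list(cells), dtype=int)] = True
    land = None
    if land_cells is not None:
        land = np.zeros(spec.n_cells, dtype=bool)
        land[np.asarray(list(land_cells), dtype=int)] = True
    return HabitatSlice(spec, age_ma, habitat, land)


def static_landscape(spec: GridSpec, cells, start_age=10.0, end_age=1.0) -> PaleoLandscape:
    ages = np.arange(start_age, end_age - 0.5, -1.0)
    return PaleoLandscape(spec, [make_slice(spec, float(a), cells) for a in ages])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160506)
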