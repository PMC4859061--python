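"""Synthetic paleo-landscape generator.

Emulates the qualitative features of reconstructed tropical shallow-reef
habitat stacks that drive the diversification model: drifting shelf
provinces, episodic fragmentation into patches separated by a scripted gap
followed by reconnection, and the slow collision of two initially disjoint
provinces whose faunas fuse on contact.

Provinces are rendered as latitude-longitude rectangles whose drift is
quantised to whole cells per slice, so the habitat cell count of a province
is constant through time except at scripted fragmentation or merge episodes.
Generation is fully deterministic; the ``seed`` only feeds the optional
random-walk drift noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import GridSpec, LAT_ORIGIN, LON_ORIGIN
from .landscape import HabitatSlice, PaleoLandscape

__all__ = [
    "Province",
    "FragmentationEpisode",
    "LandscapeScenario",
    "generate_synthetic_landscape",
    "two_province_collision",
    "tethys_closure",
    "fragmentation_benchmark",
]


@dataclass(frozen=True)
class Province:
    """A rectangular shelf province at the start age.

    lon/lat give the rectangle centre; v_lon/v_lat the drift velocity in
    degrees per Myr; v_west_edge an eastward encroachment rate of the west
    edge (shrinking corridors); age_appear an optional emergence age.
    """

    lon: float
    lat: float
    width_deg: float
    height_deg: float
    v_lon: float = 0.0
    v_lat: float = 0.0
    v_west_edge: float = 0.0
    age_appear: float | None = None


@dataclass(frozen=True)
class FragmentationEpisode:
    """Split one province into fragments for ages in (age_end, age_start].

    The province rectangle is carved along longitude into ``n_fragments``
    blocks separated by empty gaps of ``gap_deg``; at ``age_end`` the gaps
    close again (reconnection).  ``position`` in [0, 1] shifts the carve
    pattern within the rectangle.
    """

    province: int
    age_start: float
    age_end: float
    n_fragments: int = 2
    gap_deg: float = 5.0
    position: float = 0.5


@dataclass(frozen=True)
class LandscapeScenario:
    resolution_deg: float = 1.0
    start_age: float = 140.0
    end_age: float = 1.0
    provinces: tuple[Province, ...] = ()
    episodes: tuple[FragmentationEpisode, ...] = ()
    merge_age: float | None = None
    drift_noise: float = 0.0  # std of per-Myr random-walk lon jitter, degrees


def _cells_of_rect(spec: GridSpec, col0: int, n_cols: int, row0: int, n_rows: int):
    rows = np.arange(row0, row0 + n_rows)
    rows = rows[(rows >= 0) & (rows < spec.n_lat)]
    if rows.size == 0 or n_cols <= 0:
        return np.empty(0, dtype=np.int64)
    cols = (col0 + np.arange(n_cols)) % spec.n_lon
    return (rows[:, None] * spec.n_lon + cols[None, :]).reshape(-1)


def _carve(cols: np.ndarray, episode: FragmentationEpisode, res: float) -> np.ndarray:
    """Keep the fragment columns of an episode, dropping the gap columns."""
    n_cols = cols.size
    gap_cells = int(round(episode.gap_deg / res))
    n = episode.n_fragments
    if n < 2:
        raise ValueError("n_fragments must be >= 2")
    total_frag = n_cols - (n - 1) * gap_cells
    if total_frag < n:
        raise ValueError(
            f"province too narrow ({n_cols} cells) for {n} fragments with "
            f"{gap_cells}-cell gaps"
        )
    # position slides the carve pattern: it sets the first fragment's width,
    # the remaining fragment cells are split evenly among the others
    w1 = int(round(1 + episode.position * (total_frag - n)))
    w1 = max(1, min(w1, total_frag - (n - 1)))
    rest = total_frag - w1
    widths = [w1] + [rest // (n - 1)] * (n - 1)
    widths[-1] += rest - (rest // (n - 1)) * (n - 1)
    keep = np.zeros(n_cols, dtype=bool)
    pos = 0
    for width in widths:
        keep[pos : pos + width] = True
        pos += width + gap_cells
    return cols[keep]


def generate_synthetic_landscape(
    scenario: LandscapeScenario, seed: int = 0
) -> PaleoLandscape:
    """Render a scenario into a validated :class:`PaleoLandscape`."""
    if not scenario.provinces:
        raise ValueError("scenario needs at least one province")
    if scenario.merge_age is not None and len(scenario.provinces) != 2:
        raise ValueError("merge_age requires exactly two provinces")
    spec = GridSpec(scenario.resolution_deg)
    res = spec.resolution_deg
    rng = np.random.default_rng(seed)
    ages = np.arange(scenario.start_age, scenario.end_age - 0.5, -1.0)
    start = scenario.start_age

    # precompute collision gap schedule (cells) if requested
    merge_sched = None
    if scenario.merge_age is not None:
        p0, p1 = scenario.provinces
        east0 = p0.lon + p0.width_deg / 2.0
        west1 = p1.lon - p1.width_deg / 2.0
        g0_cells = int(round((west1 - east0) / res))
        if g0_cells <= 0:
            raise ValueError("provinces must start disjoint for a collision scenario")
        span = start - scenario.merge_age
        if span <= 0:
            raise ValueError("merge_age must be younger than start_age")
        merge_sched = (east0, g0_cells, span)

    noise = np.zeros(len(scenario.provinces))
    slices = []
    for step, age in enumerate(ages):
        habitat = np.zeros(spec.n_cells, dtype=bool)
        if scenario.drift_noise > 0 and step > 0:
            noise = noise + rng.normal(0.0, scenario.drift_noise, noise.size)
        any_cells = False
        for ip, p in enumerate(scenario.provinces):
            if p.age_appear is not None and age > p.age_appear + 1e-9:
                continue
            elapsed = start - age
            n_cols_full = int(round(p.width_deg / res))
            shrink = int(round(p.v_west_edge * elapsed / res))
            n_cols = n_cols_full - max(shrink, 0)
            n_rows = int(round(p.height_deg / res))
            west = p.lon - p.width_deg / 2.0 + max(shrink, 0) * res
            if ip == 1 and merge_sched is not None:
                east0, g0_cells, span = merge_sched
                if age > scenario.merge_age:
                    gap_cells = max(int(math.ceil(g0_cells * (age - scenario.merge_age) / span)), 1)
                else:
                    gap_cells = 0
                west = east0 + gap_cells * res
            else:
                west += p.v_lon * elapsed + noise[ip]
            south = p.lat - p.height_deg / 2.0 + p.v_lat * elapsed
            col0 = int(round((west - LON_ORIGIN) / res)) % spec.n_lon
            row0 = int(round((south - LAT_ORIGIN) / res))
            cols = (col0 + np.arange(n_cols)) % spec.n_lon
            for ep in scenario.episodes:
                if ep.province == ip and ep.age_end < age <= ep.age_start + 1e-9:
                    cols = _carve(cols, ep, res)
            rows = np.arange(row0, row0 + n_rows)
            rows = rows[(rows >= 0) & (rows < spec.n_lat)]
            if n_cols >= 1 and rows.size == 0:
                raise ValueError(
                    f"province {ip} drifted fully off-grid at {age:g} Ma"
                )
            if cols.size and rows.size:
                ids = (rows[:, None] * spec.n_lon + cols[None, :]).reshape(-1)
                habitat[ids] = True
                any_cells = True
        if not any_cells:
            raise ValueError(f"no habitat anywhere at {age:g} Ma")
        slices.append(HabitatSlice(spec, float(age), habitat))
    return PaleoLandscape(spec, slices)


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------


def two_province_collision(
    merge_age: float = 15.0,
    start_age: float = 60.0,
    end_age: float = 1.0,
    gap_deg: float = 14.0,
    resolution_deg: float = 1.0,
) -> LandscapeScenario:
    """Two disjoint shelf provinces that collide and touch at ``merge_age``.

    The western province stands in for a Tethyan shelf, the eastern one for
    a coastal-Australia shelf drifting onto it.  Before the merge age the
    provinces are separated by a positive sea gap; from the merge age on
    they share at least one adjacent cell pair.
    """
    west = Province(lon=20.0, lat=0.0, width_deg=16.0, height_deg=10.0)
    east = Province(
        lon=20.0 + 16.0 / 2 + gap_deg + 12.0 / 2,
        lat=0.0,
        width_deg=12.0,
        height_deg=10.0,
    )
    return LandscapeScenario(
        resolution_deg=resolution_deg,
        start_age=start_age,
        end_age=end_age,
        provinces=(west, east),
        merge_age=merge_age,
    )


def tethys_closure(
    start_age: float = 140.0,
    end_age: float = 1.0,
    resolution_deg: float = 1.0,
) -> LandscapeScenario:
    """An equatorial corridor whose western end closes progressively eastward.

    A long shallow-shelf band loses habitat from the west as the seaway
    narrows, displacing the available habitat — and with it the richness
    centroid — towards the east, with a few fragmentation pulses to fuel
    parapatric diversification along the way.
    """
    corridor = Province(
        lon=30.0,
        lat=0.0,
        width_deg=90.0,
        height_deg=8.0,
        v_west_edge=0.55,
    )
    episodes = (
        FragmentationEpisode(0, age_start=120.0, age_end=110.0, n_fragments=2, gap_deg=6.0, position=0.3),
        FragmentationEpisode(0, age_start=95.0, age_end=85.0, n_fragments=3, gap_deg=6.0, position=0.6),
        FragmentationEpisode(0, age_start=60.0, age_end=50.0, n_fragments=2, gap_deg=6.0, position=0.7),
    )
    return LandscapeScenario(
        resolution_deg=resolution_deg,
        start_age=start_age,
        end_age=end_age,
        provinces=(corridor,),
        episodes=episodes,
    )


def fragmentation_benchmark(
    start_age: float = 140.0,
    end_age: float = 1.0,
) -> LandscapeScenario:
    """Identifiability benchmark: a mainland with scripted gaps plus islands.

    Habitat occupies a 36 x 18 degree window on a 1-degree global grid.  The
    mainland shelf is fragmented episodically with gap widths sweeping 3-8
    cells, so the number of range-splitting events depends sharply on the
    split threshold d_s; three offshore islands sit at graded distances from
    the mainland so that which of them are ever colonised depends sharply on
    the dispersal scale d.
    """
    mainland = Province(lon=18.0, lat=-2.5, width_deg=30.0, height_deg=12.0)
    # islands appear after the simulation start so the root species does not
    # occupy them for free; lat offsets put their nearest centroid 3, 5 and 7
    # degrees from the mainland's top row
    islands = (
        Province(lon=8.0, lat=6.5, width_deg=3.0, height_deg=2.0, age_appear=130.0),
        Province(lon=19.0, lat=8.5, width_deg=3.0, height_deg=2.0, age_appear=130.0),
        Province(lon=30.0, lat=10.5, width_deg=3.0, height_deg=2.0, age_appear=130.0),
    )
    # gaps carved west of centre: splits accumulate species in the western
    # third, and with a 30-cell shelf the recolonisation front does not reach
    # the east between episodes, so the split history stays spatially legible
    episodes = (
        FragmentationEpisode(0, 126.0, 116.0, 2, 3.0, position=0.35),
        FragmentationEpisode(0, 112.0, 102.0, 2, 4.0, position=0.2),
        FragmentationEpisode(0, 98.0, 88.0, 2, 5.0, position=0.4),
        FragmentationEpisode(0, 84.0, 74.0, 2, 6.0, position=0.25),
        FragmentationEpisode(0, 70.0, 60.0, 2, 7.0, position=0.35),
        FragmentationEpisode(0, 56.0, 46.0, 2, 8.0, position=0.3),
        FragmentationEpisode(0, 42.0, 32.0, 2, 4.0, position=0.4),
        FragmentationEpisode(0, 28.0, 18.0, 2, 5.0, position=0.25),
    )
    return LandscapeScenario(
        resolution_deg=1.0,
        start_age=start_age,
        end_age=end_age,
        provinces=(mainland,) + islands,
        episodes=episodes,
    )
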