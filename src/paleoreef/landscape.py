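"""Dynamic habitat landscapes, tropical limits and fossil diversity maps.

A :class:`PaleoLandscape` is an ordered stack of boolean habitat grids, one
per million years, ages strictly decreasing (oldest first).  Habitat cells
are tropical shallow-reef cells; an optional land mask marks emerged land
(used only by the sea-graph distance model).  Fossil occurrence tables feed
two derived products: the latitudinal tropical limit per time slice (95th
percentile of absolute paleo-latitude of reef-coral occurrences) and
windowed fossil diversity maps rescaled to [0, 1].
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec, LAT_ORIGIN, LON_ORIGIN

__all__ = [
    "HabitatSlice",
    "PaleoLandscape",
    "LandscapeFormatError",
    "read_landscape",
    "write_landscape",
    "read_fossils",
    "tropical_limit",
    "apply_tropical_mask",
    "fossil_diversity_map",
]

FOSSIL_COLUMNS = ["taxon", "rank", "paleo_lat", "paleo_lon", "age_max", "age_min"]


class LandscapeFormatError(ValueError):
    """Raised when a grid-stack file violates the landscape contract."""


@dataclass
class HabitatSlice:
    """Boolean habitat and land masks for one age, on a global grid."""

    spec: GridSpec
    age_ma: float
    habitat: np.ndarray
    land: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.habitat = np.asarray(self.habitat, dtype=bool)
        if self.habitat.shape != (self.spec.n_cells,):
            raise ValueError("habitat mask shape does not match grid")
        if self.age_ma <= 0:
            raise ValueError("age_ma must be positive")
        if self.land is None:
            self.land = np.zeros(self.spec.n_cells, dtype=bool)
        else:
            self.land = np.asarray(self.land, dtype=bool)
            if self.land.shape != (self.spec.n_cells,):
                raise ValueError("land mask shape does not match grid")
        if np.any(self.habitat & self.land):
            raise ValueError("a cell cannot be both reef habitat and land")

    @property
    def habitat_cells(self) -> np.ndarray:
        return np.flatnonzero(self.habitat)


@dataclass
class PaleoLandscape:
    """Stack of habitat slices at a uniform 1-Myr step, oldest first."""

    spec: GridSpec
    slices: list[HabitatSlice] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slices) < 2:
            raise ValueError("a landscape needs at least 2 slices")
        ages = self.ages
        steps = np.diff(ages)
        if np.any(steps >= 0):
            raise LandscapeFormatError("slice ages must be strictly decreasing")
        if not np.allclose(steps, -1.0, atol=1e-6):
            bad = int(np.argmax(~np.isclose(steps, -1.0, atol=1e-6)))
            raise LandscapeFormatError(
                f"non-uniform time step between slices at {ages[bad]} and "
                f"{ages[bad + 1]} Ma (must be 1 Myr)"
            )
        for s in self.slices:
            if s.spec != self.spec:
                raise ValueError("slice grid does not match landscape grid")

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_ma for s in self.slices], dtype=float)

    def __len__(self) -> int:
        return len(self.slices)

    def slice_at(self, age_ma: float) -> HabitatSlice:
        idx = np.flatnonzero(np.isclose(self.ages, age_ma))
        if idx.size == 0:
            raise KeyError(f"no slice at {age_ma} Ma")
        return self.slices[int(idx[0])]

    def habitat_union(self) -> np.ndarray:
        """Cell ids that are habitat in at least one slice."""
        u = np.zeros(self.spec.n_cells, dtype=bool)
        for s in self.slices:
            u |= s.habitat
        return np.flatnonzero(u)

    def land_union(self) -> np.ndarray:
        u = np.zeros(self.spec.n_cells, dtype=bool)
        for s in self.slices:
            u |= s.land
        return u


# ---------------------------------------------------------------------------
# NetCDF / ESRI-ASCII I/O
# ---------------------------------------------------------------------------


def _spec_from_shape(n_lat: int, n_lon: int) -> GridSpec:
    res = 180.0 / n_lat
    spec = GridSpec(res)
    if spec.n_lon != n_lon:
        raise LandscapeFormatError(
            f"grid shape ({n_lat}, {n_lon}) is not a valid global grid"
        )
    return spec


def write_landscape(landscape: PaleoLandscape, path) -> None:
    """Write a landscape as a NetCDF stack (``.nc``) or an ASCII directory."""
    import xarray as xr

    path = Path(path)
    spec = landscape.spec
    if path.suffix == ".nc":
        hab = np.stack(
            [s.habitat.reshape(spec.n_lat, spec.n_lon) for s in landscape.slices]
        ).astype(np.int8)
        land = np.stack(
            [s.land.reshape(spec.n_lat, spec.n_lon) for s in landscape.slices]
        ).astype(np.int8)
        res = spec.resolution_deg
        lats = LAT_ORIGIN + (np.arange(spec.n_lat) + 0.5) * res
        lons = LON_ORIGIN + (np.arange(spec.n_lon) + 0.5) * res
        ds = xr.Dataset(
            {
                "habitat": (("time", "lat", "lon"), hab),
                "land": (("time", "lat", "lon"), land),
            },
            coords={"time": landscape.ages, "lat": lats, "lon": lons},
            attrs={"time_units": "Ma", "registration": "cell-centre"},
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for s in landscape.slices:
            _write_esri_ascii(path / f"habitat_{s.age_ma:g}Ma.asc", spec, s.habitat)
            if s.land.any():
                _write_esri_ascii(path / f"land_{s.age_ma:g}Ma.asc", spec, s.land)


def _write_esri_ascii(path: Path, spec: GridSpec, mask: np.ndarray) -> None:
    grid = mask.reshape(spec.n_lat, spec.n_lon).astype(np.int8)[::-1]  # north first
    header = (
        f"ncols {spec.n_lon}\nnrows {spec.n_lat}\n"
        f"xllcorner {LON_ORIGIN}\nyllcorner {LAT_ORIGIN}\n"
        f"cellsize {spec.resolution_deg:g}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%d")


def _read_esri_ascii(path: Path):
    with open(path) as fh:
        header = {}
        while len(header) < 6:
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_lat, n_lon = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_lat, n_lon):
        raise LandscapeFormatError(f"{path.name}: grid body does not match header")
    spec = _spec_from_shape(n_lat, n_lon)
    return spec, data[::-1].reshape(-1).astype(bool)


def read_landscape(path) -> PaleoLandscape:
    """Read a NetCDF grid stack or a directory of per-age ESRI ASCII grids."""
    import xarray as xr

    path = Path(path)
    if path.is_dir():
        return _read_ascii_dir(path)
    try:
        ds = xr.open_dataset(path, engine="scipy")
    except Exception:
        ds = xr.open_dataset(path)
    if "habitat" not in ds:
        raise LandscapeFormatError("stack has no 'habitat' variable")
    if tuple(ds["habitat"].dims) != ("time", "lat", "lon"):
        raise LandscapeFormatError("habitat must have dimensions (time, lat, lon)")
    spec = _spec_from_shape(ds.sizes["lat"], ds.sizes["lon"])
    ages = np.asarray(ds["time"].values, dtype=float)
    order = np.argsort(-ages)
    hab = np.asarray(ds["habitat"].values, dtype=bool)[order]
    land = (
        np.asarray(ds["land"].values, dtype=bool)[order]
        if "land" in ds
        else np.zeros_like(hab)
    )
    ds.close()
    slices = [
        HabitatSlice(spec, float(a), h.reshape(-1), l.reshape(-1))
        for a, h, l in zip(ages[order], hab, land)
    ]
    return PaleoLandscape(spec, slices)


def _read_ascii_dir(path: Path) -> PaleoLandscape:
    pat = re.compile(r"habitat_([-0-9.]+)Ma\.asc$")
    entries = []
    for f in sorted(path.iterdir()):
        m = pat.match(f.name)
        if m:
            entries.append((float(m.group(1)), f))
    if not entries:
        raise LandscapeFormatError(f"no habitat_<age>Ma.asc files in {path}")
    entries.sort(key=lambda t: -t[0])
    slices = []
    spec = None
    for age, f in entries:
        s, hab = _read_esri_ascii(f)
        if spec is None:
            spec = s
        elif s != spec:
            raise LandscapeFormatError(f"{f.name}: grid shape differs from stack")
        landf = path / f"land_{age:g}Ma.asc"
        land = _read_esri_ascii(landf)[1] if landf.exists() else None
        slices.append(HabitatSlice(spec, age, hab, land))
    return PaleoLandscape(spec, slices)


# ---------------------------------------------------------------------------
# Fossil occurrences
# ---------------------------------------------------------------------------


def read_fossils(path) -> pd.DataFrame:
    """Read a fossil occurrence CSV (taxon, rank, paleo_lat, paleo_lon, age_max, age_min)."""
    df = pd.read_csv(path)
    missing = [c for c in FOSSIL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fossil table missing columns: {missing}")
    _validate_fossils(df)
    return df


def _validate_fossils(df: pd.DataFrame) -> None:
    if (df["age_max"] < df["age_min"]).any() or (df["age_min"] < 0).any():
        raise ValueError("fossil ages must satisfy age_max >= age_min >= 0")
    if (df["paleo_lat"].abs() > 90).any():
        raise ValueError("fossil |paleo_lat| must be <= 90")


def _overlapping(fossils: pd.DataFrame, age_ma: float) -> pd.DataFrame:
    """Occurrences whose closed age interval contains ``age_ma``."""
    return fossils[(fossils["age_min"] <= age_ma) & (fossils["age_max"] >= age_ma)]


def tropical_limit(fossils: pd.DataFrame, age_ma: float) -> float:
    """Latitudinal tropical limit at ``age_ma``, degrees.

    The 95th percentile (linear interpolation between order statistics) of
    absolute paleo-latitude over all occurrences whose age interval overlaps
    the slice.  One percentile of |lat|, applied symmetrically about the
    equator: reef corals track warm water in both hemispheres and pooling
    absolute latitudes is robust to hemisphere-biased sampling.
    """
    _validate_fossils(fossils)
    sel = _overlapping(fossils, age_ma)
    if sel.empty:
        raise ValueError(f"no fossils for slice at {age_ma} Ma")
    return float(np.percentile(np.abs(sel["paleo_lat"].to_numpy()), 95))


def apply_tropical_mask(slice_: HabitatSlice, limit: float) -> HabitatSlice:
    """Drop habitat cells whose centroid latitude exceeds ``limit`` in absolute value."""
    if not 0 <= limit <= 90:
        raise ValueError("limit must be in [0, 90]")
    _, lat = slice_.spec.centroids(np.arange(slice_.spec.n_cells))
    habitat = slice_.habitat & (np.abs(lat) <= limit)
    return HabitatSlice(slice_.spec, slice_.age_ma, habitat, slice_.land)


def fossil_diversity_map(
    fossils: pd.DataFrame,
    age_ma: float,
    spec: GridSpec,
    window_deg: float = 40.0,
) -> np.ndarray:
    """Windowed fossil species diversity per cell, min-max rescaled to [0, 1].

    For each cell the map counts distinct species with at least one
    occurrence inside the ``window_deg`` x ``window_deg`` window centred on
    the cell centroid and an age interval overlapping ``age_ma``.  Windows
    wrap in longitude (the globe is periodic) and truncate at the poles.
    Only occurrences resolved to species rank are used.
    """
    if window_deg <= 0 or abs(window_deg / spec.resolution_deg
                              - round(window_deg / spec.resolution_deg)) > 1e-9:
        raise ValueError("window_deg must be a positive multiple of the resolution")
    _validate_fossils(fossils)
    sel = _overlapping(fossils, age_ma)
    sel = sel[sel["rank"].str.lower() == "species"]
    if sel.empty:
        raise ValueError(f"no species-rank fossils for slice at {age_ma} Ma")

    half = window_deg / 2.0
    cells = np.arange(spec.n_cells)
    clon, clat = spec.centroids(cells)
    counts = np.zeros(spec.n_cells, dtype=np.int64)
    for _, occ in sel.groupby("taxon"):
        olat = occ["paleo_lat"].to_numpy()
        olon = occ["paleo_lon"].to_numpy()
        hit = np.zeros(spec.n_cells, dtype=bool)
        for la, lo in zip(olat, olon):
            dlon = np.abs((clon - lo + 180.0) % 360.0 - 180.0)
            hit |= (np.abs(clat - la) <= half + 1e-9) & (dlon <= half + 1e-9)
        counts += hit

    vmax = counts.max()
    vmin = counts.min()
    if vmax == 0:
        warnings.warn("all-zero diversity map; rescaling skipped", stacklevel=2)
        return np.zeros(spec.n_cells, dtype=float)
    if vmax == vmin:
        warnings.warn("constant diversity map; returning ones", stacklevel=2)
        return np.ones(spec.n_cells, dtype=float)
    return (counts - vmin) / float(vmax - vmin)
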