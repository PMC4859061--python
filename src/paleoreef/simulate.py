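"""Time-stepped diversification engine on a dynamic habitat landscape.

The model starts at the oldest slice with a single ancestral species
occupying every available habitat cell and steps forward in 1-Myr slices.
Each step runs two phases:

1. **Speciation.**  Parapatric mode: a species whose range falls apart into
   n >= 2 blocks separated by more than the sea-distance threshold ``d_s``
   is replaced by n daughter species, one per block; the parent is closed as
   a pseudo-extinct internal node.  Sympatric mode: every occupied cell
   independently spawns a single-cell daughter with probability ``P_s`` per
   step, so large ranges speciate more often (S = P_s * A).  The combined
   mode runs parapatric first, then sympatric over the resulting assemblage.
2. **Dispersal.**  Each species draws a reach r from a Weibull kernel
   (shape kappa, scale d/2) truncated at the dispersal scale ``d`` and
   occupies every habitat cell of the next slice within r of its current
   range, keeping whatever part of its range remains habitable.  A species
   goes extinct only when its entire habitat disappears and no new habitat
   lies within reach.

Randomness is organised as one independent stream per species (keyed by the
root seed and the species id), so adding or removing one species never
perturbs the draws of another.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PairwiseCache, build_distance_model
from .grid import GridSpec
from .landscape import HabitatSlice, PaleoLandscape

__all__ = [
    "SimConfig",
    "Species",
    "Genealogy",
    "SimResult",
    "SimState",
    "SpeciesCapExceeded",
    "initialize",
    "speciation_phase",
    "dispersal_phase",
    "forced_extinction",
    "run_simulation",
    "diversification_series",
    "tag_origins",
    "tagged_richness_maps",
]

MODES = ("parapatric", "sympatric", "combined")


class SpeciesCapExceeded(RuntimeError):
    """Raised when extant richness exceeds the configured cap.

    Runs in the degenerate regime (typically d > d_s) can double their
    richness every step; the cap aborts them instead of letting them take
    over the machine.
    """


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    d and d_s are in degrees of arc; P_s is a per-cell per-step probability.
    ``forced_extinctions`` is a list of (age_Ma, fraction) events applied
    when the simulation reaches that slice.  ``start_region`` optionally
    restricts the root species to a (lon_min, lon_max, lat_min, lat_max)
    box, for younger-clade experiments.
    """

    mode: str = "parapatric"
    d: float = 4.0
    d_s: float | None = 5.0
    p_s: float | None = None
    weibull_shape: float = 2.0
    weibull_scale_ratio: float = 0.5
    seed: int = 0
    start_age: float | None = None
    end_age: float | None = None
    forced_extinctions: tuple[tuple[float, float], ...] = ()
    snapshot_ages: tuple[float, ...] = ()
    distance_mode: str = "great_circle"
    start_region: tuple[float, float, float, float] | None = None
    species_cap: int = 20_000
    parent_survives_split: bool = False
    count_split_daughters: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode in ("parapatric", "combined") and self.d_s is None:
            raise ValueError("parapatric/combined mode requires d_s")
        if self.mode in ("sympatric", "combined") and self.p_s is None:
            raise ValueError("sympatric/combined mode requires P_s")
        if self.d <= 0 or self.weibull_shape <= 0 or self.weibull_scale_ratio <= 0:
            raise ValueError("d, weibull_shape and weibull_scale_ratio must be positive")
        if not 1 <= self.d <= 40:
            warnings.warn(f"d={self.d} outside the explored range [1, 40]", stacklevel=2)
        if self.d_s is not None and not 1 <= self.d_s <= 40:
            warnings.warn(f"d_s={self.d_s} outside the explored range [1, 40]", stacklevel=2)
        if self.p_s is not None:
            if not 0 <= self.p_s <= 1:
                raise ValueError("P_s must be a probability")
            if self.p_s != 0 and not 1e-5 <= self.p_s <= 1e-4:
                warnings.warn(
                    f"P_s={self.p_s} outside the explored range [1e-5, 1e-4]",
                    stacklevel=2,
                )
        for age, frac in self.forced_extinctions:
            if not 0 <= frac <= 1:
                raise ValueError("forced extinction fraction must be in [0, 1]")

    @property
    def n_parameters(self) -> int:
        """Free parameters of the speciation model: 2, 2 or 3."""
        return {"parapatric": 2, "sympatric": 2, "combined": 3}[self.mode]


@dataclass
class Species:
    """One lineage: identity, genealogy links and life span (ages in Ma)."""

    id: int
    parent: int | None
    birth_age: float
    origin_mode: str  # root | parapatric | sympatric
    extinction_age: float | None = None
    pseudo_extinct: bool = False  # closed at a cladogenetic split
    final_cells: np.ndarray | None = None  # global cell ids at death/end
    origin_tag: str | None = None


@dataclass
class StepRecord:
    age_from: float
    age_to: float
    richness_start: int
    n_parapatric_splits: int = 0
    n_parapatric_daughters: int = 0
    n_sympatric: int = 0
    n_extinct_habitat: int = 0
    n_extinct_forced: int = 0
    n_pseudo_extinct: int = 0
    richness_end: int = 0


class SimState:
    """Mutable simulation state; ranges are indices into the cell universe."""

    def __init__(self, landscape: PaleoLandscape, config: SimConfig):
        self.landscape = landscape
        self.config = config
        ages = landscape.ages
        start = config.start_age if config.start_age is not None else ages[0]
        end = config.end_age if config.end_age is not None else ages[-1]
        i0 = np.flatnonzero(np.isclose(ages, start))
        i1 = np.flatnonzero(np.isclose(ages, end))
        if i0.size == 0 or i1.size == 0 or i1[0] <= i0[0]:
            raise ValueError("landscape does not cover [start_age, end_age]")
        self.i_start, self.i_end = int(i0[0]), int(i1[0])
        self.pos = self.i_start
        self.age = float(ages[self.pos])

        universe = landscape.habitat_union()
        model = build_distance_model(
            landscape.spec, config.distance_mode, land=landscape.land_union()
        )
        self.cache = PairwiseCache(model, universe)
        self.universe = self.cache.universe
        self._uindex = np.full(landscape.spec.n_cells, -1, dtype=np.int64)
        self._uindex[self.universe] = np.arange(self.universe.size)

        self.species: dict[int, Species] = {}
        self.ranges: dict[int, np.ndarray] = {}  # extant id -> universe indices
        # clustering memo: a range that has not changed since it was last
        # found connected cannot have split, so the check can be skipped
        self._range_changed: dict[int, bool] = {}
        self._connected: dict[int, bool] = {}
        self._rngs: dict[int, np.random.Generator] = {}
        self.events: list[dict] = []
        self.steps: list[StepRecord] = []
        self.snapshots: dict[float, dict[int, np.ndarray]] = {}
        self._next_id = 0

    # -- helpers ------------------------------------------------------------

    @property
    def extant_ids(self) -> list[int]:
        return sorted(self.ranges)

    @property
    def n_extant(self) -> int:
        return len(self.ranges)

    def rng_for(self, sid: int) -> np.random.Generator:
        rng = self._rngs.get(sid)
        if rng is None:
            rng = np.random.default_rng([self.config.seed, sid])
            self._rngs[sid] = rng
        return rng

    def habitat_idx(self, slice_: HabitatSlice) -> np.ndarray:
        idx = self._uindex[slice_.habitat_cells]
        return idx[idx >= 0]

    def add_species(
        self, parent: int | None, origin_mode: str, range_idx: np.ndarray
    ) -> Species:
        sp = Species(
            id=self._next_id, parent=parent, birth_age=self.age, origin_mode=origin_mode
        )
        self._next_id += 1
        self.species[sp.id] = sp
        self.ranges[sp.id] = np.asarray(range_idx, dtype=np.int64)
        self._range_changed[sp.id] = True
        return sp

    def kill(self, sid: int, age: float, pseudo: bool = False) -> None:
        sp = self.species[sid]
        sp.extinction_age = age
        sp.pseudo_extinct = pseudo
        sp.final_cells = self.universe[self.ranges.pop(sid)]
        self._rngs.pop(sid, None)
        self._range_changed.pop(sid, None)
        self._connected.pop(sid, None)

    def take_snapshot(self, age: float) -> None:
        self.snapshots[float(age)] = {
            sid: self.universe[idx].copy() for sid, idx in self.ranges.items()
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def initialize(landscape: PaleoLandscape, config: SimConfig) -> SimState:
    """One root species occupying all habitat of the start slice.

    With ``start_region`` set, the root occupies only the habitat cells
    inside that lon/lat box.
    """
    state = SimState(landscape, config)
    first = landscape.slices[state.i_start]
    idx = state.habitat_idx(first)
    if config.start_region is not None:
        lo_lon, hi_lon, lo_lat, hi_lat = config.start_region
        lon, lat = landscape.spec.centroids(state.universe[idx])
        keep = (lon >= lo_lon) & (lon <= hi_lon) & (lat >= lo_lat) & (lat <= hi_lat)
        idx = idx[keep]
    if idx.size == 0:
        raise ValueError("empty initial habitat")
    root = state.add_species(None, "root", idx)
    state.events.append(
        {"age": state.age, "event": "root", "species": root.id, "parent": -1}
    )
    return state


def speciation_phase(state: SimState, record: StepRecord | None = None) -> SimState:
    """Phase 1 of a step: parapatric splits, then sympatric cell events."""
    cfg = state.config
    rec = record if record is not None else StepRecord(state.age, state.age, state.n_extant)

    if cfg.mode in ("parapatric", "combined"):
        for sid in state.extant_ids:
            if not state._range_changed.get(sid, True) and state._connected.get(sid):
                continue
            blocks = state.cache.clusters_idx(state.ranges[sid], cfg.d_s)
            if len(blocks) < 2:
                state._connected[sid] = True
                state._range_changed[sid] = False
                continue
            if cfg.parent_survives_split:
                # largest block (ties: first) keeps the parent identity
                keep = max(range(len(blocks)), key=lambda i: (blocks[i].size, -i))
                state.ranges[sid] = blocks[keep]
                daughters = [b for i, b in enumerate(blocks) if i != keep]
            else:
                daughters = blocks
                state.kill(sid, state.age, pseudo=True)
                rec.n_pseudo_extinct += 1
            for block in daughters:
                sp = state.add_species(sid, "parapatric", block)
                state.events.append(
                    {"age": state.age, "event": "parapatric", "species": sp.id, "parent": sid}
                )
            rec.n_parapatric_splits += 1
            rec.n_parapatric_daughters += len(daughters)

    if cfg.mode in ("sympatric", "combined") and cfg.p_s:
        for sid in state.extant_ids:
            cells = state.ranges[sid]
            u = state.rng_for(sid).random(cells.size)
            for idx in cells[u < cfg.p_s]:
                sp = state.add_species(sid, "sympatric", np.array([idx], dtype=np.int64))
                state.events.append(
                    {"age": state.age, "event": "sympatric", "species": sp.id, "parent": sid}
                )
                rec.n_sympatric += 1
    if record is None:
        state.steps.append(rec)
    return state


def _draw_reach(state: SimState, sid: int) -> float:
    cfg = state.config
    u = float(state.rng_for(sid).random())
    scale = cfg.weibull_scale_ratio * cfg.d
    x = scale * (-math.log1p(-u)) ** (1.0 / cfg.weibull_shape)
    return min(x, cfg.d)


def dispersal_phase(
    state: SimState, next_slice: HabitatSlice, record: StepRecord | None = None
) -> SimState:
    """Phase 2: move every species onto the next slice's habitat.

    New range = (old range that stays habitable) + (habitat within the
    drawn reach r of the old range).  Empty new range means extinction,
    dated at the next slice's age.
    """
    rec = record if record is not None else StepRecord(state.age, next_slice.age_ma, state.n_extant)
    hab = state.habitat_idx(next_slice)
    hab_mask = np.zeros(state.universe.size, dtype=bool)
    hab_mask[hab] = True
    for sid in state.extant_ids:
        old = state.ranges[sid]
        r = _draw_reach(state, sid)  # drawn every step for every species
        kept = old[hab_mask[old]]
        if kept.size == hab.size:
            new = kept  # the range already covers every habitat cell
        else:
            occ = np.zeros(state.universe.size, dtype=bool)
            occ[kept] = True
            hab_rest = hab[~occ[hab]]
            reached = state.cache.reach_idx(old, hab_rest, r)
            new = np.sort(np.concatenate((kept, reached)))
        if new.size == 0:
            state.kill(sid, next_slice.age_ma)
            state.events.append(
                {
                    "age": next_slice.age_ma,
                    "event": "extinction",
                    "species": sid,
                    "parent": state.species[sid].parent if state.species[sid].parent is not None else -1,
                }
            )
            rec.n_extinct_habitat += 1
        else:
            if new.size != old.size or not np.array_equal(new, old):
                state._range_changed[sid] = True
            state.ranges[sid] = new
    if record is None:
        state.steps.append(rec)
    return state


def forced_extinction(
    state: SimState,
    fraction: float,
    rng: np.random.Generator,
    record: StepRecord | None = None,
) -> SimState:
    """Remove round(fraction * n_extant) species uniformly at random."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    ids = state.extant_ids
    n_remove = int(math.floor(fraction * len(ids) + 0.5))
    if n_remove == 0:
        return state
    victims = rng.choice(np.asarray(ids), size=n_remove, replace=False)
    for sid in sorted(int(v) for v in victims):
        state.kill(sid, state.age)
        state.events.append(
            {"age": state.age, "event": "forced_extinction", "species": sid, "parent": -1}
        )
        if record is not None:
            record.n_extinct_forced += 1
    return state


def run_simulation(landscape: PaleoLandscape, config: SimConfig) -> "SimResult":
    """Run the full engine from start_age to end_age; deterministic per seed."""
    state = initialize(landscape, config)
    ages = landscape.ages
    snapshot_ages = set(float(a) for a in config.snapshot_ages)
    if float(state.age) in snapshot_ages:
        state.take_snapshot(state.age)
    forced = {float(a): f for a, f in config.forced_extinctions}

    for pos in range(state.i_start, state.i_end):
        next_slice = landscape.slices[pos + 1]
        rec = StepRecord(float(ages[pos]), float(next_slice.age_ma), state.n_extant)
        speciation_phase(state, rec)
        dispersal_phase(state, next_slice, rec)
        state.pos = pos + 1
        state.age = float(next_slice.age_ma)
        if state.age in forced:
            rng = np.random.default_rng([config.seed, 982_451_653, pos])
            forced_extinction(state, forced[state.age], rng, rec)
        rec.richness_end = state.n_extant
        state.steps.append(rec)
        if state.age in snapshot_ages:
            state.take_snapshot(state.age)
        if state.n_extant > config.species_cap:
            raise SpeciesCapExceeded(
                f"{state.n_extant} extant species at {state.age:g} Ma exceeds the "
                f"cap of {config.species_cap} (degenerate regime, typically d > d_s)"
            )
    if state.n_extant == 0:
        warnings.warn("full extinction: no species survive to the end age", stacklevel=2)
    end_age = float(ages[state.i_end])
    for sid, idx in state.ranges.items():
        state.species[sid].final_cells = state.universe[idx]
    return SimResult(
        config=config,
        spec=landscape.spec,
        end_age=end_age,
        species=state.species,
        events=state.events,
        steps=state.steps,
        snapshots=state.snapshots,
        extant_ids=state.extant_ids,
    )


# ---------------------------------------------------------------------------
# Results, genealogy, derived series
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    config: SimConfig
    spec: GridSpec
    end_age: float
    species: dict[int, Species]
    events: list[dict]
    steps: list[StepRecord]
    snapshots: dict[float, dict[int, np.ndarray]]
    extant_ids: list[int]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["age", "event", "species", "parent"])

    def steps_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def genealogy(self) -> "Genealogy":
        return Genealogy(self.species, self.end_age)

    def to_newick(self) -> str:
        return self.genealogy().to_newick()

    def snapshot_matrix(self, age_ma: float) -> pd.DataFrame:
        """Site-by-species 0/1 matrix of the snapshot at ``age_ma``.

        Rows are occupied cells (cell ids), columns species ids.
        """
        snap = self._snapshot(age_ma)
        sids = sorted(snap)
        cells = sorted(set(int(c) for sid in sids for c in snap[sid]))
        cell_pos = {c: i for i, c in enumerate(cells)}
        mat = np.zeros((len(cells), len(sids)), dtype=np.int64)
        for j, sid in enumerate(sids):
            mat[[cell_pos[int(c)] for c in snap[sid]], j] = 1
        return pd.DataFrame(mat, index=cells, columns=sids)

    def richness_map(self, age_ma: float, support: np.ndarray | None = None) -> pd.Series:
        """Species count per cell at a snapshot age.

        ``support`` optionally fixes the cell index (zeros where unoccupied),
        e.g. the habitat cells of that slice.
        """
        snap = self._snapshot(age_ma)
        counts: dict[int, int] = {}
        for cells in snap.values():
            for c in cells:
                counts[int(c)] = counts.get(int(c), 0) + 1
        if support is None:
            ser = pd.Series(counts, dtype=float).sort_index()
        else:
            ser = pd.Series(
                [counts.get(int(c), 0) for c in support],
                index=[int(c) for c in support],
                dtype=float,
            )
        ser.index.name = "cell_id"
        return ser

    def _snapshot(self, age_ma: float) -> dict[int, np.ndarray]:
        for a, snap in self.snapshots.items():
            if np.isclose(a, age_ma):
                return snap
        raise KeyError(f"no snapshot at {age_ma} Ma")


class Genealogy:
    """Phylogeny of all lineages ever created, serialisable to Newick.

    Branch lengths are in Myr; parapatric splits appear as (possibly
    multifurcating) internal nodes at the split age, sympatric births as
    bifurcations along the parent branch.  Pseudo-extinct parents are
    internal nodes, all other species are tips (extinct tips end at their
    extinction age, extant tips at the end age).
    """

    def __init__(self, species: dict[int, Species], end_age: float):
        self.species = species
        self.end_age = end_age
        roots = [s for s in species.values() if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.children: dict[int, list[Species]] = {}
        for s in species.values():
            if s.parent is not None:
                if s.birth_age > species[s.parent].birth_age + 1e-9:
                    raise ValueError("child born before its parent")
                self.children.setdefault(s.parent, []).append(s)

    def _tip_age(self, s: Species) -> float:
        return s.extinction_age if s.extinction_age is not None else self.end_age

    def to_dendropy(self):
        import dendropy

        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)

        def subtree(s: Species):
            kids = self.children.get(s.id, [])
            para = sorted(
                (k for k in kids if k.origin_mode == "parapatric"), key=lambda k: k.id
            )
            symp = sorted(
                (k for k in kids if k.origin_mode == "sympatric"),
                key=lambda k: (k.birth_age, k.id),
            )
            end = self._tip_age(s)
            if para:
                base = dendropy.Node()
                base.label = f"s{s.id}"
                for k in para:
                    child, child_age = subtree(k)
                    child.edge.length = max(k.birth_age - child_age, 0.0)
                    base.add_child(child)
            else:
                base = dendropy.Node()
                base.taxon = taxa.new_taxon(f"s{s.id}")
            base_age = end
            for k in symp:  # ascending age: nearest the tip first
                joint = dendropy.Node()
                joint.label = f"s{s.id}"
                base.edge.length = k.birth_age - base_age
                child, child_age = subtree(k)
                child.edge.length = max(k.birth_age - child_age, 0.0)
                joint.add_child(base)
                joint.add_child(child)
                base, base_age = joint, k.birth_age
            return base, base_age

        node, age = subtree(self.root)
        node.edge.length = max(self.root.birth_age - age, 0.0)
        tree.seed_node = node
        return tree

    def to_newick(self) -> str:
        tree = self.to_dendropy()
        return tree.as_string(schema="newick", suppress_rooting=True).strip()

    def n_tips(self) -> int:
        return sum(1 for s in self.species.values() if not s.pseudo_extinct)


def diversification_series(result: SimResult) -> pd.DataFrame:
    """Per-step speciation, extinction and net diversification rates.

    Rates are events per extant lineage per Myr, normalised by the richness
    at the start of the step.  A parapatric split counts as one speciation
    event per splitting parent (or n-1 per split when the config says so);
    pseudo-extinctions of split parents are bookkeeping, not extinction
    events.  Steps starting with zero lineages give NaN.
    """
    rows = []
    for s in result.steps:
        if result.config.count_split_daughters:
            spec_events = (s.n_parapatric_daughters - s.n_parapatric_splits) + s.n_sympatric
        else:
            spec_events = s.n_parapatric_splits + s.n_sympatric
        ext_events = s.n_extinct_habitat + s.n_extinct_forced
        if s.richness_start == 0:
            sr = er = np.nan
        else:
            sr = spec_events / s.richness_start
            er = ext_events / s.richness_start
        rows.append(
            {
                "age_Ma": s.age_from,
                "speciation_rate": sr,
                "extinction_rate": er,
                "net_diversification": sr - er if s.richness_start else np.nan,
            }
        )
    return pd.DataFrame(rows)


def tag_origins(
    result: SimResult, regions: dict[str, set[int]], tag_age: float
) -> pd.Series:
    """Label lineages by the region holding the majority of their range.

    Every species extant at ``tag_age`` (which must be a snapshot age) gets
    the label of the region containing most of its range cells (ties broken
    lexicographically, untagged if outside all regions); descendants born
    after the tag age inherit their parent's label.
    """
    names = sorted(regions)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if regions[a] & regions[b]:
                raise ValueError(f"regions {a!r} and {b!r} overlap")
    snap = result._snapshot(tag_age)
    tags: dict[int, str] = {}
    for sid, cells in snap.items():
        cellset = set(int(c) for c in cells)
        counts = {name: len(cellset & regions[name]) for name in names}
        best = max(counts.values()) if counts else 0
        if best == 0:
            tags[sid] = "untagged"
            continue
        winners = sorted(n for n, c in counts.items() if c == best)
        if len(winners) > 1:
            warnings.warn(
                f"species {sid}: tie between regions {winners}, taking {winners[0]}",
                stacklevel=2,
            )
        tags[sid] = winners[0]
    # descendants inherit; walk in id order (ids increase with birth order)
    for sid in sorted(result.species):
        if sid in tags:
            continue
        sp = result.species[sid]
        if sp.birth_age <= tag_age + 1e-9 and sp.parent in tags:
            tags[sid] = tags[sp.parent]
    for sp in result.species.values():
        sp.origin_tag = tags.get(sp.id)
    ser = pd.Series(tags, dtype="object").sort_index()
    ser.index.name = "species"
    return ser


def tagged_richness_maps(
    result: SimResult, tags: pd.Series, age_ma: float
) -> dict[str, pd.Series]:
    """Per-tag richness maps at a (later) snapshot age."""
    snap = result._snapshot(age_ma)
    maps: dict[str, dict[int, int]] = {}
    for sid, cells in snap.items():
        tag = tags.get(sid)
        if tag is None:
            continue
        bucket = maps.setdefault(tag, {})
        for c in cells:
            bucket[int(c)] = bucket.get(int(c), 0) + 1
    return {
        tag: pd.Series(counts, dtype=float).sort_index() for tag, counts in maps.items()
    }
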