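"""Diversification engine: phases, genealogy, rates, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import paleoreef as pr
from paleoreef import (
    FragmentationEpisode,
    LandscapeScenario,
    PaleoLandscape,
    Province,
    SimConfig,
    diversification_series,
    dispersal_phase,
    forced_extinction,
    initialize,
    run_simulation,
    speciation_phase,
    tag_origins,
    tagged_richness_maps,
)

from conftest import box_cells, make_slice, static_landscape


@pytest.fixture(scope="module")
def spec1m():
    return pr.GridSpec(1.0)


def twelve_cell_landscape(spec):
    cells = box_cells(spec, 0, 4, 0, 3)  # 4 x 3 = 12 cells
    assert cells.size == 12
    return static_landscape(spec, cells)


# certain reach: a near-step kernel concentrated at d
CERTAIN_REACH = dict(weibull_shape=60.0, weibull_scale_ratio=1.0)


class TestInitialize:
    def test_root_occupies_all_habitat(self, spec1m):
        state = initialize(twelve_cell_landscape(spec1m), SimConfig(seed=1))
        assert state.n_extant == 1
        assert state.ranges[0].size == 12

    def test_start_region_restricts_root(self, spec1m):
        cfg = SimConfig(seed=1, start_region=(0.0, 1.0, 0.0, 3.0))
        state = initialize(twelve_cell_landscape(spec1m), cfg)
        assert state.ranges[0].size == 3

    def test_empty_initial_habitat_errors(self, spec1m):
        cells = box_cells(spec1m, 0, 3, 0, 2)
        slices = [make_slice(spec1m, float(a), [] if a == 10 else cells) for a in (10, 9, 8)]
        ls = PaleoLandscape(spec1m, slices)
        with pytest.raises(ValueError, match="empty initial habitat"):
            initialize(ls, SimConfig(seed=1))


class TestSpeciationPhase:
    def test_parapatric_split_closes_parent(self, spec1m):
        cells = np.concatenate(
            [box_cells(spec1m, 0, 2, 0, 1), box_cells(spec1m, 20, 22, 0, 1)]
        )
        state = initialize(static_landscape(spec1m, cells), SimConfig(d_s=5, seed=1))
        speciation_phase(state)
        assert state.n_extant == 2
        assert state.species[0].pseudo_extinct
        assert state.species[0].extinction_age == 10.0
        assert {s.origin_mode for s in state.species.values()} == {"root", "parapatric"}

    def test_connected_range_never_splits(self, spec1m):
        state = initialize(twelve_cell_landscape(spec1m), SimConfig(d_s=5, seed=1))
        speciation_phase(state)
        assert state.n_extant == 1

    def test_parent_survives_split_option(self, spec1m):
        cells = np.concatenate(
            [box_cells(spec1m, 0, 4, 0, 2), box_cells(spec1m, 20, 22, 0, 1)]
        )
        cfg = SimConfig(d_s=5, seed=1, parent_survives_split=True)
        state = initialize(static_landscape(spec1m, cells), cfg)
        speciation_phase(state)
        assert state.n_extant == 2
        assert not state.species[0].pseudo_extinct
        assert state.ranges[0].size == 8  # largest fragment keeps the parent id

    def test_sympatric_certain_probability_spawns_per_cell(self, spec1m):
        cells = box_cells(spec1m, 0, 3, 0, 1)  # 3 cells
        with pytest.warns(UserWarning, match="P_s"):
            cfg = SimConfig(mode="sympatric", p_s=1.0, seed=1)
        state = initialize(static_landscape(spec1m, cells), cfg)
        speciation_phase(state)
        assert state.n_extant == 4  # parent + one daughter per occupied cell
        daughters = [s for s in state.species.values() if s.origin_mode == "sympatric"]
        assert all(state.ranges[s.id].size == 1 for s in daughters)

    def test_zero_probability_never_speciates(self, spec1m):
        cfg = SimConfig(mode="sympatric", p_s=0.0, seed=1)
        state = initialize(twelve_cell_landscape(spec1m), cfg)
        for _ in range(20):
            speciation_phase(state)
        assert state.n_extant == 1

    def test_sympatric_counts_follow_binomial_law(self, spec1m):
        """Chi-square goodness of fit of per-step event counts vs Binomial(A, P_s)."""
        cells = box_cells(spec1m, 0, 10, 0, 5)  # A = 50
        with pytest.warns(UserWarning, match="P_s"):
            cfg = SimConfig(mode="sympatric", p_s=0.01, seed=9)
        state = initialize(static_landscape(spec1m, cells), cfg)
        n_rep = 10_000
        counts = np.zeros(n_rep, dtype=int)
        for i in range(n_rep):
            before = set(state.species)
            speciation_phase(state)
            new = [sid for sid in state.species if sid not in before]
            counts[i] = len(new)
            for sid in new:  # reset assemblage, keep the parent's rng stream
                state.ranges.pop(sid)
                state.species.pop(sid)
                state._range_changed.pop(sid, None)
            state.steps.clear()
            state.events = [e for e in state.events if e["event"] == "root"]
        # bins {0, 1, 2, >=3}: every expected count is comfortably >= 5
        pmf = stats.binom.pmf([0, 1, 2], 50, 0.01)
        exp = np.append(pmf, 1 - pmf.sum()) * n_rep
        obs = np.array(
            [(counts == 0).sum(), (counts == 1).sum(), (counts == 2).sum(), (counts >= 3).sum()]
        )
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.01


class TestDispersalPhase:
    def test_range_never_shrinks_on_static_habitat(self, spec1m):
        ls = twelve_cell_landscape(spec1m)
        cfg = SimConfig(d=2, d_s=5, seed=3, start_region=(0.0, 1.0, 0.0, 1.0))
        state = initialize(ls, cfg)
        size = state.ranges[0].size
        for pos in range(len(ls) - 1):
            dispersal_phase(state, ls.slices[pos + 1])
            assert state.ranges[0].size >= size
            size = state.ranges[0].size

    def test_extinction_when_habitat_vanishes_out_of_reach(self, spec1m):
        near = box_cells(spec1m, 0, 2, 0, 1)
        far = box_cells(spec1m, 50, 52, 0, 1)
        slices = [
            make_slice(spec1m, 10, near),
            make_slice(spec1m, 9, far),
            make_slice(spec1m, 8, far),
        ]
        ls = PaleoLandscape(spec1m, slices)
        cfg = SimConfig(d=4, d_s=5, seed=3, **CERTAIN_REACH)
        state = initialize(ls, cfg)
        dispersal_phase(state, ls.slices[1])
        assert state.n_extant == 0
        assert state.species[0].extinction_age == 9.0
        assert any(e["event"] == "extinction" for e in state.events)

    def test_survival_by_colonising_reachable_habitat(self, spec1m):
        near = box_cells(spec1m, 0, 2, 0, 1)
        moved = box_cells(spec1m, 4, 5, 0, 1)  # one cell, two columns east (arc ~3)
        slices = [
            make_slice(spec1m, 10, near),
            make_slice(spec1m, 9, moved),
            make_slice(spec1m, 8, moved),
        ]
        ls = PaleoLandscape(spec1m, slices)
        cfg = SimConfig(d=4, d_s=5, seed=3, **CERTAIN_REACH)  # reach ~4 > gap
        state = initialize(ls, cfg)
        dispersal_phase(state, ls.slices[1])
        assert state.n_extant == 1
        assert set(state.universe[state.ranges[0]]) == set(moved)

    def test_reach_monotone_in_dispersal_scale(self, spec1m):
        """Same seed, larger d: every snapshot range contains the smaller one."""
        scen = LandscapeScenario(
            resolution_deg=1.0,
            start_age=30.0,
            end_age=1.0,
            provinces=(
                Province(lon=0, lat=0, width_deg=14, height_deg=6),
                # an island 3 degrees offshore emerging mid-run: only a
                # species with reach >= 3 can ever occupy it
                Province(lon=0, lat=6.5, width_deg=4, height_deg=2, age_appear=20.0),
            ),
        )
        ls = pr.generate_synthetic_landscape(scen, seed=0)
        snaps = (25.0, 15.0, 5.0)
        res = {}
        for d in (2, 5):
            cfg = SimConfig(mode="parapatric", d=d, d_s=30, seed=11, snapshot_ages=snaps)
            res[d] = run_simulation(ls, cfg)
        for age in snaps:
            small = set(res[2].snapshots[age][0])
            large = set(res[5].snapshots[age][0])
            assert small <= large


class TestForcedExtinction:
    def make_ten(self, spec1m):
        state = initialize(twelve_cell_landscape(spec1m), SimConfig(seed=1))
        for _ in range(9):
            state.add_species(0, "sympatric", state.ranges[0][:1])
        assert state.n_extant == 10
        return state

    def test_removes_rounded_fraction(self, spec1m, rng):
        state = self.make_ten(spec1m)
        forced_extinction(state, 0.8, rng)
        assert state.n_extant == 2
        assert sum(e["event"] == "forced_extinction" for e in state.events) == 8

    def test_zero_fraction_is_noop(self, spec1m, rng):
        state = self.make_ten(spec1m)
        forced_extinction(state, 0.0, rng)
        assert state.n_extant == 10

    def test_full_fraction_clears_assemblage(self, spec1m, rng):
        state = self.make_ten(spec1m)
        forced_extinction(state, 1.0, rng)
        assert state.n_extant == 0


class TestRunSimulation:
    def test_static_connected_landscape_stays_monospecific(self, spec1m):
        ls = twelve_cell_landscape(spec1m)
        res = run_simulation(ls, SimConfig(mode="parapatric", d=4, d_s=5, seed=2))
        assert res.extant_ids == [0]
        assert res.events_frame()["event"].tolist() == ["root"]

    def test_scripted_two_way_split_gives_two_species(self, spec1m):
        scen = LandscapeScenario(
            resolution_deg=1.0,
            start_age=20.0,
            end_age=1.0,
            provinces=(Province(lon=0, lat=0, width_deg=20, height_deg=4),),
            episodes=(FragmentationEpisode(0, 12.0, 0.0, 2, 8.0),),
        )
        ls = pr.generate_synthetic_landscape(scen, seed=0)
        cfg = SimConfig(mode="parapatric", d=2, d_s=5, seed=4)
        res = run_simulation(ls, cfg)
        assert len(res.extant_ids) == 2
        ev = res.events_frame()
        assert (ev["event"] == "parapatric").sum() == 2
        assert ev.loc[ev.event == "parapatric", "age"].unique().tolist() == [12.0]

    def test_determinism_same_seed_identical_results(self, spec1m):
        ls = pr.generate_synthetic_landscape(pr.two_province_collision(), seed=0)
        cfg = SimConfig(mode="combined", d=3, d_s=5, p_s=5e-5, seed=7,
                        snapshot_ages=(20.0, 5.0))
        a = run_simulation(ls, cfg)
        b = run_simulation(ls, cfg)
        pd.testing.assert_frame_equal(a.events_frame(), b.events_frame())
        pd.testing.assert_frame_equal(a.steps_frame(), b.steps_frame())
        assert a.to_newick() == b.to_newick()
        for age in (20.0, 5.0):
            assert a.snapshot_matrix(age).equals(b.snapshot_matrix(age))

    def test_richness_bookkeeping_exact_every_step(self):
        ls = pr.generate_synthetic_landscape(pr.tethys_closure(start_age=80.0), seed=0)
        cfg = SimConfig(mode="combined", d=4, d_s=5, p_s=1e-4, seed=13,
                        forced_extinctions=((40.0, 0.5),))
        res = run_simulation(ls, cfg)
        for s in res.steps:
            births = s.n_parapatric_daughters + s.n_sympatric
            deaths = s.n_pseudo_extinct + s.n_extinct_habitat + s.n_extinct_forced
            assert s.richness_end == s.richness_start + births - deaths
        assert any(s.n_extinct_forced > 0 for s in res.steps)

    def test_occupancy_subset_of_habitat(self):
        ls = pr.generate_synthetic_landscape(pr.tethys_closure(start_age=60.0), seed=0)
        snaps = (40.0, 20.0, 5.0)
        cfg = SimConfig(mode="parapatric", d=4, d_s=5, seed=5, snapshot_ages=snaps)
        res = run_simulation(ls, cfg)
        for age in snaps:
            habitat = set(ls.slice_at(age).habitat_cells.tolist())
            for cells in res.snapshots[age].values():
                assert set(int(c) for c in cells) <= habitat

    def test_species_cap_aborts_runaway_runs(self, spec1m):
        ls = pr.generate_synthetic_landscape(pr.fragmentation_benchmark(), seed=0)
        cfg = SimConfig(mode="parapatric", d=8, d_s=3, seed=1, species_cap=100)
        with pytest.raises(pr.SpeciesCapExceeded):
            run_simulation(ls, cfg)

    def test_wide_threshold_never_splits(self):
        # maximal gap in this landscape is far below d_s = 40
        scen = LandscapeScenario(
            resolution_deg=1.0,
            start_age=20.0,
            end_age=1.0,
            provinces=(Province(lon=0, lat=0, width_deg=20, height_deg=4),),
            episodes=(FragmentationEpisode(0, 12.0, 6.0, 2, 8.0),),
        )
        ls = pr.generate_synthetic_landscape(scen, seed=0)
        res = run_simulation(ls, SimConfig(mode="parapatric", d=2, d_s=40, seed=4))
        assert len(res.extant_ids) == 1


class TestGenealogy:
    def run_collision(self):
        ls = pr.generate_synthetic_landscape(pr.two_province_collision(), seed=0)
        cfg = SimConfig(mode="combined", d=3, d_s=5, p_s=8e-5, seed=21)
        return run_simulation(ls, cfg)

    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        res = self.run_collision()
        nwk = res.to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == res.genealogy().n_tips()
        for e in tree.preorder_edge_iter():
            assert e.length is None or e.length >= 0

    def test_single_root_and_child_ages_decrease(self):
        res = self.run_collision()
        g = res.genealogy()
        assert g.root.id == 0
        for s in res.species.values():
            if s.parent is not None:
                assert s.birth_age <= res.species[s.parent].birth_age

    def test_three_way_split_appears_as_multifurcation(self, spec1m):
        scen = LandscapeScenario(
            resolution_deg=1.0,
            start_age=15.0,
            end_age=1.0,
            provinces=(Province(lon=0, lat=0, width_deg=32, height_deg=4),),
            episodes=(FragmentationEpisode(0, 8.0, 0.0, 3, 7.0),),
        )
        ls = pr.generate_synthetic_landscape(scen, seed=0)
        res = run_simulation(ls, SimConfig(mode="parapatric", d=2, d_s=5, seed=4))
        assert len(res.extant_ids) == 3
        tree = res.genealogy().to_dendropy()
        assert len(tree.seed_node.child_nodes()) == 3


class TestDiversificationSeries:
    def test_quiet_run_gives_all_zero_rates(self, spec1m):
        ls = twelve_cell_landscape(spec1m)
        res = run_simulation(ls, SimConfig(mode="parapatric", d=4, d_s=5, seed=2))
        ser = diversification_series(res)
        assert (ser["speciation_rate"] == 0).all()
        assert (ser["extinction_rate"] == 0).all()

    def test_one_split_among_n_lineages(self, spec1m):
        scen = LandscapeScenario(
            resolution_deg=1.0,
            start_age=20.0,
            end_age=1.0,
            provinces=(Province(lon=0, lat=0, width_deg=20, height_deg=4),),
            episodes=(FragmentationEpisode(0, 12.0, 0.0, 2, 8.0),),
        )
        ls = pr.generate_synthetic_landscape(scen, seed=0)
        res = run_simulation(ls, SimConfig(mode="parapatric", d=2, d_s=5, seed=4))
        ser = diversification_series(res)
        at_split = ser[ser["age_Ma"] == 12.0].iloc[0]
        # 1 splitting parent among 1 extant lineage -> rate 1.0 per lineage
        assert at_split["speciation_rate"] == pytest.approx(1.0)
        assert at_split["extinction_rate"] == 0.0

    def test_forced_extinction_rate(self, spec1m, rng):
        ls = twelve_cell_landscape(spec1m)
        cfg = SimConfig(mode="sympatric", p_s=0.0, seed=2,
                        forced_extinctions=((5.0, 0.0),))
        res = run_simulation(ls, cfg)
        # build the 8-out-of-10 case directly on the recorded counts
        from paleoreef.simulate import StepRecord

        rec = StepRecord(6.0, 5.0, 10, n_extinct_forced=8, richness_end=2)
        res.steps.append(rec)
        ser = diversification_series(res)
        assert ser.iloc[-1]["extinction_rate"] == pytest.approx(0.8)


class TestTagOrigins:
    def run_tagged(self):
        ls = pr.generate_synthetic_landscape(pr.two_province_collision(), seed=0)
        cfg = SimConfig(mode="parapatric", d=3, d_s=5, seed=42,
                        snapshot_ages=(20.0, 10.0, 5.0))
        res = run_simulation(ls, cfg)
        spec = ls.spec
        cells = np.arange(spec.n_cells)
        lon, _ = spec.centroids(cells)
        regions = {
            "australia": set(cells[lon >= 30].tolist()),
            "tethys": set(cells[lon < 30].tolist()),
        }
        return ls, res, regions

    def test_majority_rule_and_inheritance(self):
        _, res, regions = self.run_tagged()
        tags = tag_origins(res, regions, 20.0)
        assert set(tags.unique()) <= {"tethys", "australia", "untagged"}
        # descendants of tagged species inherit
        for sid, sp in res.species.items():
            if sp.parent is not None and sid in tags and sp.parent in tags:
                if sp.birth_age < 20.0:
                    assert tags[sid] == tags[sp.parent]

    def test_contact_zone_holds_both_faunas_after_merge(self):
        _, res, regions = self.run_tagged()
        tags = tag_origins(res, regions, 20.0)
        maps = tagged_richness_maps(res, tags, 5.0)
        shared = set(maps["tethys"].index) & set(maps["australia"].index)
        assert len(shared) > 0

    def test_overlapping_regions_rejected(self):
        _, res, regions = self.run_tagged()
        bad = {"a": {1, 2, 3}, "b": {3, 4}}
        with pytest.raises(ValueError, match="overlap"):
            tag_origins(res, bad, 20.0)


class TestSimConfigValidation:
    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mode="allopatric")

    def test_missing_mode_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mode="parapatric", d_s=None)
        with pytest.raises(ValueError):
            SimConfig(mode="sympatric", p_s=None)

    def test_out_of_range_values_warn_not_error(self):
        with pytest.warns(UserWarning, match="outside the explored range"):
            SimConfig(d=50, d_s=5)
        with pytest.warns(UserWarning, match="outside the explored range"):
            SimConfig(mode="sympatric", p_s=1e-2)

    def test_bad_forced_extinction_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(forced_extinctions=((66.0, 1.5),))
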