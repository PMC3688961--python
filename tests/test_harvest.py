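"""Harvest: prescription dialect, scheduling, and the three treatments."""

import numpy as np
import pytest

from oakmosaic import (
    CELL_AREA_HA,
    HarvestPrescription,
    Landscape,
    ValidationError,
    apply_clearcut,
    apply_group_selection,
    apply_thinning,
    default_landtypes,
    eligible_stands,
    format_prescription,
    harvest_timestep,
    parse_prescription,
    rank_and_select,
)
from oakmosaic.core import age_at_dbh
from oakmosaic.harvest import (
    StandInfo,
    _draw_opening_size,
    load_default_prescription,
    validate_prescriptions,
)

PLAN_BLOCK = (
    "#Management Area ID#\t8\n"
    "#Ranking algorithm for stand selection:1is random stand selection, "
    "6 is highest average basal area#\t6\n"
    "#Entry year#\t5\n"
    "#Reentry year#\t5\n"
    "#Minimum stand harvest basal area (m^2^)#\t18.36\n"
    "#remove largest tree first#\t1\n"
    "#Proportion of management area to harvest#\t0.03\n"
    "#Target stand basal area (m^2^)#\t18.36\n"
    "#Species priority ranking for harvest#\n"
    "#Pine#\t6\n#Black oak#\t3\n#Red oak#\t4\n#White oak#\t5\n"
    "#Hickory#\t1\n#Maple#\t2\n"
)


def grid_landscape(species, shape, n_stands=1, ba_per_stand=None, landtype_id=1):
    """A landscape split into ``n_stands`` equal column-block stands, one MA."""
    nrows, ncols = shape
    n = nrows * ncols
    stand = (np.arange(n) % ncols) * n_stands // ncols + 1
    land = Landscape(
        species, shape, np.full(n, landtype_id), stand, np.ones(n, int),
        default_landtypes(),
    )
    return land


def fill_uniform(land, name, dbh, ba_target):
    """Give every cell ``ba_target`` m2/ha of one species at a fixed DBH."""
    sp = land.species_set[name]
    age = round(age_at_dbh(sp, dbh) / 5) * 5
    d = sp.dbh(age)
    density = ba_target / (np.pi * (d / 200.0) ** 2)
    for idx in range(land.n_cells):
        land.add_cohort(idx, name, age, density)


class TestPrescriptionDialect:
    def test_parse_management_plan_block(self):
        p = parse_prescription(PLAN_BLOCK)
        assert p.management_area_id == 8
        assert p.ranking == 6
        assert p.entry_year == 5 and p.reentry_interval == 5
        assert p.min_stand_ba == pytest.approx(18.36)
        assert p.remove_largest_first is True
        assert p.area_proportion == pytest.approx(0.03)
        assert p.target_ba == pytest.approx(18.36)
        assert p.species_priority == {
            "hickory": 1, "maple": 2, "black_oak": 3,
            "red_oak": 4, "white_oak": 5, "pine": 6,
        }

    def test_round_trip(self):
        p = parse_prescription(PLAN_BLOCK)
        assert parse_prescription(format_prescription(p)) == p
        gs = HarvestPrescription(3, treatment="group_selection", opening_size_cells=4)
        assert parse_prescription(format_prescription(gs)) == gs

    def test_packaged_default_matches_plan_block(self):
        assert load_default_prescription() == parse_prescription(PLAN_BLOCK)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError, match="unrecognized"):
            parse_prescription("#Management Area ID# 1\n#Rotation length# 80\n")

    def test_priority_must_be_permutation(self):
        with pytest.raises(ValidationError, match="permutation"):
            HarvestPrescription(1, species_priority={"pine": 1, "maple": 3})


class TestEligibility:
    def make(self, sid, ba, area=10.0):
        return StandInfo(sid, ba, area, np.array([]))

    def test_below_floor_excluded(self):
        p = HarvestPrescription(1)
        out = eligible_stands([self.make(1, 10.0)], p, year=10)
        assert out == []

    def test_all_below_floor_empty(self):
        p = HarvestPrescription(1)
        stands = [self.make(i, 5.0 + i) for i in range(5)]
        assert eligible_stands(stands, p, year=10) == []

    def test_reentry_boundary_inclusive(self):
        p = HarvestPrescription(1, reentry_interval=5)
        s = self.make(1, 25.0)
        assert eligible_stands([s], p, 10, {1: 5.0}) == [s]
        assert eligible_stands([s], p, 9, {1: 5.0}) == []

    def test_before_entry_year_nothing(self):
        p = HarvestPrescription(1, entry_year=5)
        assert eligible_stands([self.make(1, 25.0)], p, year=0) == []


class TestRankAndSelect:
    def test_highest_ba_first_with_id_ties(self):
        p = HarvestPrescription(1, ranking=6)
        stands = [StandInfo(1, 25.0, 8.1, np.array([])),
                  StandInfo(2, 30.0, 8.1, np.array([])),
                  StandInfo(3, 20.0, 8.1, np.array([]))]
        sel = rank_and_select(stands, p, ma_area_ha=810.0, rng=np.random.default_rng(0))
        assert [s.mean_ba for s in sel[:1]] == [30.0]

    def test_selection_stops_at_area_crossing(self):
        p = HarvestPrescription(1, area_proportion=0.03)
        stands = [StandInfo(i, 30.0 - i, 8.1, np.array([])) for i in range(10)]
        sel = rank_and_select(stands, p, ma_area_ha=270.0, rng=np.random.default_rng(0))
        # target 8.1 ha: one stand crosses it exactly
        assert len(sel) == 1

    def test_cumulative_area_meets_proportion(self):
        p = HarvestPrescription(1, area_proportion=0.03)
        stands = [StandInfo(i, 25.0, 8.1, np.array([])) for i in range(100)]
        ma_area = 100 * 8.1
        sel = rank_and_select(stands, p, ma_area, rng=np.random.default_rng(0))
        assert sum(s.area_ha for s in sel) >= 0.03 * ma_area - 1e-9

    def test_random_ranking_reproducible_and_seed_dependent(self):
        p = HarvestPrescription(1, ranking=1)
        stands = [StandInfo(i, 25.0, 8.1, np.array([])) for i in range(30)]
        ma_area = 1e6  # select everything; observe the order
        a = rank_and_select(stands, p, ma_area, np.random.default_rng(1))
        b = rank_and_select(stands, p, ma_area, np.random.default_rng(1))
        c = rank_and_select(stands, p, ma_area, np.random.default_rng(2))
        assert [s.id for s in a] == [s.id for s in b]
        assert [s.id for s in a] != [s.id for s in c]


class TestThinning:
    def test_stand_at_target_untouched(self, species):
        land = grid_landscape(species, (2, 2))
        fill_uniform(land, "pine", 30.0, 18.36)
        before = land.density.copy()
        removed = apply_thinning(land, np.arange(4), load_default_prescription())
        assert removed.sum() == 0
        assert np.array_equal(land.density, before)

    def test_priority_species_removed_before_others(self, species):
        # hickory (rank 1) is exhausted before any pine (rank 6) is touched,
        # then pine largest-first until the stand mean reaches the target
        land = grid_landscape(species, (2, 2))
        fill_uniform(land, "hickory", 25.0, 5.0)
        fill_uniform(land, "pine", 30.0, 15.0)
        fill_uniform(land, "pine", 45.0, 10.0)
        cells = np.arange(4)
        pre_ba = land.ba_by_species().mean(axis=1)
        removed = apply_thinning(land, cells, load_default_prescription())
        post = land.ba_by_species().mean(axis=1)
        ih, ip = species.index("hickory"), species.index("pine")
        assert post[ih] == pytest.approx(0.0, abs=1e-9)          # all hickory gone
        mean_ba = land.total_ba()[cells].mean()
        assert mean_ba <= 18.36 + 1e-9
        # largest pine cohort reduced, smaller pine cohort untouched
        ss = land.species_set
        big_bin = np.argmax(removed[ip].sum(axis=1))
        assert ss.dbh_table[ip, big_bin] > 40.0
        small_bins = removed[ip, ss.dbh_table[ip] < 35.0].sum()
        assert small_bins == 0

    def test_matches_single_tree_greedy_oracle(self, species):
        """Residual equals a brute-force oracle removing one whole tree at a
        time in (priority rank, DBH desc) order until mean BA <= target."""
        land = grid_landscape(species, (1, 2))
        fill_uniform(land, "hickory", 25.0, 5.0)
        fill_uniform(land, "pine", 40.0, 25.0)
        p = load_default_prescription()
        cells = np.arange(2)

        # oracle on a copy, cohort ledger as (species, bin, cell) tree counts
        oracle = land.copy()
        ss = oracle.species_set
        rank = {n: p.species_priority[n] for n in ss.names}
        entries = sorted(
            ((s, a, c) for s, a, c in zip(*np.nonzero(oracle.density))),
            key=lambda t: (rank[ss.names[t[0]]], -ss.dbh_table[t[0], t[1]], t[2]),
        )
        n = cells.size
        for s, a, c in entries:
            while oracle.density[s, a, c] > 0 and oracle.total_ba()[cells].mean() > p.target_ba:
                take = min(1.0 / CELL_AREA_HA, oracle.density[s, a, c])
                oracle.density[s, a, c] -= take
        apply_thinning(land, cells, p)
        assert land.total_ba()[cells].mean() == pytest.approx(
            oracle.total_ba()[cells].mean(), abs=1e-6
        )

    def test_residual_never_above_target(self, species):
        rng = np.random.default_rng(3)
        for trial in range(5):
            land = grid_landscape(species, (3, 3))
            for name in ("pine", "red_oak", "hickory"):
                fill_uniform(land, name, float(rng.uniform(15, 50)),
                             float(rng.uniform(5, 15)))
            apply_thinning(land, np.arange(9), load_default_prescription())
            assert land.total_ba()[np.arange(9)].mean() <= 18.36 + 1e-9


class TestClearcut:
    def test_residual_zero_and_ledger_conserves(self, species):
        land = grid_landscape(species, (2, 3))
        fill_uniform(land, "red_oak", 35.0, 20.0)
        pre = land.total_ba().copy()
        removed = apply_clearcut(land, np.arange(6))
        assert land.total_ba().sum() == 0.0
        got = np.einsum("sac,sa->c", removed, land.species_set.ba_tree)
        assert got == pytest.approx(pre, rel=1e-12)

    def test_empty_stand_zero_ledger(self, species):
        land = grid_landscape(species, (2, 2))
        removed = apply_clearcut(land, np.arange(4))
        assert removed.sum() == 0.0


class TestGroupSelection:
    def test_only_opening_cells_touched_and_contiguous(self, species):
        land = grid_landscape(species, (10, 10))
        fill_uniform(land, "white_oak", 30.0, 20.0)
        p = HarvestPrescription(1, treatment="group_selection", opening_size_cells=3)
        stand_cells = np.arange(100)
        removed, opening = apply_group_selection(land, stand_cells, p,
                                                 np.random.default_rng(0))
        outside = np.setdiff1d(stand_cells, opening)
        assert np.all(land.total_ba()[opening] == 0.0)
        assert np.all(land.total_ba()[outside] > 0.0)
        # rook contiguity of the opening
        rows, cols = np.divmod(opening, 10)
        seen = {(rows[0], cols[0])}
        frontier = [(rows[0], cols[0])]
        pts = set(zip(rows.tolist(), cols.tolist()))
        while frontier:
            r, c = frontier.pop()
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if nb in pts and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        assert seen == pts

    def test_opening_larger_than_stand_clears_whole_stand(self, species):
        land = grid_landscape(species, (2, 2))
        fill_uniform(land, "pine", 30.0, 20.0)
        p = HarvestPrescription(1, treatment="group_selection", opening_size_cells=50)
        removed, opening = apply_group_selection(land, np.arange(4), p,
                                                 np.random.default_rng(0))
        assert opening.size == 4
        assert land.total_ba().sum() == 0.0

    def test_opening_size_distribution_mean(self):
        rng = np.random.default_rng(0)
        draws = [_draw_opening_size(3.0, rng) for _ in range(1000)]
        # E[max(1, Poisson(3))] = 3 + P(X=0) = 3.0498
        assert np.mean(draws) == pytest.approx(3.05, abs=0.2)
        assert min(draws) >= 1


class TestHarvestTimestep:
    def prescriptions(self, **kw):
        return {1: HarvestPrescription(1, **kw)}

    def test_identity_before_entry_year(self, species):
        land = grid_landscape(species, (4, 4), n_stands=4)
        fill_uniform(land, "pine", 35.0, 25.0)
        out, rec = harvest_timestep(land, self.prescriptions(entry_year=5), 0,
                                    np.random.default_rng(0))
        assert out.state_equal(land)
        assert rec.removed_ba_by_species.sum() == 0.0

    def test_no_prescriptions_identity(self, species):
        land = grid_landscape(species, (4, 4))
        fill_uniform(land, "pine", 35.0, 25.0)
        out, rec = harvest_timestep(land, {}, 5, np.random.default_rng(0))
        assert out.state_equal(land)

    @pytest.mark.parametrize("treatment", ["thinning", "clearcut", "group_selection"])
    def test_conservation_pre_equals_post_plus_ledger(self, species, treatment):
        land = grid_landscape(species, (6, 6), n_stands=3)
        fill_uniform(land, "red_oak", 35.0, 15.0)
        fill_uniform(land, "hickory", 20.0, 10.0)
        pre = land.total_ba().mean()
        kw = dict(treatment=treatment)
        if treatment == "clearcut":
            kw["target_ba"] = 0.0
        out, rec = harvest_timestep(land, self.prescriptions(**kw), 5,
                                    np.random.default_rng(0))
        assert rec.pre_mean_ba == pytest.approx(pre, rel=1e-12)
        assert rec.pre_mean_ba - rec.post_mean_ba == pytest.approx(
            rec.removed_ba_by_species.sum(), abs=1e-9
        )

    def test_group_selection_cleared_area_reaches_proportion(self, species):
        land = grid_landscape(species, (10, 10), n_stands=10)
        fill_uniform(land, "white_oak", 30.0, 25.0)
        pres = self.prescriptions(treatment="group_selection", area_proportion=0.1,
                                  opening_size_cells=2)
        out, rec = harvest_timestep(land, pres, 5, np.random.default_rng(1))
        assert rec.area_treated_ha >= 0.1 * land.total_area_ha - 1e-9

    def test_prescription_keyed_to_wrong_ma_rejected(self, species):
        land = grid_landscape(species, (2, 2))
        with pytest.raises(ValidationError):
            validate_prescriptions({2: HarvestPrescription(1)}, land)
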