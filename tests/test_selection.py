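import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchlink.grids import LandscapeError
from patchlink.home_range import HomeRange
from patchlink.selection import (
    SelectionTable,
    availability_within_range,
    build_functional_map,
    selection_test,
    usable_fraction,
)
from patchlink.selection import _agresti_coull
from patchlink.synthetic import attach_structural_layer

from conftest import functional_landscape


def whole_plot_range(landscape):
    return HomeRange(
        mask=np.ones(landscape.class_grid.shape, bool),
        isopleth_level=0.95,
        cell_size_m=landscape.cell_size_m,
        origin_xy=landscape.origin_xy,
    )


class TestAvailability:
    def test_uniform_landscape(self):
        ls = functional_landscape(np.full((6, 6), 2))
        avail = availability_within_range(ls, whole_plot_range(ls))
        assert avail[2] == 1.0
        assert sum(avail.values()) == 1.0

    def test_half_and_half_mask(self):
        grid = np.zeros((4, 4), int)
        grid[:, 2:] = 2
        grid[:, :2] = 1
        ls = functional_landscape(grid)
        hr = HomeRange(
            mask=np.ones((4, 4), bool), isopleth_level=0.95, cell_size_m=10.0, origin_xy=(0, 0)
        )
        avail = availability_within_range(ls, hr)
        assert avail[1] == 0.5 and avail[2] == 0.5

    def test_whole_plot_natural_shrubland_share(self, natural_small):
        # shrubland is 47.5 % of the clumped plot's surface
        avail = availability_within_range(natural_small, whole_plot_range(natural_small))
        assert avail[1] == pytest.approx(0.475, abs=0.02)

    def test_empty_overlap(self, natural_small):
        hr = HomeRange(
            mask=np.zeros((5, 5), bool),
            isopleth_level=0.95,
            cell_size_m=10.0,
            origin_xy=(1e6, 1e6),
        )
        with pytest.raises(LandscapeError, match="overlap"):
            availability_within_range(natural_small, hr)


class TestSelectionTest:
    def test_use_proportional_to_availability(self):
        avail = {1: 0.5, 2: 0.3, 3: 0.2}
        table = selection_test({1: 50, 2: 30, 3: 20}, avail)
        assert table.chi_square == 0.0
        assert table.p_value == 1.0
        assert set(table.table["call"]) == {"neutral"}
        assert table.df == 2

    def test_roads_strongly_selected(self):
        # 31 of 100 foraging fixes on roads available at 1 %
        table = selection_test({30: 31, 10: 69}, {30: 0.01, 10: 0.99})
        row = table.table.set_index("cover").loc[30]
        assert row["call"] == "selected"
        assert table.p_value < 0.001
        # brute-force multinomial oracle for the chi-square p-value
        rng = np.random.default_rng(0)
        draws = rng.multinomial(100, [0.01, 0.99], size=200000)
        exp = np.array([1.0, 99.0])
        sim = (((draws - exp) ** 2) / exp).sum(axis=1)
        assert (sim >= table.chi_square).mean() < 0.001

    def test_agresti_coull_interval_example(self):
        lo, hi = _agresti_coull(31, 100, 1.959963984540054)
        assert lo == pytest.approx(0.2275, abs=2e-4)
        assert hi == pytest.approx(0.4066, abs=2e-4)

    def test_zero_availability_used_flagged(self):
        table = selection_test({1: 5, 2: 5}, {1: 0.0, 2: 1.0})
        row = table.table.set_index("cover").loc[1]
        assert row["call"] == "selected"
        assert table.df == 0  # only one tested category

    def test_used_props_sum_to_one(self):
        table = selection_test({1: 3, 2: 7, 3: 0}, {1: 0.2, 2: 0.5, 3: 0.3})
        assert table.table["used_prop"].sum() == pytest.approx(1.0)
        assert table.table["avail_prop"].sum() == pytest.approx(1.0)

    def test_category_absent_from_availability(self):
        with pytest.raises(ValueError, match="absent"):
            selection_test({1: 5, 9: 1}, {1: 1.0})

    @given(
        counts=st.lists(st.integers(0, 60), min_size=3, max_size=5),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_widening_conf_never_creates_calls(self, counts, seed):
        # CI is monotone in conf: a neutral call cannot become directional
        if sum(counts) == 0:
            counts[0] = 1
        k = len(counts)
        rng = np.random.default_rng(seed)
        avail = rng.dirichlet(np.ones(k))
        used = dict(enumerate(counts))
        t1 = selection_test(used, dict(enumerate(avail)), conf=0.90)
        t2 = selection_test(used, dict(enumerate(avail)), conf=0.99)
        for c in t1.table["cover"]:
            call1 = t1.table.set_index("cover").loc[c, "call"]
            call2 = t2.table.set_index("cover").loc[c, "call"]
            if call1 == "neutral":
                assert call2 == "neutral"


def _vote_table(individual, behavior, selected_covers, all_covers):
    rows = [
        {
            "cover": c,
            "used_count": 10,
            "used_prop": 0.5,
            "avail_prop": 0.1,
            "ci_low": 0.3 if c in selected_covers else 0.0,
            "ci_high": 0.7,
            "call": "selected" if c in selected_covers else "neutral",
        }
        for c in all_covers
    ]
    return SelectionTable(
        table=pd.DataFrame(rows),
        chi_square=1.0,
        df=1,
        p_value=0.5,
        conf=0.95,
        behavior=behavior,
        individual=individual,
    )


class TestBuildFunctionalMap:
    def make_structural(self):
        grid = np.array([[10, 10, 30], [40, 40, 30], [20, 20, 20]])
        legend = {10: "open shrubland", 20: "pinewood", 30: "road", 40: "pasture"}
        from patchlink.grids import GridLandscape

        return GridLandscape(grid, 10.0, legend, level="structural")

    def test_unanimous_nesting_selection(self):
        st_ls = self.make_structural()
        covers = [10, 20, 30, 40]
        tables = []
        for i in range(10):
            tables.append(_vote_table(f"b{i}", "nesting", [10], covers))
            tables.append(_vote_table(f"b{i}", "roosting", [20], covers))
            tables.append(_vote_table(f"b{i}", "foraging", [30], covers))
        assignment, functional = build_functional_map(tables, st_ls)
        assert assignment.mapping == {10: 1, 20: 2, 30: 3, 40: 0}
        assert functional.level == "functional"
        assert np.array_equal(
            functional.class_grid, np.array([[1, 1, 3], [0, 0, 3], [2, 2, 2]])
        )

    def test_no_selection_all_non_usable(self):
        st_ls = self.make_structural()
        tables = [
            _vote_table("b1", b, [], [10, 20, 30, 40])
            for b in ("nesting", "roosting", "foraging")
        ]
        assignment, _ = build_functional_map(tables, st_ls)
        assert set(assignment.mapping.values()) == {0}

    def test_simple_majority_wins(self):
        # 6 of 10 select roads when foraging, 4 neutral -> roads are foraging
        st_ls = self.make_structural()
        covers = [10, 20, 30, 40]
        tables = []
        for i in range(10):
            tables.append(_vote_table(f"b{i}", "nesting", [10], covers))
            tables.append(_vote_table(f"b{i}", "roosting", [20], covers))
            tables.append(_vote_table(f"b{i}", "foraging", [30] if i < 6 else [], covers))
        assignment, _ = build_functional_map(tables, st_ls)
        assert assignment.mapping[30] == 3

    def test_exact_half_is_not_a_majority(self):
        st_ls = self.make_structural()
        covers = [10, 20, 30, 40]
        tables = []
        for i in range(10):
            tables.append(_vote_table(f"b{i}", "nesting", [10], covers))
            tables.append(_vote_table(f"b{i}", "roosting", [20], covers))
            tables.append(_vote_table(f"b{i}", "foraging", [30] if i < 5 else [], covers))
        assignment, _ = build_functional_map(tables, st_ls)
        assert assignment.mapping[30] == 0

    def test_missing_behavior_rejected(self):
        st_ls = self.make_structural()
        tables = [_vote_table("b1", "nesting", [10], [10, 20, 30, 40])]
        with pytest.raises(ValueError, match="roosting"):
            build_functional_map(tables, st_ls)

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError, match="no selection tables"):
            build_functional_map([], self.make_structural())


class TestUsableFraction:
    def test_all_non_usable(self):
        assert usable_fraction(functional_landscape(np.zeros((3, 3), int))) == 0.0

    def test_hand_counted(self):
        grid = np.zeros((4, 4), int)
        grid.ravel()[:5] = [1, 2, 3, 1, 2]
        assert usable_fraction(functional_landscape(grid)) == 0.3125

    def test_study_usable_fractions_on_synthetic_plots(self, natural_small, managed_small):
        assert usable_fraction(natural_small) == pytest.approx(0.609, abs=0.02)
        assert usable_fraction(managed_small) == pytest.approx(0.741, abs=0.02)

    def test_structural_input_rejected(self, natural_small):
        st_ls, _ = attach_structural_layer(
            natural_small, {c: {c + 100: 1.0} for c in range(4)}, seed=0
        )
        with pytest.raises(LandscapeError, match="functional"):
            usable_fraction(st_ls)
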