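"""Time-window construction, imputation, and trajectory grouping."""

import numpy as np
import pandas as pd
import pytest

from cordbmi.growth import GrowthSeries
from cordbmi.trajectory import (
    WindowedMatrix,
    build_windows,
    build_standard_windows,
    classify_trajectories,
    collapse_groups,
    impute_adjacent,
    lowess_curve,
    window_average,
)


def flat_series(n, age_values, prefix="c", sex="F", bmi=16.0):
    return [
        GrowthSeries(f"{prefix}{i}", sex, list(age_values), [bmi] * len(age_values))
        for i in range(n)
    ]


class TestBuildWindows:
    def test_single_shared_age_yields_one_window(self):
        windows = build_windows(flat_series(40, [60.0]))
        assert len(windows) == 1
        assert windows[0].contains(60.0)
        assert windows[0].n_children == 40

    def test_wide_gap_forces_two_windows(self):
        series = flat_series(60, [6.0]) + flat_series(60, [30.0], prefix="d")
        windows = build_windows(series)
        assert len(windows) == 2
        for w in windows:
            assert w.width <= 12.0
            assert w.n_children >= 30
        assert windows[0].contains(6.0) and windows[1].contains(30.0)

    def test_too_small_cohort_errors(self):
        with pytest.raises(ValueError):
            build_windows(flat_series(10, [60.0]))

    def test_generated_cohort_satisfies_constraints(self, default_cohort, standard_windows):
        """Every emitted window has >= 30 children and width <= 12 months."""
        assert len(standard_windows) >= 10
        for w in standard_windows:
            assert w.n_children >= 30
            assert w.width <= 12.0 + 1e-9
        bounds = [(w.age_lo, w.age_hi) for w in standard_windows]
        assert bounds == sorted(bounds)
        for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
            assert hi1 <= lo2 + 1e-9  # disjoint, ordered

    def test_percentile_windows_start_at_two_years(self, standard_windows):
        pct = [w for w in standard_windows if w.age_lo >= 24.0 - 1e-9]
        assert pct, "no windows at or above 24 months"
        below = [w for w in standard_windows if w.age_hi <= 24.0 + 1e-9]
        assert len(pct) + len(below) == len(standard_windows)


class TestWindowAverage:
    def test_mean_of_visits_in_window(self):
        s = [GrowthSeries("c0", "F", [10.0, 11.0], [30.2, 29.8])]
        windows = build_windows(flat_series(30, [10.5]) + s, min_n=5)
        wm = window_average(s, windows)
        assert wm.values.loc["c0"].iloc[0] == pytest.approx(30.0)

    def test_no_visit_is_missing_single_visit_is_value(self):
        anchor = flat_series(30, [6.0]) + flat_series(30, [30.0], prefix="d")
        s = GrowthSeries("x", "F", [30.0], [17.5])
        windows = build_windows(anchor)
        wm = window_average(anchor + [s], windows)
        assert np.isnan(wm.values.loc["x", windows[0].index])
        assert not wm.observed.loc["x", windows[0].index]
        assert wm.values.loc["x", windows[1].index] == pytest.approx(17.5)


def matrix_from_rows(rows):
    vals = pd.DataFrame(rows, dtype=float)
    return WindowedMatrix(
        values=vals,
        observed=vals.notna(),
        mean_age=vals * 0 + 1.0,
        windows=[],
        kind="BMIPCT",
    )


class TestImputeAdjacent:
    def test_interior_and_edge_rules(self):
        out = impute_adjacent(matrix_from_rows([[np.nan, 40.0, np.nan, 60.0, np.nan]]))
        assert list(out.values.iloc[0]) == [40.0, 40.0, 50.0, 60.0, 60.0]
        assert list(out.provenance.iloc[0]) == [
            "edge_filled", "observed", "interpolated", "observed", "edge_filled",
        ]

    def test_long_gap_brackets_same_pair(self):
        out = impute_adjacent(matrix_from_rows([[70.0, np.nan, np.nan, 30.0]]))
        assert list(out.values.iloc[0]) == [70.0, 50.0, 50.0, 30.0]

    def test_fully_observed_row_unchanged_and_idempotent(self):
        m = matrix_from_rows([[10.0, 20.0, 30.0]])
        out = impute_adjacent(m)
        assert list(out.values.iloc[0]) == [10.0, 20.0, 30.0]
        twice = impute_adjacent(impute_adjacent(matrix_from_rows([[np.nan, 40.0, np.nan]])))
        once = impute_adjacent(matrix_from_rows([[np.nan, 40.0, np.nan]]))
        assert twice.values.equals(once.values)

    def test_all_missing_row_errors(self):
        with pytest.raises(ValueError):
            impute_adjacent(matrix_from_rows([[np.nan, np.nan]]))


def synthetic_matrix(n_per_group=60, n_windows=12, seed=0, levels=(90.0, 30.0)):
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    for g, level in enumerate(levels):
        for i in range(n_per_group):
            rows.append(level + rng.normal(0, 3, n_windows))
            ids.append(f"g{g}_{i}")
    vals = pd.DataFrame(rows, index=ids)
    return WindowedMatrix(
        values=vals, observed=vals.notna(), mean_age=vals * 0 + 1,
        windows=[], kind="BMIPCT",
    )


class TestClassifyTrajectories:
    def test_recovers_well_separated_levels(self):
        m = synthetic_matrix()
        out = classify_trajectories(m, seed=0)
        clusters = out["kmeans_cluster"].to_numpy()
        planted = np.array([1] * 60 + [2] * 60)
        assert np.array_equal(clusters, planted)
        assert out.attrs["var_explained"]["pc1"] > 0.8

    def test_duplicating_children_preserves_assignments(self):
        m = synthetic_matrix()
        out1 = classify_trajectories(m, seed=0)
        dup_vals = pd.concat([m.values, m.values.set_axis([f"{i}_dup" for i in m.values.index])])
        m2 = WindowedMatrix(dup_vals, dup_vals.notna(), dup_vals * 0 + 1, [], "BMIPCT")
        out2 = classify_trajectories(m2, seed=0)
        assert (out2.loc[out1.index, "group4"] == out1["group4"]).all()

    def test_invariant_to_child_ordering(self):
        m = synthetic_matrix()
        out1 = classify_trajectories(m, seed=0)
        perm = m.values.sample(frac=1.0, random_state=7)
        m2 = WindowedMatrix(perm, perm.notna(), perm * 0 + 1, [], "BMIPCT")
        out2 = classify_trajectories(m2, seed=0)
        assert (out2.loc[out1.index, "group4"] == out1["group4"]).all()

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError):
            classify_trajectories(matrix_from_rows([[1.0, np.nan]]), seed=0)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            classify_trajectories(matrix_from_rows([[1.0, 1.0], [1.0, 1.0]]), seed=0)


def test_collapse_groups_mapping():
    asg = pd.DataFrame({"group4": ["NW-A", "NW-B", "early-OWO", "late-OWO"]})
    out = collapse_groups(asg)
    assert list(out["group3"]) == ["NW", "NW", "early-OWO", "late-OWO"]


class TestLowess:
    def test_constant_input_gives_constant_curve(self):
        curve = lowess_curve(np.arange(20.0), np.full(20, 50.0))
        assert curve["value"].to_numpy() == pytest.approx(np.full(20, 50.0))

    def test_linear_input_recovered(self):
        x = np.linspace(0, 100, 50)
        curve = lowess_curve(x, 2.0 * x + 5.0, frac=0.5)
        assert curve["value"].to_numpy() == pytest.approx(2.0 * x + 5.0, abs=1e-6)

    def test_noisy_sigmoid_recovered(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 200, 500))
        truth = 40 + 50 / (1 + np.exp(-(x - 100) / 15))
        y = truth + rng.normal(0, 2, 500)
        curve = lowess_curve(x, y, frac=0.2)
        interp = np.interp(x, curve["age_months"], curve["value"])
        inner = (x > 10) & (x < 190)
        assert np.max(np.abs(interp[inner] - truth[inner])) < 3.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            lowess_curve([1, 2, 3], [1, 2, 3])
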