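"""Trace table I/O and preprocessing into corrected expression series."""

import numpy as np
import pandas as pd
import pytest

from stresstiming import (
    PreprocessConfig,
    compute_expression,
    doubling_series,
    extract_trajectories,
    growth_rate_series,
    normalize_traces,
    population_average,
    read_trace_table,
    simulate_lineage,
    write_trace_table,
)
from stresstiming.traces import ExpressionTraceSet, moving_average, validate_trace_table


def small_table():
    return pd.DataFrame(
        {
            "colony_id": "c",
            "cell_id": [1, 1, 1, 2, 2],
            "parent_id": pd.array([None, None, None, 1, 1], dtype="Int64"),
            "frame": [0, 1, 2, 3, 4],
            "time_h": [-0.5, 0.0, 0.5, 1.0, 1.5],
            "area": [100.0, 110.0, 120.0, 65.0, 70.0],
            "fluor_yfp": [1000.0, 1200.0, 1500.0, 900.0, 1100.0],
            "bg_yfp": [2.0, 2.0, 2.0, 2.0, 2.0],
        }
    )


class TestTraceTableIO:
    def test_simulator_output_round_trips(self, tmp_path, noisy_colony):
        _, table, _, _ = noisy_colony
        path = tmp_path / "traces.tsv"
        write_trace_table(table, path)
        back = read_trace_table(path)
        pd.testing.assert_frame_equal(back, table, check_dtype=False)

    def test_unknown_extra_columns_preserved_with_warning(self):
        df = small_table()
        df["custom_score"] = 1.0
        with pytest.warns(UserWarning, match="custom_score"):
            out = validate_trace_table(df)
        assert "custom_score" in out.columns

    def test_orphan_parent_rejected(self):
        df = small_table()
        df.loc[3:, "parent_id"] = 99
        with pytest.raises(ValueError, match="absent parent"):
            validate_trace_table(df)

    def test_non_monotone_times_rejected(self):
        df = small_table()
        df.loc[2, "time_h"] = -1.0
        with pytest.raises(ValueError, match="strictly increasing"):
            validate_trace_table(df)

    def test_nonpositive_area_rejected(self):
        df = small_table()
        df.loc[1, "area"] = 0.0
        with pytest.raises(ValueError, match="area"):
            validate_trace_table(df)

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="area"):
            validate_trace_table(small_table().drop(columns=["area"]))


class TestComputeExpression:
    def test_constant_background_and_autofluorescence(self):
        df = small_table().iloc[:1].copy()
        df["fluor_yfp"] = 1000.0
        df["area"] = 100.0
        cfg = PreprocessConfig(background_mode="constant")
        out = compute_expression(
            df, cfg, background={"yfp": 2.0}, autofluorescence={"yfp": 3.0}
        )
        assert out.data["expr_yfp"].iloc[0] == pytest.approx(1000 / 100 - 2 - 3)

    def test_dynamic_autofluorescence_per_frame(self):
        df = small_table().iloc[:3].copy()
        df["fluor_yfp"] = df["area"] * 10.0  # per-area 10 before background
        df["bg_yfp"] = 0.0
        cfg = PreprocessConfig(autofluorescence_mode="per_timepoint")
        control = pd.Series([3.0, 4.0, 5.0], index=[0, 1, 2])
        out = compute_expression(df, cfg, autofluorescence={"yfp": control})
        np.testing.assert_allclose(out.data["expr_yfp"], [7.0, 6.0, 5.0])

    def test_control_series_must_cover_grid(self):
        df = small_table()
        cfg = PreprocessConfig(autofluorescence_mode="per_timepoint")
        control = pd.Series([3.0, 4.0], index=[0, 1])
        with pytest.raises(ValueError, match="cover"):
            compute_expression(df, cfg, autofluorescence={"yfp": control})

    def test_negative_expression_retained(self):
        df = small_table().iloc[:1].copy()
        df["fluor_yfp"] = 100.0
        df["area"] = 100.0  # per-area 1.0, background 2.0 -> -1.0, then -3
        out = compute_expression(df, autofluorescence={"yfp": 3.0})
        assert out.data["expr_yfp"].iloc[0] == pytest.approx(-4.0)

    def test_linearity_in_totals_and_background(self):
        df = small_table()
        base = compute_expression(df).data["expr_yfp"]
        scaled = df.copy()
        scaled["fluor_yfp"] *= 3.0
        scaled["bg_yfp"] *= 3.0
        out = compute_expression(scaled).data["expr_yfp"]
        np.testing.assert_allclose(out, 3.0 * base)


class TestNormalizeTraces:
    def _expr(self, values_by_cell):
        rows = []
        for cid, vals in values_by_cell.items():
            for frame, v in enumerate(vals):
                rows.append(
                    {
                        "colony_id": "c",
                        "cell_id": cid,
                        "parent_id": pd.NA,
                        "frame": frame,
                        "time_h": float(frame),
                        "area": 1.0,
                        "expr_yfp": float(v),
                    }
                )
        return ExpressionTraceSet(pd.DataFrame(rows), ["yfp"])

    def test_own_max_scales_each_cell(self):
        out = normalize_traces(self._expr({1: [0, 5, 10]}), "own_max")
        np.testing.assert_allclose(out.data["expr_yfp"], [0, 0.5, 1.0])

    def test_median_full_response_preserves_cell_ratios(self):
        expr = self._expr({1: [0, 2, 4], 2: [0, 4, 8]})
        out = normalize_traces(expr, "median_full_response")
        a = out.data[out.data.cell_id == 1]["expr_yfp"].to_numpy()
        b = out.data[out.data.cell_id == 2]["expr_yfp"].to_numpy()
        np.testing.assert_allclose(b[1:] / a[1:], 2.0)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant|zero"):
            normalize_traces(self._expr({1: [5, 5, 5]}), "own_max")
        with pytest.raises(ValueError, match="zero"):
            normalize_traces(self._expr({1: [5, 5, 5]}), "median_full_response")


class TestGrowthRateSeries:
    def test_recovers_exponential_rate(self):
        t = np.linspace(0, 5, 23)
        _, rate = growth_rate_series(t, np.exp(0.5 * t))
        np.testing.assert_allclose(rate, 0.5, rtol=1e-9)

    def test_constant_size_gives_zero(self):
        t = np.linspace(0, 5, 10)
        _, rate = growth_rate_series(t, np.full_like(t, 3.0))
        np.testing.assert_allclose(rate, 0.0, atol=1e-12)

    def test_window_one_returns_raw_differences(self):
        t = np.array([0.0, 1.0, 2.0])
        s = np.array([1.0, 2.0, 8.0])
        _, rate = growth_rate_series(t, s, window=1)
        np.testing.assert_allclose(rate, [np.log(2), np.log(4)])

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            growth_rate_series(np.array([0.0, 1.0]), np.array([1.0, -1.0]))

    def test_noiseless_simulator_rate_recovered(self, noiseless_colony):
        config, _, _, tree = noiseless_colony
        cell = tree.cells[tree.founders[0]]
        _, rate = growth_rate_series(cell.times, cell.sizes)
        np.testing.assert_allclose(rate, config.growth_rate_mean, rtol=1e-10)


class TestDoublingSeries:
    def _path_segments(self, tree):
        leaf = tree.leaves[0]
        path = tree.path_to_root(leaf)
        return [(tree.cells[c].times, tree.cells[c].sizes) for c in path]

    def test_noiseless_doubling_time_gives_linear_series(self, noiseless_colony):
        config, _, _, tree = noiseless_colony
        segments = self._path_segments(tree)
        times, doublings = doubling_series(segments)
        tau = np.log(2) / config.growth_rate_mean
        np.testing.assert_allclose(doublings, times / tau, rtol=1e-6, atol=1e-9)

    def test_zero_doublings_at_stress_addition(self, noiseless_colony):
        _, _, _, tree = noiseless_colony
        times, doublings = doubling_series(self._path_segments(tree))
        assert np.interp(0.0, times, doublings) == pytest.approx(0.0, abs=1e-9)

    def test_continuous_across_divisions(self, noisy_colony):
        config, _, _, tree = noisy_colony
        leaf = tree.leaves[0]
        path = tree.path_to_root(leaf)
        segments = [(tree.cells[c].times, tree.cells[c].sizes) for c in path]
        times, doublings = doubling_series(segments)
        # no jump larger than ~one frame's growth at the fastest observed rate
        max_rate = max(tree.cells[c].growth_rate for c in path) / np.log(2)
        jumps = np.abs(np.diff(doublings))
        assert jumps.max() < 2.0 * max_rate * config.frame_interval

    def test_integrates_growth_rate(self, noiseless_colony):
        # doublings == integral of growth rate / ln 2 in the noiseless case
        config, _, _, tree = noiseless_colony
        times, doublings = doubling_series(self._path_segments(tree))
        expected = config.growth_rate_mean * times / np.log(2)
        mask = times > 0.5
        rel = np.abs(doublings[mask] - expected[mask]) / np.abs(expected[mask])
        assert rel.max() < 0.01

    def test_single_frame_first_segment_rejected(self):
        with pytest.raises(ValueError, match="extrapolation"):
            doubling_series(
                [
                    (np.array([0.0]), np.array([1.0])),
                    (np.array([1.0, 2.0]), np.array([0.6, 0.7])),
                ]
            )


class TestPopulationAverage:
    def test_identical_traces_have_zero_sd(self):
        tr = np.array([0.0, 1.0, 4.0, 2.0])
        mean, sd = population_average([tr, tr, tr])
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)
        np.testing.assert_allclose(mean, (tr - tr.min()) / np.ptp(tr))

    def test_invariant_to_prior_normalization(self):
        tr = np.array([1.0, 3.0, 9.0])
        normed = (tr - tr.min()) / np.ptp(tr)
        m1, s1 = population_average([tr, tr])
        m2, s2 = population_average([normed, normed])
        np.testing.assert_allclose(m1, m2)
        np.testing.assert_allclose(s1, s2)

    def test_output_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        traces = [np.cumsum(rng.uniform(0, 1, 30)) for _ in range(7)]
        mean, sd = population_average(traces)
        assert mean.min() >= 0 and mean.max() <= 1

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="length"):
            population_average([np.arange(3.0), np.arange(4.0)])


class TestMovingAverage:
    def test_symmetric_shrinking_edges(self):
        x = np.array([0.0, 3.0, 6.0, 30.0])
        out = moving_average(x, 3)
        np.testing.assert_allclose(out, [0.0, 3.0, 13.0, 30.0])

    def test_unbiased_on_linear_trend(self):
        x = np.linspace(2.0, 7.0, 11)
        np.testing.assert_allclose(moving_average(x, 5), x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(5.0), 2)


class TestExtractTrajectories:
    def test_paths_cover_all_leaves(self, noiseless_colony):
        _, table, _, tree = noiseless_colony
        expr = compute_expression(table)
        trajs = extract_trajectories(expr)
        assert sorted(t.leaf_id for t in trajs) == tree.leaves

    def test_founder_identified_on_each_path(self, noiseless_colony):
        _, table, truth, tree = noiseless_colony
        expr = compute_expression(table)
        trajs = extract_trajectories(expr)
        founder_map = truth.set_index("cell_id")["founder_id"]
        for tr in trajs:
            assert tr.founder_id == founder_map[tr.leaf_id]
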