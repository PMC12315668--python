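"""Cleaning, aggregation, harmonization, inclusion, and replay checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clpnet.cohort import OBSERVED_VARIABLES, PanelDataset, default_config, simulate_cohort
from clpnet.preprocess import (
    VariableSpec,
    aggregate_working_memory,
    build_node_table,
    complete_case_filter,
    harmonize_scales,
    invert_orientation,
    remove_outliers,
    replay_report,
    standardize_nodes,
)


def brute_force_outliers(values, threshold):
    """Independent oracle: explicit single-pass z-scoring."""
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    mean, sd = obs.mean(), obs.std(ddof=1)
    out = x.copy()
    removed = 0
    if sd > 0:
        for i, v in enumerate(x):
            if not np.isnan(v) and abs(v - mean) / sd >= threshold:
                out[i] = np.nan
                removed += 1
    return out, removed


class TestRemoveOutliers:
    def test_gross_outlier_removed_single_pass(self):
        # 39 tight inliers plus one gross point whose single-pass z
        # (moments computed with the outlier included) exceeds 4
        values = list(np.linspace(8.0, 12.0, 39)) + [60.0]
        expect, n_expect = brute_force_outliers(values, 4.0)
        assert n_expect == 1 and np.isnan(expect[-1])
        got, n, _ = remove_outliers(values, 4.0)
        np.testing.assert_array_equal(got, expect)
        assert n == 1

    def test_inliers_untouched(self):
        values = np.array([9.0, 10.0, 11.0, 10.5, 9.5])
        got, n, _ = remove_outliers(values, 4.0)
        np.testing.assert_array_equal(got, values)
        assert n == 0

    def test_constant_vector_is_identity_with_warning(self):
        with pytest.warns(UserWarning, match="zero SD"):
            got, n, _ = remove_outliers([3.0] * 10, 4.0)
        assert n == 0 and np.all(got == 3.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.one_of(st.floats(-50, 50), st.none()),
                    min_size=5, max_size=40),
           st.floats(1.5, 6.0))
    def test_matches_bruteforce_oracle(self, values, threshold):
        x = np.array([np.nan if v is None else v for v in values])
        if (~np.isnan(x)).sum() < 3:
            return
        expect, n_expect = brute_force_outliers(x, threshold)
        if np.nanstd(x) == 0:
            return
        got, n, _ = remove_outliers(x, threshold)
        np.testing.assert_array_equal(got, expect)
        assert n == n_expect


class TestInvertOrientation:
    SPEC = VariableSpec("go_rt", "cognitive", orientation="invert")

    def test_negation_preserves_missing(self):
        out = invert_orientation([500.0, 600.0, np.nan], self.SPEC)
        np.testing.assert_array_equal(out, [-500.0, -600.0, np.nan])

    def test_double_inversion_is_identity(self):
        x = np.array([1.0, -2.0, 3.5])
        np.testing.assert_array_equal(
            invert_orientation(invert_orientation(x, self.SPEC), self.SPEC), x)

    def test_inversion_flips_correlation_sign(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        y = x + rng.standard_normal(200)
        r0 = np.corrcoef(x, y)[0, 1]
        r1 = np.corrcoef(invert_orientation(x, self.SPEC), y)[0, 1]
        assert r1 == pytest.approx(-r0)

    def test_keep_orientation_rejected(self):
        with pytest.raises(ValueError):
            invert_orientation([1.0], VariableSpec("digit_backward", "cognitive"))


class TestAggregateWorkingMemory:
    def test_identical_indicators_yield_their_zscore(self):
        x = np.array([1.0, 3.0, 5.0, 9.0])
        agg, _ = aggregate_working_memory(x, x)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(agg, z)

    def test_opposite_zscores_cancel(self):
        agg, _ = aggregate_working_memory([2.0, 4.0, 6.0], [6.0, 4.0, 2.0])
        np.testing.assert_allclose(agg, [0.0, 0.0, 0.0], atol=1e-12)

    def test_variance_of_mean_algebra(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20000)
        # perfectly correlated indicators -> SD 1
        agg, _ = aggregate_working_memory(3 + 2 * x, 10 - 0 * x + 2 * x)
        assert np.std(agg, ddof=1) == pytest.approx(1.0, abs=1e-9)
        # independent indicators -> SD sqrt(1/2)
        agg2, _ = aggregate_working_memory(x, rng.standard_normal(20000))
        assert np.std(agg2, ddof=1) == pytest.approx(np.sqrt(0.5), abs=0.02)

    def test_missing_indicator_propagates(self):
        agg, _ = aggregate_working_memory([2.0, 4.0, 6.0, np.nan],
                                          [6.0, np.nan, 2.0, 4.0])
        assert np.isnan(agg[1]) and np.isnan(agg[3])
        assert not np.isnan(agg[0])

    def test_zero_sd_indicator_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            aggregate_working_memory([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestHarmonizeScales:
    def test_single_instrument_equals_plain_zscore(self):
        x = np.array([4.0, 8.0, 6.0, 10.0])
        out, _ = harmonize_scales(x, ["cbcl"] * 4)
        np.testing.assert_allclose(out, (x - x.mean()) / x.std(ddof=1))

    def test_subgroups_each_centered(self):
        scores = [8.0, 12.0, 10.0, 28.0, 30.0, 32.0]
        labels = ["cbcl"] * 3 + ["abcl"] * 3
        out, _ = harmonize_scales(scores, labels)
        out = np.asarray(out)
        assert out[:3].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[3:].mean() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_six_participant_table(self):
        # cbcl 1,2,3 (sd=1) and abcl 10,20,30 (sd=10): both map to -1,0,1
        out, params = harmonize_scales([1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
                                       ["cbcl"] * 3 + ["abcl"] * 3)
        np.testing.assert_allclose(out, [-1, 0, 1, -1, 0, 1])
        assert params["cbcl"] == (2.0, 1.0)
        assert params["abcl"] == (20.0, 10.0)

    def test_zero_sd_subgroup_rejected(self):
        with pytest.raises(ValueError, match="cbcl"):
            harmonize_scales([5.0, 5.0, 5.0, 1.0, 2.0, 3.0],
                             ["cbcl"] * 3 + ["abcl"] * 3)


def tiny_panel(missing_cells=()):
    rows = []
    for pid in range(10):
        for w in (1, 2, 3):
            row = {"participant_id": f"P{pid}", "wave": w, "group": "community",
                   "age": 10.0 + w, "gender": 0, "instrument": "cbcl"}
            for v in OBSERVED_VARIABLES:
                row[v] = float(pid + w)
            rows.append(row)
    df = pd.DataFrame(rows)
    for pid, w, var in missing_cells:
        df.loc[(df["participant_id"] == f"P{pid}") & (df["wave"] == w), var] = np.nan
    return PanelDataset(df)


class TestCompleteCaseFilter:
    def test_no_missing_is_identity(self):
        panel = tiny_panel()
        out = complete_case_filter(panel, list(OBSERVED_VARIABLES))
        pd.testing.assert_frame_equal(out.table, panel.table)

    def test_counting_example(self):
        panel = tiny_panel([(0, 1, "go_rt"), (3, 1, "digit_backward"),
                            (7, 1, "corsi_backward")])
        out = complete_case_filter(panel, list(OBSERVED_VARIABLES))
        assert out.n_participants == 7

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(4)
        cells = [(int(rng.integers(10)), int(rng.integers(1, 4)),
                  OBSERVED_VARIABLES[rng.integers(6)]) for _ in range(12)]
        panel = tiny_panel(cells)
        extra = {3: ["internalizing", "externalizing"]}
        out = complete_case_filter(panel, list(OBSERVED_VARIABLES), extra)
        # brute-force row scan
        keep = set()
        for pid in panel.table["participant_id"].unique():
            w1 = panel.table[(panel.table["participant_id"] == pid)
                             & (panel.table["wave"] == 1)]
            w3 = panel.table[(panel.table["participant_id"] == pid)
                             & (panel.table["wave"] == 3)]
            if (w1[list(OBSERVED_VARIABLES)].notna().all(axis=1).all()
                    and w3[["internalizing", "externalizing"]].notna().all(axis=1).all()):
                keep.add(pid)
        assert set(out.table["participant_id"].unique()) == keep

    def test_empty_result_raises(self):
        panel = tiny_panel([(p, 1, "go_rt") for p in range(10)])
        with pytest.raises(ValueError, match="every participant"):
            complete_case_filter(panel, list(OBSERVED_VARIABLES))


class TestStandardizeNodes:
    def frame(self):
        rng = np.random.default_rng(5)
        return pd.DataFrame({
            "wave": np.repeat([1, 2], 50),
            "a": np.concatenate([5 + 2 * rng.standard_normal(50),
                                 9 + 2 * rng.standard_normal(50)]),
        })

    def test_moments_after_standardization(self):
        out, _ = standardize_nodes(self.frame(), ["a"], per_wave=True)
        for w in (1, 2):
            sub = out.loc[out["wave"] == w, "a"]
            assert sub.mean() == pytest.approx(0.0, abs=1e-12)
            assert sub.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        once, _ = standardize_nodes(self.frame(), ["a"], per_wave=True)
        twice, _ = standardize_nodes(once, ["a"], per_wave=True)
        np.testing.assert_allclose(twice["a"], once["a"], atol=1e-12)

    def test_per_wave_differs_from_pooled_under_shifted_means(self):
        frame = self.frame()
        per_wave, _ = standardize_nodes(frame, ["a"], per_wave=True)
        pooled, _ = standardize_nodes(frame, ["a"], per_wave=False)
        assert not np.allclose(per_wave["a"], pooled["a"])

    def test_zero_sd_rejected(self):
        frame = pd.DataFrame({"wave": [1, 1, 1], "a": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            standardize_nodes(frame, ["a"], per_wave=True)


class TestNodeTable:
    def test_report_replay_is_bit_identical(self, small_cohort):
        table, report = build_node_table(small_cohort, (1, 2))
        again = replay_report(small_cohort, (1, 2), report)
        pd.testing.assert_frame_equal(table, again)

    def test_participant_order_insensitive(self, small_cohort):
        table, _ = build_node_table(small_cohort, (1, 2))
        shuffled = PanelDataset(
            small_cohort.table.sample(frac=1.0, random_state=9).reset_index(drop=True))
        table2, _ = build_node_table(shuffled, (1, 2))
        pd.testing.assert_frame_equal(table, table2)

    def test_orientation_contract_higher_is_better(self):
        """After preprocessing, every cognitive node correlates positively
        with its generating latent."""
        panel = simulate_cohort(default_config(2000, seed=31))
        table, _ = build_node_table(panel, (1, 2))
        merged = table[table["wave"] == 1].merge(
            panel.wave(1).reset_index(), on="participant_id")
        for node in ("working_memory", "inhibition_speed", "inhibition_accuracy"):
            r = np.corrcoef(merged[node], merged[f"latent_{node}"])[0, 1]
            assert r > 0.3, node

    def test_wave_pair_23_uses_harmonized_instruments(self):
        panel = simulate_cohort(default_config(1500, seed=32))
        table, report = build_node_table(panel, (2, 3))
        assert set(table["wave"]) == {2, 3}
        # separate CBCL/ABCL moments recorded for wave-3 symptoms
        assert any(k.startswith("internalizing@3:abcl")
                   for k in report.standardization_params)
        assert any(k.startswith("internalizing@3:cbcl")
                   for k in report.standardization_params)

    def test_report_counts(self, small_cohort):
        _, report = build_node_table(small_cohort, (1, 2))
        assert report.n_input == small_cohort.n_participants
        assert 0 < report.n_after_complete_case <= report.n_input
        assert all(v >= 0 for v in report.n_outlier_cells_removed.values())
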