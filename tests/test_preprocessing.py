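"""Hourly aggregation, filters, split and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import icubench as ib
from icubench.cohort import VARIABLES

from conftest import build_cohort


def records_frame(rows):
    return pd.DataFrame(rows, columns=["stay_id", "time_hours", "variable", "value"])


class TestAggregateHourly:
    def test_odd_count_median(self):
        c = ib.aggregate_hourly(
            records_frame([(1, 5.1, "HR", 80), (1, 5.5, "HR", 84), (1, 5.9, "HR", 90)])
        )
        assert c.values[0, 5, 0] == 84.0

    def test_even_count_median_is_mean_of_middle_two(self):
        c = ib.aggregate_hourly(records_frame([(1, 2.0, "HR", 70), (1, 2.4, "HR", 80)]))
        assert c.values[0, 2, 0] == 75.0

    def test_bins_are_half_open_and_window_bounded(self):
        c = ib.aggregate_hourly(
            records_frame([(1, 3.0, "RR", 10), (1, 3.999, "RR", 20), (1, 48.0, "RR", 99)])
        )
        assert c.values[0, 3, 2] == 15.0
        assert not (c.values == 99).any()  # at/beyond window discarded

    def test_negative_timestamp_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ib.aggregate_hourly(records_frame([(1, -0.5, "HR", 80)]))

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown variable"):
            ib.aggregate_hourly(records_frame([(1, 1.0, "Lactate", 2.0)]))

    @given(st.lists(st.floats(min_value=20, max_value=180), min_size=1, max_size=9))
    def test_median_matches_sort_oracle(self, values):
        rows = [(1, 7.0 + k / 10.0, "MBP", v) for k, v in enumerate(values)]
        c = ib.aggregate_hourly(records_frame(rows))
        srt = sorted(values)
        n = len(srt)
        oracle = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2.0
        assert c.values[0, 7, 3] == pytest.approx(oracle, rel=1e-12)


class TestPlausibilityFilters:
    @pytest.fixture
    def params(self):
        return ib.StandardizationParams(
            mean={v: 80.0 for v in VARIABLES}, sd={v: 10.0 for v in VARIABLES}
        )

    def test_spo2_above_100_removed(self, params):
        vals = np.full((1, 48, 4), 80.0)
        vals[0, 0, 1] = 101.0
        filtered, removed = ib.apply_plausibility_filters(build_cohort(vals), params)
        assert np.isnan(filtered.values[0, 0, 1])
        assert filtered.native_missing[0, 0, 1]
        assert removed["SpO2"] == 1

    def test_three_sd_boundary_is_retained(self, params):
        vals = np.full((1, 48, 4), 80.0)
        vals[0, 0, 0] = 110.0  # exactly mean + 3 SD
        vals[0, 1, 0] = 110.0001
        filtered, _ = ib.apply_plausibility_filters(build_cohort(vals), params)
        assert filtered.values[0, 0, 0] == 110.0
        assert np.isnan(filtered.values[0, 1, 0])

    def test_non_positive_values_removed(self, params):
        vals = np.full((1, 48, 4), 80.0)
        vals[0, 0, 3] = 0.0  # non-positive pressure
        filtered, _ = ib.apply_plausibility_filters(build_cohort(vals), params)
        assert np.isnan(filtered.values[0, 0, 3])

    def test_matches_brute_force_cell_scan(self, params, observed_small):
        filtered, _ = ib.apply_plausibility_filters(observed_small, params)
        for j, v in enumerate(VARIABLES):
            lo, hi = 80.0 - 30.0, 80.0 + 30.0
            floor, ceil = ib.preprocessing.DEFAULT_PLAUSIBILITY_BOUNDS[v]
            for i in range(observed_small.n_stays):
                for t in range(observed_small.n_hours):
                    x = observed_small.values[i, t, j]
                    if np.isnan(x):
                        assert np.isnan(filtered.values[i, t, j])
                    elif lo <= x <= hi and x > floor and x <= ceil:
                        assert filtered.values[i, t, j] == x  # retained, unaltered
                    else:
                        assert np.isnan(filtered.values[i, t, j])


class TestFilterStays:
    def make(self, missing_hours_per_stay):
        n = len(missing_hours_per_stay)
        vals = np.full((n, 48, 4), 80.0)
        for i, m in enumerate(missing_hours_per_stay):
            vals[i, :m, 0] = np.nan
        return build_cohort(vals)

    def test_threshold_is_strict(self):
        retained, log = ib.filter_stays(self.make([16, 17]), max_missing_hours=16)
        assert list(retained.stay_ids) == [0]
        assert log["missing_hours"].tolist() == [17]

    def test_sweep_matches_brute_force_rule(self):
        cohort = self.make(list(range(0, 49, 4)))
        retained, _ = ib.filter_stays(cohort, max_missing_hours=16)
        expected = [i for i, m in enumerate(range(0, 49, 4)) if m <= 16]
        assert list(retained.stay_ids) == expected

    def test_monotone_in_threshold(self):
        cohort = self.make([0, 5, 10, 20, 30, 48])
        prev: set = set()
        for thr in range(0, 49):
            kept = set(ib.filter_stays(cohort, thr)[0].stay_ids.tolist())
            assert prev <= kept
            prev = kept


class TestSplit:
    def test_exact_proportions(self, synthetic_small):
        ten = synthetic_small.subset(synthetic_small.stay_ids[:10])
        split = ib.split_cohort(ten, (0.6, 0.2, 0.2), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 2)

    def test_partition_and_determinism(self, synthetic_small):
        s1 = ib.split_cohort(synthetic_small, seed=4)
        s2 = ib.split_cohort(synthetic_small, seed=4)
        np.testing.assert_array_equal(s1.train, s2.train)
        np.testing.assert_array_equal(s1.test, s2.test)
        all_ids = np.concatenate([s1.train, s1.validation, s1.test])
        assert sorted(all_ids) == sorted(synthetic_small.stay_ids.tolist())

    def test_degenerate_all_on_one_set(self, synthetic_small):
        split = ib.split_cohort(synthetic_small, (1.0, 0.0, 0.0), seed=0)
        assert len(split.train) == synthetic_small.n_stays
        assert len(split.validation) == len(split.test) == 0

    def test_fewer_stays_than_groups(self, synthetic_small):
        two = synthetic_small.subset(synthetic_small.stay_ids[:2])
        with pytest.raises(ValueError, match="cannot split"):
            ib.split_cohort(two, (0.4, 0.3, 0.3), seed=0)


class TestStandardization:
    def test_two_point_mean_and_sample_sd(self):
        vals = np.full((1, 48, 4), 80.0)
        vals[0, :, :] = np.nan
        vals[0, 0, :] = 70.0
        vals[0, 1, :] = 90.0
        params = ib.fit_standardization(build_cohort(vals))
        assert params.mean["HR"] == 80.0
        assert params.sd["HR"] == pytest.approx(np.sqrt(200.0))  # (n-1) convention

    def test_zero_variance_raises(self):
        vals = np.full((1, 48, 4), 80.0)
        with pytest.raises(ValueError, match="zero variance"):
            ib.fit_standardization(build_cohort(vals))

    def test_matches_two_pass_oracle(self, observed_small):
        params = ib.fit_standardization(observed_small)
        for j, v in enumerate(VARIABLES):
            obs = observed_small.values[:, :, j]
            obs = obs[~np.isnan(obs)]
            mu = sum(obs) / len(obs)
            var = sum((x - mu) ** 2 for x in obs) / (len(obs) - 1)
            assert params.mean[v] == pytest.approx(mu, rel=1e-9)
            assert params.sd[v] == pytest.approx(np.sqrt(var), rel=1e-9)

    def test_round_trip_identity(self, observed_small):
        params = ib.fit_standardization(observed_small)
        z = ib.standardize(observed_small, params)
        back = ib.standardize(z, params, inverse=True)
        np.testing.assert_allclose(back.values, observed_small.values, rtol=1e-9)
        np.testing.assert_array_equal(np.isnan(z.values), np.isnan(observed_small.values))

    def test_value_at_mean_maps_to_zero(self):
        params = ib.StandardizationParams(
            mean={v: 80.0 for v in VARIABLES}, sd={v: 10.0 for v in VARIABLES}
        )
        vals = np.full((1, 48, 4), 80.0)
        z = ib.standardize(build_cohort(vals), params)
        assert np.all(z.values == 0.0)

    def test_elementwise_formula_oracle(self, observed_small):
        params = ib.fit_standardization(observed_small)
        z = ib.standardize(observed_small, params)
        for j, v in enumerate(VARIABLES):
            expected = (observed_small.values[:, :, j] - params.mean[v]) / params.sd[v]
            np.testing.assert_allclose(z.values[:, :, j], expected, rtol=1e-12)

    def test_train_params_invariant_to_test_contents(self, synthetic_small):
        split = ib.split_cohort(synthetic_small, seed=0)
        train = synthetic_small.subset(split.train)
        p1 = ib.fit_standardization(train)
        mutated = synthetic_small.copy()
        test_rows = [mutated.index_of(s) for s in split.test]
        mutated.values[test_rows] += 50.0
        p2 = ib.fit_standardization(mutated.subset(split.train))
        assert p1.mean == p2.mean and p1.sd == p2.sd
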