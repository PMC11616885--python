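"""Feature extraction: curation, window primitives, and the universal oracle."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from fohpred import features
from fohpred.features import (
    ChannelCurationRule,
    compatible_feature_set,
    compute_rpp,
    curate_measurements,
    extract_features,
    feature_columns,
    feature_registry,
    personal_ratio,
    weight_delta,
    window_statistics,
)
from fohpred.labels import transform_reports
from oracles import FeatureOracle, pratio_oracle


def _meas(rows):
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "channel", "value"])


class TestCuration:
    def test_bounds_from_plausibility_rules(self):
        df = _meas(
            [
                ("P0", pd.Timestamp("2021-03-01 10:00"), "hr", 39.0),   # sensor contact
                ("P0", pd.Timestamp("2021-03-01 10:01"), "hr", 40.0),   # at bound: kept
                ("P0", pd.Timestamp("2021-03-01 08:00"), "sbp", 200.0),  # at bound: kept
                ("P0", pd.Timestamp("2021-03-01 08:00"), "dbp", 39.0),  # entry error
                ("P0", pd.Timestamp("2021-03-01 08:01"), "dbp", 40.0),
            ]
        )
        curated, log = curate_measurements(df)
        assert len(curated) == 3
        assert set(zip(log["channel"], log["value"])) == {("hr", 39.0), ("dbp", 39.0)}

    def test_idempotent(self, heartman_cohort):
        _cfg, cohort, _ = heartman_cohort
        once, _ = curate_measurements(cohort.measurements)
        twice, log = curate_measurements(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log.empty

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            ChannelCurationRule("hr", lower=100.0, upper=50.0)


class TestWindowStatistics:
    def test_simple_mean(self):
        df = _meas(
            [("P0", pd.Timestamp("2021-03-01 19:00"), "hr", v) for v in (70.0, 80.0, 90.0)]
        )
        anchor = pd.Timestamp("2021-03-01 20:00")
        assert window_statistics(df, anchor, "3h", "mean") == 80.0

    def test_empty_window_and_single_sample_sd(self):
        df = _meas([("P0", pd.Timestamp("2021-03-01 10:00"), "hr", 70.0)])
        anchor = pd.Timestamp("2021-03-01 20:00")
        assert np.isnan(window_statistics(df, anchor, "3h", "mean"))
        assert np.isnan(window_statistics(df, anchor, "24h", "sd"))

    def test_unknown_window_rejected(self):
        df = _meas([("P0", pd.Timestamp("2021-03-01 10:00"), "hr", 70.0)])
        with pytest.raises(ValueError):
            window_statistics(df, pd.Timestamp("2021-03-01 20:00"), "5h", "mean")

    def test_random_samples_match_brute_force(self):
        rng = np.random.default_rng(0)
        ts = pd.Timestamp("2021-03-01") + pd.to_timedelta(
            rng.integers(0, 3 * 1440, size=200), unit="m"
        )
        vals = rng.normal(70, 10, size=200)
        df = _meas(list(zip(["P0"] * 200, ts, ["hr"] * 200, vals)))
        anchor = pd.Timestamp("2021-03-02 20:00")
        for window in ("3h", "24h", "day", "week"):
            if window == "day":
                d0 = anchor.normalize()
                mask = (ts >= d0) & (ts < d0 + pd.Timedelta(days=1))
            else:
                hours = {"3h": 3, "24h": 24, "week": 168}[window]
                mask = (ts > anchor - pd.Timedelta(hours=hours)) & (ts <= anchor)
            expect = vals[mask].mean() if mask.any() else np.nan
            got = window_statistics(df, anchor, window, "mean")
            assert got == pytest.approx(expect, rel=1e-12)


class TestRPP:
    def test_forced_by_definition(self):
        hr_t = [pd.Timestamp("2021-03-01 09:55"), pd.Timestamp("2021-03-01 10:05")]
        got = compute_rpp((pd.Timestamp("2021-03-01 10:00"), 120.0), hr_t, [78.0, 82.0])
        assert got == 9600.0

    def test_no_hr_in_window_is_missing(self):
        hr_t = [pd.Timestamp("2021-03-01 11:00")]
        assert np.isnan(compute_rpp((pd.Timestamp("2021-03-01 10:00"), 120.0), hr_t, [80.0]))

    def test_randomized_against_brute_force(self):
        rng = np.random.default_rng(1)
        hr_t = pd.Timestamp("2021-03-01") + pd.to_timedelta(
            rng.integers(0, 1440, size=100), unit="m"
        )
        hr_v = rng.normal(75, 8, size=100)
        t0 = pd.Timestamp("2021-03-01 12:07")
        inside = (hr_t >= t0 - pd.Timedelta(minutes=10)) & (hr_t <= t0 + pd.Timedelta(minutes=10))
        expect = 130.0 * hr_v[inside].mean()
        assert compute_rpp((t0, 130.0), hr_t, hr_v) == pytest.approx(expect, rel=1e-12)


class TestWeightDelta:
    D = date(2021, 3, 20)

    def test_plain_four_day_change(self):
        daily = {self.D: 80.0, self.D - pd.Timedelta(days=4).to_pytimedelta(): 79.0}
        assert weight_delta(daily, self.D, 4) == 1.0

    def test_four_day_fallback_to_seven(self):
        from datetime import timedelta

        daily = {self.D: 80.0, self.D - timedelta(days=6): 78.0}
        assert weight_delta(daily, self.D, 4) == 2.0

    def test_outside_fallback_horizon_missing(self):
        from datetime import timedelta

        daily = {self.D: 80.0, self.D - timedelta(days=8): 78.0}
        assert np.isnan(weight_delta(daily, self.D, 4))

    def test_one_day_fallback_within_three(self):
        from datetime import timedelta

        daily = {self.D: 81.0, self.D - timedelta(days=3): 80.0}
        assert weight_delta(daily, self.D, 1) == 1.0
        assert np.isnan(weight_delta({self.D: 81.0, self.D - timedelta(days=4): 80.0}, self.D, 1))


class TestPersonalRatio:
    def test_value_at_own_mean_is_one(self):
        out = personal_ratio([80.0, 90.0, 100.0], ["a", "a", "a"])
        assert out[1] == pytest.approx(1.0)

    def test_constant_column_sd_ratio_missing(self):
        out = personal_ratio([5.0, 5.0, 5.0], ["a", "a", "a"], aggregate="sd")
        assert np.isnan(out).all()

    def test_mean_of_mean_ratios_is_one_per_patient(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(50, 5, size=60)
        pids = np.repeat(["a", "b", "c"], 20)
        out = personal_ratio(vals, pids)
        for p in "abc":
            assert out[pids == p].mean() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def extracted(request):
    """Matrices plus oracles for both dialects, built once."""
    out = {}
    for dialect in ("heartman", "chiron"):
        cfg, cohort, _ = request.getfixturevalue(f"{dialect}_cohort")
        reports = transform_reports(cohort.reports)
        matrix = extract_features(cohort, reports, feature_registry(dialect))
        curated, _ = features.curate_measurements(cohort.measurements)
        out[dialect] = (cohort, reports, matrix, curated)
    return out


class TestExtraction:
    @pytest.mark.parametrize("dialect", ["heartman", "chiron"])
    def test_every_feature_matches_brute_force_oracle(self, extracted, dialect):
        """The universal oracle: each registered column, recomputed naively."""
        cohort, reports, matrix, curated = extracted[dialect]
        registry = feature_registry(dialect)
        base = [s for s in registry if s.kind != "pratio"]
        pratio = [s for s in registry if s.kind == "pratio"]
        oracles = {
            pid: FeatureOracle(curated[curated["patient_id"] == pid], dialect)
            for pid in matrix["patient_id"].unique()
        }
        for _, row in matrix.iterrows():
            oracle = oracles[row["patient_id"]]
            for spec in base:
                expect = oracle.compute(spec, row["date"])
                got = row[spec.name]
                if np.isnan(expect):
                    assert np.isnan(got), (spec.name, row["patient_id"], row["date"])
                else:
                    assert got == pytest.approx(expect, rel=1e-9), (
                        spec.name, row["patient_id"], row["date"],
                    )
        for spec in pratio:
            expect = pratio_oracle(matrix, spec.extra, spec.stat)
            pd.testing.assert_series_equal(
                matrix[spec.name], expect, check_names=False, rtol=1e-9
            )

    @pytest.mark.parametrize("dialect", ["heartman", "chiron"])
    def test_one_row_per_report_and_registry_columns(self, extracted, dialect):
        _cohort, reports, matrix, _curated = extracted[dialect]
        assert len(matrix) == len(reports)
        assert set(feature_columns(matrix)) == {s.name for s in feature_registry(dialect)}

    def test_activity_fractions_partition_the_day(self, extracted):
        _cohort, _reports, matrix, _curated = extracted["heartman"]
        cols = [f"activity.{c}.day.fraction" for c in
                ("walking", "running", "other_movement", "standing", "rest")]
        sums = matrix[cols].sum(axis=1)
        observed = matrix[cols].notna().all(axis=1)
        assert np.allclose(sums[observed], 1.0)

    def test_no_future_leakage(self, heartman_cohort):
        # erasing everything after each report's calendar day changes nothing
        _cfg, cohort, _ = heartman_cohort
        reports = transform_reports(cohort.reports).iloc[:10]
        registry = feature_registry("heartman")
        full = extract_features(cohort, reports, registry)
        for _, r in reports.iterrows():
            cutoff = pd.Timestamp(r["date"]) + pd.Timedelta(days=1)
            meas = cohort.measurements
            trimmed = cohort.measurements[
                (meas["patient_id"] != r["patient_id"]) | (meas["timestamp"] < cutoff)
            ]
            from fohpred.synthetic import Cohort

            got = extract_features(
                Cohort(trimmed.reset_index(drop=True), cohort.reports, "heartman"),
                reports[(reports["patient_id"] == r["patient_id"]) & (reports["date"] == r["date"])],
                [s for s in registry if s.kind != "pratio"],
            )
            row_full = full[(full["patient_id"] == r["patient_id"]) & (full["date"] == r["date"])]
            row_trim = got[got["date"] == r["date"]]
            for s in registry:
                if s.kind == "pratio":
                    continue
                a, b = row_full[s.name].iloc[0], row_trim[s.name].iloc[0]
                assert (np.isnan(a) and np.isnan(b)) or a == b, s.name


class TestCompatibility:
    def test_cross_dialect_intersection_is_the_both_flagged_set(self, extracted):
        _c, _r, hm, _ = extracted["heartman"]
        _c2, _r2, ch, _2 = extracted["chiron"]
        common = compatible_feature_set(hm, ch)
        flagged = sorted({s.name for s in feature_registry("heartman") if s.dialect == "both"})
        assert common == flagged

    def test_identical_schemas_full_list(self, extracted):
        _c, _r, hm, _ = extracted["heartman"]
        assert compatible_feature_set(hm, hm) == sorted(feature_columns(hm))

    def test_disjoint_schemas_rejected(self):
        a = pd.DataFrame({"patient_id": [1], "date": [date(2021, 3, 1)], "x": [1.0]})
        b = pd.DataFrame({"patient_id": [1], "date": [date(2021, 3, 1)], "y": [1.0]})
        with pytest.raises(ValueError):
            compatible_feature_set(a, b)
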