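"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity from first principles with plain
pandas masks and python loops, sharing no code with the package's optimized
paths, so that agreement between the two is informative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fohpred.features import FeatureSpec
from fohpred.synthetic import ACTIVE_CLASSES, ACTIVITY_CLASSES, FOH_ENTRY_MINUTE

# ---------------------------------------------------------------------------
# label transformation oracle: two explicit rule passes instead of a scanner


def transform_run_oracle(y: list[str]) -> list[str]:
    """Rule-by-rule transformation of one run of consecutive-day labels."""
    n = len(y)
    # pass 1: immediate reversals become 'same as usual' and do not propagate
    reversal = [False] * n
    for i in range(1, n):
        if {y[i - 1], y[i]} == {"worse", "better"}:
            reversal[i] = True
    out = ["same" if reversal[i] else y[i] for i in range(n)]
    # pass 2: each non-reversal extreme propagates over following 'same' days,
    # at most 5 days counting the trigger day itself
    for i in range(n):
        if y[i] in ("worse", "better") and not reversal[i]:
            for j in range(i + 1, min(i + 4, n - 1) + 1):
                if y[j] == "same":
                    out[j] = y[i]
                else:
                    break
    return out


def transform_oracle(dates, y: list[str]) -> list[str]:
    """Gap-aware oracle: split into consecutive-day runs, transform each."""
    out: list[str] = []
    run: list[str] = []
    for i in range(len(dates)):
        if i and (dates[i] - dates[i - 1]).days == 1:
            run.append(y[i])
        else:
            out += transform_run_oracle(run)
            run = [y[i]]
    out += transform_run_oracle(run)
    return out


# ---------------------------------------------------------------------------
# metric oracles


def f1_oracle(y_true, y_pred, classes) -> tuple[dict, float]:
    """Per-class F1 and macro F1 from explicitly counted contingencies."""
    y_true, y_pred = list(y_true), list(y_pred)
    per = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        pred_c = sum(1 for p in y_pred if p == c)
        true_c = sum(1 for t in y_true if t == c)
        prec = tp / pred_c if pred_c else 0.0
        rec = tp / true_c if true_c else 0.0
        per[c] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return per, sum(per.values()) / len(classes)


# ---------------------------------------------------------------------------
# feature oracle: naive recomputation of every registry kind


def _entry_ts(d) -> pd.Timestamp:
    return pd.Timestamp(d) + pd.Timedelta(minutes=FOH_ENTRY_MINUTE)


class FeatureOracle:
    """Brute-force per-feature recomputation for one patient's stream."""

    def __init__(self, measurements: pd.DataFrame, dialect: str):
        self.dialect = dialect
        self.meas = measurements.copy()
        self.meas["timestamp"] = pd.to_datetime(self.meas["timestamp"])
        self._channels: dict[str, pd.DataFrame] = {}
        self._act: dict | None = None

    def channel(self, ch: str) -> pd.DataFrame:
        if ch not in self._channels:
            self._channels[ch] = self.meas[self.meas["channel"] == ch]
        return self._channels[ch]

    def activity_lookup(self) -> dict:
        if self._act is None:
            adf = self.channel("activity_class")
            self._act = dict(zip(adf["timestamp"], adf["value"]))
        return self._act

    def in_window(self, ch: str, entry: pd.Timestamp, window: str) -> pd.Series:
        df = self.channel(ch)
        t = df["timestamp"]
        if window == "day":
            d0 = entry.normalize()
            mask = (t >= d0) & (t < d0 + pd.Timedelta(days=1))
        else:
            hours = {"3h": 3, "24h": 24, "week": 168}[window]
            mask = (t > entry - pd.Timedelta(hours=hours)) & (t <= entry)
        return df.loc[mask, "value"]

    def day_vals(self, ch: str, day: pd.Timestamp) -> pd.Series:
        return self.in_window(ch, day + pd.Timedelta(minutes=FOH_ENTRY_MINUTE), "day")

    def day_mean(self, ch: str, day: pd.Timestamp) -> float:
        v = self.day_vals(ch, day)
        return float(v.mean()) if len(v) else np.nan

    @staticmethod
    def stat(v, stat: str) -> float:
        v = pd.Series(list(v), dtype=float)
        if stat in ("mean", "value"):
            return float(v.mean()) if len(v) else np.nan
        if stat == "sd":
            return float(v.std(ddof=1)) if len(v) >= 2 else np.nan
        if stat == "count":
            return float(len(v))
        if stat == "sum":
            return float(v.sum()) if len(v) else 0.0
        raise ValueError(stat)

    def prev_day(self, fn, day: pd.Timestamp, max_back: int = 3) -> float:
        for back in range(1, max_back + 1):
            v = fn(day - pd.Timedelta(days=back))
            if not np.isnan(v):
                return v
        return np.nan

    def matched(self, ch: str, entry: pd.Timestamp, window: str):
        """(value, activity-class) pairs joined on identical timestamps."""
        df = self.channel(ch)
        act = self.activity_lookup()
        t = df["timestamp"]
        if window == "day":
            d0 = entry.normalize()
            mask = (t >= d0) & (t < d0 + pd.Timedelta(days=1))
        else:
            hours = {"3h": 3, "24h": 24, "week": 168}[window]
            mask = (t > entry - pd.Timedelta(hours=hours)) & (t <= entry)
        rows = df.loc[mask]
        pairs = [
            (v, int(act[ts]))
            for ts, v in zip(rows["timestamp"], rows["value"])
            if ts in act
        ]
        if not pairs:
            return np.empty(0), np.empty(0, dtype=int)
        vals, acts = zip(*pairs)
        return np.array(vals), np.array(acts)

    def rpp_day(self, day: pd.Timestamp) -> float:
        sbp = self.day_vals("sbp", day)
        sdf = self.channel("sbp")
        hr = self.channel("hr")
        vals = []
        d0 = day.normalize()
        events = sdf[(sdf["timestamp"] >= d0) & (sdf["timestamp"] < d0 + pd.Timedelta(days=1))]
        for _, row in events.iterrows():
            lo = row["timestamp"] - pd.Timedelta(minutes=10)
            hi = row["timestamp"] + pd.Timedelta(minutes=10)
            win = hr[(hr["timestamp"] >= lo) & (hr["timestamp"] <= hi)]["value"]
            if len(win):
                vals.append(row["value"] * win.mean())
        return float(np.mean(vals)) if vals else np.nan

    # -- dispatch ----------------------------------------------------------

    def compute(self, spec: FeatureSpec, report_date) -> float:
        entry = _entry_ts(report_date)
        day0 = entry.normalize()
        codes = {c: i for i, c in enumerate(ACTIVITY_CLASSES[self.dialect])}
        kind = spec.kind

        if kind == "window_stat":
            ch = spec.channels[0]
            if spec.window == "diff":
                today = self.day_mean(ch, day0)
                prev = self.prev_day(lambda d: self.day_mean(ch, d), day0)
                return today - prev if not (np.isnan(today) or np.isnan(prev)) else np.nan
            return self.stat(self.in_window(ch, entry, spec.window), spec.stat)

        if kind == "daily_value":
            return self.day_mean(spec.channels[0], day0)

        if kind == "delta":
            ch = spec.channels[0]
            today = self.day_mean(ch, day0)
            if np.isnan(today):
                return np.nan
            backs = [1, 2, 3] if spec.window == "d1" else [4, 5, 6, 7]
            for b in backs:
                ref = self.day_mean(ch, day0 - pd.Timedelta(days=b))
                if not np.isnan(ref):
                    return today - ref
            return np.nan

        if kind == "ratio2":
            a, b = spec.channels

            def ratio(d=None, window=None):
                if d is not None:
                    num, den = self.day_mean(a, d), self.day_mean(b, d)
                else:
                    va, vb = self.in_window(a, entry, window), self.in_window(b, entry, window)
                    num = float(va.mean()) if len(va) else np.nan
                    den = float(vb.mean()) if len(vb) else np.nan
                return num / den if not (np.isnan(num) or np.isnan(den) or den == 0) else np.nan

            if spec.window == "diff":
                today = ratio(d=day0)
                prev = self.prev_day(lambda d: ratio(d=d), day0)
                return today - prev if not (np.isnan(today) or np.isnan(prev)) else np.nan
            return ratio(window=spec.window)

        if kind == "rpp":
            if spec.window == "day":
                return self.rpp_day(day0)
            if spec.window == "diff":
                today = self.rpp_day(day0)
                prev = self.prev_day(self.rpp_day, day0)
                return today - prev if not (np.isnan(today) or np.isnan(prev)) else np.nan
            # interval window: events are SBP entries inside (entry-24h, entry]
            sdf = self.channel("sbp")
            hr = self.channel("hr")
            lo = entry - pd.Timedelta(hours=24)
            events = sdf[(sdf["timestamp"] > lo) & (sdf["timestamp"] <= entry)]
            vals = []
            for _, row in events.iterrows():
                wlo = row["timestamp"] - pd.Timedelta(minutes=10)
                whi = row["timestamp"] + pd.Timedelta(minutes=10)
                win = hr[(hr["timestamp"] >= wlo) & (hr["timestamp"] <= whi)]["value"]
                if len(win):
                    vals.append(row["value"] * win.mean())
            return float(np.mean(vals)) if vals else np.nan

        if kind == "act_fraction":
            code = codes[spec.extra]

            def frac(d=None, window=None):
                if d is not None:
                    v = self.day_vals("activity_class", d)
                else:
                    v = self.in_window("activity_class", entry, window)
                return float((v == code).mean()) if len(v) else np.nan

            if spec.window == "diff":
                today = frac(d=day0)
                prev = self.prev_day(lambda d: frac(d=d), day0)
                return today - prev if not (np.isnan(today) or np.isnan(prev)) else np.nan
            return frac(window=spec.window)

        if kind == "hr_static_dynamic":
            static = [codes[c] for c in ACTIVITY_CLASSES[self.dialect]
                      if c not in ACTIVE_CLASSES[self.dialect]]
            dyn = [codes[c] for c in ACTIVE_CLASSES[self.dialect]]

            def ratio(d=None, window=None):
                if d is not None:
                    v, a = self.matched("hr", _entry_ts(d.date()), "day")
                else:
                    v, a = self.matched("hr", entry, window)
                vs, vd = v[np.isin(a, static)], v[np.isin(a, dyn)]
                if len(vs) == 0 or len(vd) == 0 or vd.mean() == 0:
                    return np.nan
                return float(vs.mean() / vd.mean())

            if spec.window == "diff":
                today = ratio(d=day0)
                prev = self.prev_day(lambda d: ratio(d=d), day0)
                return today - prev if not (np.isnan(today) or np.isnan(prev)) else np.nan
            return ratio(window=spec.window)

        if kind == "per_activity_stat":
            v, a = self.matched(spec.channels[0], entry, "day")
            return self.stat(v[a == codes[spec.extra]], spec.stat)

        if kind in ("hr_act_diff", "hr_act_ratio"):
            ca, cb = spec.extra.split("|")
            v, a = self.matched("hr", entry, "day")
            va, vb = v[a == codes[ca]], v[a == codes[cb]]
            if len(va) == 0 or len(vb) == 0:
                return np.nan
            if kind == "hr_act_diff":
                return float(va.mean() - vb.mean())
            return float(va.mean() / vb.mean()) if vb.mean() != 0 else np.nan

        if kind == "act_pair_ratio":
            ca, cb = spec.extra.split("|")
            v = self.day_vals("activity_class", day0)
            if len(v) == 0:
                return np.nan
            fa, fb = float((v == codes[ca]).mean()), float((v == codes[cb]).mean())
            return fa / fb if fb != 0 else np.nan

        if kind == "paired_ratio_mean":
            a, b = spec.channels
            da = self.channel(a)
            db = self.channel(b).set_index("timestamp")["value"]
            d0 = day0
            t = da["timestamp"]
            rows = da[(t >= d0) & (t < d0 + pd.Timedelta(days=1))]
            ratios = []
            for _, row in rows.iterrows():
                if row["timestamp"] in db.index and db.loc[row["timestamp"]] != 0:
                    ratios.append(row["value"] / db.loc[row["timestamp"]])
            return float(np.mean(ratios)) if ratios else np.nan

        if kind == "double_product":
            sbp, dbp = self.day_mean("sbp", day0), self.day_mean("dbp", day0)
            hr = self.day_mean("hr", day0)
            if any(np.isnan(x) for x in (sbp, dbp, hr)):
                return np.nan
            return (sbp + dbp) / 2 * hr

        if kind == "ratio_daily":
            a, b = spec.channels
            va, vb = self.day_mean(a, day0), self.day_mean(b, day0)
            return va / vb if not (np.isnan(va) or np.isnan(vb) or vb == 0) else np.nan

        if kind == "ex_count":
            return float(len(self.in_window(spec.channels[0], entry, spec.window)))
        if kind == "ex_sum":
            v = self.in_window(spec.channels[0], entry, spec.window)
            return float(v.sum()) if len(v) else 0.0

        raise ValueError(f"oracle has no rule for kind {kind!r}")


def verify_registry(dialect: str, seed: int, n_patients: int = 5, n_days: int = 30):
    """Check every registered feature against the brute-force oracle.

    Returns ``(n_checked, n_mismatch, max_rel_err)`` over a randomized
    cohort of the given size; NaN agreement counts as a match.
    """
    from fohpred.features import (
        curate_measurements,
        extract_features,
        feature_registry,
    )
    from fohpred.labels import transform_reports
    from fohpred.synthetic import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(n_patients=n_patients, n_days=n_days, dialect=dialect, seed=seed)
    cohort, _ = generate_cohort(cfg)
    reports = transform_reports(cohort.reports)
    registry = feature_registry(dialect)
    matrix = extract_features(cohort, reports, registry)
    curated, _ = curate_measurements(cohort.measurements)
    base = [s for s in registry if s.kind != "pratio"]
    pratio = [s for s in registry if s.kind == "pratio"]
    oracles = {
        pid: FeatureOracle(curated[curated["patient_id"] == pid], dialect)
        for pid in matrix["patient_id"].unique()
    }
    n_checked = n_mismatch = 0
    max_rel = 0.0

    def check(expect, got):
        nonlocal n_checked, n_mismatch, max_rel
        n_checked += 1
        if np.isnan(expect) or np.isnan(got):
            if np.isnan(expect) != np.isnan(got):
                n_mismatch += 1
            return
        rel = abs(got - expect) / max(1.0, abs(expect))
        max_rel = max(max_rel, rel)
        if rel > 1e-9:
            n_mismatch += 1

    for _, row in matrix.iterrows():
        oracle = oracles[row["patient_id"]]
        for spec in base:
            check(oracle.compute(spec, row["date"]), row[spec.name])
    for spec in pratio:
        expect = pratio_oracle(matrix, spec.extra, spec.stat)
        for e, g in zip(expect, matrix[spec.name]):
            check(e, g)
    return n_checked, n_mismatch, max_rel


def pratio_oracle(matrix: pd.DataFrame, base: str, stat: str) -> pd.Series:
    """Personal ratio recomputed per patient with plain groupby.

    Mirrors the contract: a denominator indistinguishable from zero at the
    column's scale (<= 1e-9 of the mean absolute value) gives a missing
    ratio.
    """
    def per_patient(grp: pd.Series) -> pd.Series:
        denom = grp.std(ddof=1) if stat == "sd" else grp.mean()
        if denom is None or np.isnan(denom) or abs(denom) <= 1e-9 * grp.abs().mean():
            return pd.Series(np.nan, index=grp.index)
        return grp / denom

    return matrix.groupby("patient_id")[base].transform(per_patient)
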