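"""Per-day feature extraction from telemonitoring streams, for both dialects.

One feature-matrix row is produced per FOH report.  Every emitted column is
described by exactly one :class:`FeatureSpec` in the dialect's registry, and
feature names are namespaced ``<group>.<channel>.<window>.<stat>[.pratio]``
so that the cross-dialect compatible feature set is computable by name:
specs flagged ``both`` appear, with an identical definition, in the Chiron
and HeartMan registries.

Window semantics (the FOH entry is anchored at a fixed evening time of its
calendar date):

* ``3h`` / ``24h`` / ``week`` — the interval of that length ending at the
  FOH entry timestamp (right-closed);
* ``day`` — the full calendar date of the entry;
* ``diff`` — the day-window value minus the value of the most recent prior
  day with data, looking back at most 3 days;
* ``d1`` / ``d4`` — for one-per-day manual entries, today's value minus a
  reference entry: the most recent within the last 3 days (``d1``), or the
  entry 4 days back, falling back to the most recent 5-7 days back (``d4``).

No feature for day *d* uses any measurement after that day ends.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from fohpred.synthetic import ACTIVE_CLASSES, ACTIVITY_CLASSES, FOH_ENTRY_MINUTE, Cohort

MISSING = np.nan

# ---------------------------------------------------------------------------
# curation


@dataclass(frozen=True)
class ChannelCurationRule:
    """Remove physiologically implausible values from one channel."""

    channel: str
    lower: float | None = None  # inclusive bound: values below are removed
    upper: float | None = None  # inclusive bound: values above are removed

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


#: Default plausibility bounds: HR below 40 bpm is poor sensor contact,
#: SBP above 200 mmHg and DBP below 40 mmHg are treated as entry errors.
DEFAULT_CURATION: tuple[ChannelCurationRule, ...] = (
    ChannelCurationRule("hr", lower=40.0),
    ChannelCurationRule("sbp", upper=200.0),
    ChannelCurationRule("dbp", lower=40.0),
)


def curate_measurements(
    measurements: pd.DataFrame,
    rules: Sequence[ChannelCurationRule] = DEFAULT_CURATION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop out-of-bound values; returns (curated, rejection log).

    Bounds are inclusive: a value exactly at a limit is kept.  Idempotent.
    """
    bad = np.zeros(len(measurements), dtype=bool)
    reasons = np.full(len(measurements), "", dtype=object)
    for rule in rules:
        on = (measurements["channel"] == rule.channel).to_numpy()
        vals = measurements["value"].to_numpy()
        if rule.lower is not None:
            hit = on & (vals < rule.lower)
            reasons[hit] = f"below {rule.lower}"
            bad |= hit
        if rule.upper is not None:
            hit = on & (vals > rule.upper)
            reasons[hit] = f"above {rule.upper}"
            bad |= hit
    log = measurements.loc[bad].copy()
    log["reason"] = reasons[bad]
    return measurements.loc[~bad].reset_index(drop=True), log.reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature registry


@dataclass(frozen=True)
class FeatureSpec:
    """Definition of one emitted feature column."""

    name: str
    group: str  # discrete | continuous | activity | exercise | environmental | daily | derived
    kind: str  # computation rule, dispatched on in the engine
    channels: tuple[str, ...]
    window: str  # 3h | 24h | day | week | diff | d1 | d4
    stat: str  # mean | sd | value | fraction | count | sum
    dialect: str  # chiron | heartman | both
    extra: str = ""  # activity class / pair, or pratio source column


def _named(group: str, channel: str, window: str, stat: str) -> str:
    return f"{group}.{channel}.{window}.{stat}"


def _window_specs(
    group: str, kind: str, channels: tuple[str, ...], label: str, windows: Iterable[str],
    stats: Iterable[str], dialect: str, extra: str = ""
) -> list[FeatureSpec]:
    out = []
    for w in windows:
        for s in stats:
            if w in ("diff", "d1", "d4") and s == "sd":
                continue  # differences are single values
            out.append(
                FeatureSpec(_named(group, label, w, s), group, kind, channels, w, s, dialect, extra)
            )
    return out


def _add_pratios(
    specs: list[FeatureSpec], names: set[str], own_dialect: str
) -> list[FeatureSpec]:
    """Personal-ratio companion specs for the given base feature names.

    A pratio column is cross-dialect ('both') only when both registries
    personalize that base feature; otherwise it belongs to this registry's
    dialect even if the base column is shared.
    """
    shared_pr = _shared_pratio_names()
    out = []
    for s in specs:
        if s.name in names:
            pr_name = s.name + ".pratio"
            out.append(
                FeatureSpec(
                    pr_name,
                    s.group,
                    "pratio",
                    s.channels,
                    s.window,
                    s.stat,
                    "both" if pr_name in shared_pr else own_dialect,
                    extra=s.name,
                )
            )
    return out


def heartman_registry() -> list[FeatureSpec]:
    """Feature enumeration for the HeartMan dialect (wristband + app + ambient)."""
    specs: list[FeatureSpec] = []
    # continuous physiology: mean and SD over short/long windows + day diff
    for ch in ("hr", "skin_temp", "gsr", "energy_expenditure"):
        specs += _window_specs("cont", "window_stat", (ch,), ch,
                               ("3h", "24h", "day", "diff"), ("mean", "sd"), "heartman")
    # ratios pairing a body signal with its ambient counterpart
    specs += _window_specs("derived", "ratio2", ("skin_temp", "air_temp"), "temp_ratio",
                           ("3h", "24h", "day", "diff"), ("mean",), "heartman")
    specs += _window_specs("derived", "ratio2", ("gsr", "air_humidity"), "gsr_humidity_ratio",
                           ("3h", "24h", "day", "diff"), ("mean",), "heartman")
    # cardiac workload: SBP x HR around the measurement (no 3h variant: one BP entry/day)
    specs += _window_specs("derived", "rpp", ("sbp", "hr"), "rpp", ("24h", "day", "diff"), ("mean",), "heartman")
    # manual entries: today's value and short/clinical-horizon changes
    for ch in ("weight", "sbp", "dbp"):
        specs.append(FeatureSpec(_named("daily", ch, "day", "value"), "daily", "daily_value", (ch,), "day", "value", "both"))
        specs.append(FeatureSpec(_named("discrete", ch, "d1", "delta"), "discrete", "delta", (ch,), "d1", "value", "heartman"))
        specs.append(FeatureSpec(_named("discrete", ch, "d4", "delta"), "discrete", "delta", (ch,), "d4", "value", "heartman"))
    # activity time budget
    for cls in ACTIVITY_CLASSES["heartman"]:
        specs += _window_specs("activity", "act_fraction", ("activity_class",), cls,
                               ("day", "24h", "week", "diff"), ("fraction",), "heartman", extra=cls)
    specs += _window_specs("activity", "hr_static_dynamic", ("hr", "activity_class"), "hr_static_dynamic",
                           ("day", "24h", "week", "diff"), ("mean",), "heartman")
    # guided exercises
    for w in ("day", "week"):
        specs.append(FeatureSpec(_named("exercise", "count", w, "count"), "exercise", "ex_count", ("exercise_duration",), w, "count", "heartman"))
        specs.append(FeatureSpec(_named("exercise", "duration", w, "sum"), "exercise", "ex_sum", ("exercise_duration",), w, "sum", "heartman"))
    specs.append(FeatureSpec(_named("exercise", "type", "day", "mean"), "exercise", "window_stat", ("exercise_type",), "day", "mean", "heartman"))
    specs.append(FeatureSpec(_named("exercise", "validity", "day", "mean"), "exercise", "window_stat", ("exercise_validity",), "day", "mean", "heartman"))
    # ambient conditions
    for ch in ("air_humidity", "air_temp", "air_pressure"):
        specs += _window_specs("env", "window_stat", (ch,), ch, ("day", "3h"), ("mean", "sd"), "heartman")

    # fix dialect flags for the shared (cross-dialect) definitions
    shared = _shared_names()
    specs = [replace(s, dialect="both") if s.name in shared else s for s in specs]

    pr_names = {s.name for s in specs if s.group != "exercise"}
    specs += _add_pratios(specs, pr_names, "heartman")
    return specs


def chiron_registry() -> list[FeatureSpec]:
    """Feature enumeration for the Chiron dialect (chest strap + app), day-level."""
    specs: list[FeatureSpec] = []
    # one-per-day manual / ambient values
    for ch in ("air_temp", "air_humidity", "sbp", "dbp", "spo2", "weight"):
        specs.append(FeatureSpec(_named("daily", ch, "day", "value"), "daily", "daily_value", (ch,), "day", "value", "chiron"))
    # multi-per-day channels: whole-day and per-activity statistics
    multi = ("body_humidity", "skin_temp", "pr_interval", "qrs_duration",
             "qt_interval", "t_wave_amp", "r_wave_amp", "hr", "energy_expenditure")
    for ch in multi:
        for s in ("mean", "sd"):
            specs.append(FeatureSpec(_named("cont", ch, "day", s), "cont", "window_stat", (ch,), "day", s, "chiron"))
            for cls in ACTIVITY_CLASSES["chiron"]:
                specs.append(
                    FeatureSpec(f"cont.{ch}.day.{s}.{cls}", "cont", "per_activity_stat",
                                (ch, "activity_class"), "day", s, "chiron", extra=cls)
                )
    # derived daily values
    specs.append(FeatureSpec("derived.temp_ratio.day.mean", "derived", "ratio2", ("skin_temp", "air_temp"), "day", "mean", "chiron"))
    specs.append(FeatureSpec("derived.humidity_ratio.day.mean", "derived", "ratio2", ("body_humidity", "air_humidity"), "day", "mean", "chiron"))
    specs.append(FeatureSpec("derived.rpp.day.mean", "derived", "rpp", ("sbp", "hr"), "day", "mean", "chiron"))
    specs.append(FeatureSpec("derived.double_product.day.value", "derived", "double_product", ("sbp", "dbp", "hr"), "day", "value", "chiron"))
    specs.append(FeatureSpec("derived.bp_ratio.day.value", "derived", "ratio_daily", ("sbp", "dbp"), "day", "value", "chiron"))
    cls3 = ACTIVITY_CLASSES["chiron"]
    pairs = [(a, b) for i, a in enumerate(cls3) for b in cls3[i + 1:]]
    for a, b in pairs:
        specs.append(FeatureSpec(f"derived.actdur_ratio_{a}_{b}.day.value", "derived", "act_pair_ratio",
                                 ("activity_class",), "day", "value", "chiron", extra=f"{a}|{b}"))
        specs.append(FeatureSpec(f"derived.hr_diff_{a}_{b}.day.value", "derived", "hr_act_diff",
                                 ("hr", "activity_class"), "day", "value", "chiron", extra=f"{a}|{b}"))
        specs.append(FeatureSpec(f"derived.hr_ratio_{a}_{b}.day.value", "derived", "hr_act_ratio",
                                 ("hr", "activity_class"), "day", "value", "chiron", extra=f"{a}|{b}"))
    specs.append(FeatureSpec("derived.hr_ee_ratio.day.mean", "derived", "paired_ratio_mean", ("hr", "energy_expenditure"), "day", "mean", "chiron"))

    shared = _shared_names()
    specs = [replace(s, dialect="both") if s.name in shared else s for s in specs]

    # only an explicit list of parameters is personalized in this dialect
    personalized = {
        "derived.humidity_ratio.day.mean",
        "derived.temp_ratio.day.mean",
        "cont.t_wave_amp.day.mean",
        "cont.r_wave_amp.day.mean",
        "cont.skin_temp.day.mean",
        "cont.body_humidity.day.mean",
        "cont.qrs_duration.day.mean",
        "cont.qt_interval.day.mean",
        "derived.hr_ee_ratio.day.mean",
    }
    specs += _add_pratios(specs, personalized, "chiron")
    return specs


def _shared_names() -> set[str]:
    """Base feature names defined identically in both dialects."""
    return {
        "cont.hr.day.mean", "cont.hr.day.sd",
        "cont.skin_temp.day.mean", "cont.skin_temp.day.sd",
        "cont.energy_expenditure.day.mean", "cont.energy_expenditure.day.sd",
        "derived.temp_ratio.day.mean",
        "derived.rpp.day.mean",
        "daily.weight.day.value", "daily.sbp.day.value", "daily.dbp.day.value",
    }


def _shared_pratio_names() -> set[str]:
    """Personal-ratio columns present in both dialects."""
    return {"cont.skin_temp.day.mean.pratio", "derived.temp_ratio.day.mean.pratio"}


def feature_registry(dialect: str) -> list[FeatureSpec]:
    if dialect == "heartman":
        return heartman_registry()
    if dialect == "chiron":
        return chiron_registry()
    raise ValueError(f"unknown dialect {dialect!r}")


def registry_table(dialect: str) -> pd.DataFrame:
    """The registry as a flat table (written next to extracted matrices)."""
    return pd.DataFrame(
        [
            {
                "name": s.name, "group": s.group, "kind": s.kind,
                "channels": "+".join(s.channels), "window": s.window,
                "stat": s.stat, "dialect": s.dialect, "extra": s.extra,
            }
            for s in feature_registry(dialect)
        ]
    )


# ---------------------------------------------------------------------------
# window primitives

WINDOW_HOURS = {"3h": 3, "24h": 24, "week": 168}


def _window_bounds(entry: pd.Timestamp, window: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    """(start, end] for interval windows; [start, end) for the day window."""
    if window == "day":
        d0 = entry.normalize()
        return d0, d0 + pd.Timedelta(days=1)
    if window in WINDOW_HOURS:
        return entry - pd.Timedelta(hours=WINDOW_HOURS[window]), entry
    raise ValueError(f"unknown window {window!r}")


class _Series:
    """Sorted (timestamps, values) for one patient-channel, sliceable fast."""

    __slots__ = ("t", "v")

    def __init__(self, t: np.ndarray, v: np.ndarray):
        self.t = t  # int64 ns
        self.v = v

    def slice(self, start: pd.Timestamp, end: pd.Timestamp, window: str) -> np.ndarray:
        if window == "day":  # [start, end)
            i = np.searchsorted(self.t, start.value, side="left")
            j = np.searchsorted(self.t, end.value, side="left")
        else:  # (start, end]
            i = np.searchsorted(self.t, start.value, side="right")
            j = np.searchsorted(self.t, end.value, side="right")
        return self.v[i:j]


def _stat(values: np.ndarray, stat: str) -> float:
    if stat in ("mean", "value"):
        return float(np.mean(values)) if len(values) else MISSING
    if stat == "sd":
        return float(np.std(values, ddof=1)) if len(values) >= 2 else MISSING
    if stat == "count":
        return float(len(values))
    if stat == "sum":
        return float(np.sum(values)) if len(values) else 0.0
    raise ValueError(f"unknown statistic {stat!r}")


def window_statistics(
    stream: pd.DataFrame, anchor: pd.Timestamp, window: str, stat: str
) -> float:
    """Statistic of a single-channel stream over a window ending at ``anchor``.

    ``stream`` needs columns ``timestamp`` and ``value``.  Returns NaN for an
    empty window, and for an SD over fewer than two samples.
    """
    t = pd.to_datetime(stream["timestamp"]).to_numpy().astype("datetime64[ns]").astype(np.int64)
    order = np.argsort(t, kind="stable")
    ser = _Series(t[order], stream["value"].to_numpy()[order])
    start, end = _window_bounds(pd.Timestamp(anchor), window)
    return _stat(ser.slice(start, end, window), stat)


def compute_rpp(
    sbp_event: tuple[pd.Timestamp, float],
    hr_times: Sequence[pd.Timestamp] | np.ndarray,
    hr_values: Sequence[float] | np.ndarray,
) -> float:
    """Rate-pressure product: SBP times mean HR within +-10 min of the entry."""
    t0, sbp = sbp_event
    t0 = pd.Timestamp(t0)
    ht = pd.to_datetime(pd.Series(hr_times)).to_numpy().astype("datetime64[ns]")
    hv = np.asarray(hr_values, dtype=float)
    lo, hi = t0 - pd.Timedelta(minutes=10), t0 + pd.Timedelta(minutes=10)
    inside = (ht >= lo.to_datetime64()) & (ht <= hi.to_datetime64())
    if not inside.any():
        return MISSING
    return float(sbp) * float(hv[inside].mean())


def weight_delta(
    daily: dict[date, float], day: date, lag_days: int
) -> float:
    """Change in a one-per-day entry vs. an earlier reference entry.

    lag 1: reference is the most recent prior entry at most 3 days back;
    lag 4: the entry exactly 4 days back, else the most recent 5-7 days back.
    Used for weight and for SBP/DBP alike.  NaN when today's entry or any
    admissible reference is absent.
    """
    if lag_days not in (1, 4):
        raise ValueError("lag_days must be 1 or 4")
    today = daily.get(day)
    if today is None or np.isnan(today):
        return MISSING
    if lag_days == 1:
        candidates = [1, 2, 3]
    else:
        candidates = [4, 5, 6, 7]
    for back in candidates:
        ref = daily.get(day - timedelta(days=back))
        if ref is not None and not np.isnan(ref):
            return float(today) - float(ref)
    return MISSING


def personal_ratio(
    column: Sequence[float] | np.ndarray,
    patient_ids: Sequence,
    aggregate: str = "mean",
) -> np.ndarray:
    """Feature value divided by the patient's own study-period aggregate.

    ``aggregate`` is ``mean`` for average-type features and ``sd`` for
    standard-deviation-type features.  The ratio is missing where the
    denominator is undefined, zero, or indistinguishable from zero at the
    column's own scale (below 1e-9 of the mean absolute value — difference
    features legitimately average out to ~0, where a ratio is meaningless).
    """
    col = np.asarray(column, dtype=float)
    pids = np.asarray(patient_ids)
    out = np.full(len(col), MISSING)
    for pid in pd.unique(pids):
        sel = pids == pid
        vals = col[sel]
        obs = vals[~np.isnan(vals)]
        if aggregate == "mean":
            denom = obs.mean() if len(obs) else np.nan
        elif aggregate == "sd":
            denom = obs.std(ddof=1) if len(obs) >= 2 else np.nan
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        if np.isnan(denom) or abs(denom) <= 1e-9 * np.abs(obs).mean():
            continue
        out[sel] = vals / denom
    return out


# ---------------------------------------------------------------------------
# extraction engine


def _day_series_means(ser: _Series, day0: pd.Timestamp) -> float:
    vals = ser.slice(day0, day0 + pd.Timedelta(days=1), "day")
    return float(np.mean(vals)) if len(vals) else MISSING


def _prev_day_value(fn, day0: pd.Timestamp, max_back: int = 3) -> float:
    """Most recent non-missing day value among the previous ``max_back`` days."""
    for back in range(1, max_back + 1):
        v = fn(day0 - pd.Timedelta(days=back))
        if not np.isnan(v):
            return v
    return MISSING


class _PatientData:
    """Per-patient indexed streams."""

    def __init__(self, meas: pd.DataFrame, dialect: str):
        self.dialect = dialect
        self.series: dict[str, _Series] = {}
        t_all = meas["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        for ch, grp in meas.groupby("channel", sort=False):
            idx = grp.index.to_numpy()
            t = t_all[meas.index.get_indexer(idx)]
            order = np.argsort(t, kind="stable")
            self.series[ch] = _Series(t[order], grp["value"].to_numpy()[order])

    def get(self, ch: str) -> _Series:
        return self.series.get(ch, _Series(np.empty(0, dtype=np.int64), np.empty(0)))


def _activity_codes(dialect: str) -> dict[str, int]:
    return {c: i for i, c in enumerate(ACTIVITY_CLASSES[dialect])}


def _compute_spec(spec: FeatureSpec, pdat: _PatientData, entry: pd.Timestamp) -> float:
    """One feature value for one FOH entry; NaN encodes 'not computable'."""
    dialect = pdat.dialect
    day0 = entry.normalize()

    def win_vals(ch: str, window: str) -> np.ndarray:
        start, end = _window_bounds(entry, window)
        return pdat.get(ch).slice(start, end, window)

    def day_mean(ch: str, d: pd.Timestamp) -> float:
        return _day_series_means(pdat.get(ch), d)

    kind = spec.kind
    if kind == "window_stat":
        ch = spec.channels[0]
        if spec.window == "diff":
            today = day_mean(ch, day0)
            prev = _prev_day_value(lambda d: day_mean(ch, d), day0)
            return today - prev if not (np.isnan(today) or np.isnan(prev)) else MISSING
        return _stat(win_vals(ch, spec.window), spec.stat)

    if kind == "daily_value":
        return day_mean(spec.channels[0], day0)

    if kind == "delta":
        ch = spec.channels[0]
        lag = 1 if spec.window == "d1" else 4
        daily = {
            (day0 - pd.Timedelta(days=b)).date(): day_mean(ch, day0 - pd.Timedelta(days=b))
            for b in range(0, 8)
        }
        return weight_delta(daily, day0.date(), lag)

    if kind == "ratio2":
        a, b = spec.channels

        def ratio_at(window: str, d: pd.Timestamp | None = None) -> float:
            if d is not None:
                num, den = day_mean(a, d), day_mean(b, d)
            else:
                va, vb = win_vals(a, window), win_vals(b, window)
                num = float(np.mean(va)) if len(va) else MISSING
                den = float(np.mean(vb)) if len(vb) else MISSING
            if np.isnan(num) or np.isnan(den) or den == 0:
                return MISSING
            return num / den

        if spec.window == "diff":
            today = ratio_at("day", day0)
            prev = _prev_day_value(lambda d: ratio_at("day", d), day0)
            return today - prev if not (np.isnan(today) or np.isnan(prev)) else MISSING
        return ratio_at(spec.window)

    if kind == "rpp":
        sbp_ser, hr_ser = pdat.get("sbp"), pdat.get("hr")

        def rpp_for_events(start: pd.Timestamp, end: pd.Timestamp, closed_day: bool) -> float:
            if closed_day:
                i = np.searchsorted(sbp_ser.t, start.value, side="left")
                j = np.searchsorted(sbp_ser.t, end.value, side="left")
            else:
                i = np.searchsorted(sbp_ser.t, start.value, side="right")
                j = np.searchsorted(sbp_ser.t, end.value, side="right")
            vals = []
            for k in range(i, j):
                v = compute_rpp(
                    (pd.Timestamp(sbp_ser.t[k]), sbp_ser.v[k]),
                    hr_ser.t.astype("datetime64[ns]"),
                    hr_ser.v,
                )
                if not np.isnan(v):
                    vals.append(v)
            return float(np.mean(vals)) if vals else MISSING

        def rpp_day(d: pd.Timestamp) -> float:
            return rpp_for_events(d, d + pd.Timedelta(days=1), True)

        if spec.window == "diff":
            today = rpp_day(day0)
            prev = _prev_day_value(rpp_day, day0)
            return today - prev if not (np.isnan(today) or np.isnan(prev)) else MISSING
        if spec.window == "day":
            return rpp_day(day0)
        start, end = _window_bounds(entry, spec.window)
        return rpp_for_events(start, end, False)

    if kind == "act_fraction":
        codes = _activity_codes(dialect)
        code = codes[spec.extra]

        def frac(window: str, d: pd.Timestamp | None = None) -> float:
            if d is not None:
                vals = pdat.get("activity_class").slice(d, d + pd.Timedelta(days=1), "day")
            else:
                vals = win_vals("activity_class", window)
            if len(vals) == 0:
                return MISSING
            return float(np.mean(vals == code))

        if spec.window == "diff":
            today = frac("day", day0)
            prev = _prev_day_value(lambda d: frac("day", d), day0)
            return today - prev if not (np.isnan(today) or np.isnan(prev)) else MISSING
        return frac(spec.window)

    if kind in ("hr_static_dynamic", "per_activity_stat", "hr_act_diff", "hr_act_ratio", "paired_ratio_mean"):
        act = pdat.get("activity_class")
        codes = _activity_codes(dialect)

        def matched(ch: str, start: pd.Timestamp, end: pd.Timestamp, closed_day: bool):
            ser = pdat.get(ch)
            side = "left" if closed_day else "right"
            i = np.searchsorted(ser.t, start.value, side=side)
            j = np.searchsorted(ser.t, end.value, side=side)
            t, v = ser.t[i:j], ser.v[i:j]
            # pair with the activity sample at the identical timestamp
            pos = np.searchsorted(act.t, t)
            ok = (pos < len(act.t)) & (act.t[np.minimum(pos, len(act.t) - 1)] == t)
            return v[ok], act.v[pos[ok]].astype(int)

        if kind == "paired_ratio_mean":
            a, b = spec.channels
            sa, sb = pdat.get(a), pdat.get(b)
            start, end = _window_bounds(entry, "day")
            ia = np.searchsorted(sa.t, start.value, side="left")
            ja = np.searchsorted(sa.t, end.value, side="left")
            ta, va = sa.t[ia:ja], sa.v[ia:ja]
            if len(ta) == 0 or len(sb.t) == 0:
                return MISSING
            pos = np.searchsorted(sb.t, ta)
            ok = (pos < len(sb.t)) & (sb.t[np.minimum(pos, len(sb.t) - 1)] == ta)
            va, vb = va[ok], sb.v[pos[ok]]
            good = vb != 0
            if not good.any():
                return MISSING
            return float(np.mean(va[good] / vb[good]))

        def act_window(window: str, d: pd.Timestamp | None = None):
            if d is not None:
                return matched(spec.channels[0], d, d + pd.Timedelta(days=1), True)
            start, end = _window_bounds(entry, window)
            return matched(spec.channels[0], start, end, window == "day")

        if kind == "hr_static_dynamic":
            def ratio(window: str, d: pd.Timestamp | None = None) -> float:
                v, a = act_window(window, d)
                static = [codes[c] for c in ACTIVITY_CLASSES[dialect] if c not in ACTIVE_CLASSES[dialect]]
                dyn = [codes[c] for c in ACTIVE_CLASSES[dialect]]
                vs, vd = v[np.isin(a, static)], v[np.isin(a, dyn)]
                if len(vs) == 0 or len(vd) == 0 or np.mean(vd) == 0:
                    return MISSING
                return float(np.mean(vs) / np.mean(vd))

            if spec.window == "diff":
                today = ratio("day", day0)
                prev = _prev_day_value(lambda d: ratio("day", d), day0)
                return today - prev if not (np.isnan(today) or np.isnan(prev)) else MISSING
            return ratio(spec.window)

        if kind == "per_activity_stat":
            v, a = act_window("day")
            sel = v[a == codes[spec.extra]]
            return _stat(sel, spec.stat)

        # hr_act_diff / hr_act_ratio between a pair of activity classes
        ca, cb = spec.extra.split("|")
        v, a = act_window("day")
        va, vb = v[a == codes[ca]], v[a == codes[cb]]
        if len(va) == 0 or len(vb) == 0:
            return MISSING
        ma, mb = float(np.mean(va)), float(np.mean(vb))
        if kind == "hr_act_diff":
            return ma - mb
        return ma / mb if mb != 0 else MISSING

    if kind == "act_pair_ratio":
        codes = _activity_codes(dialect)
        ca, cb = spec.extra.split("|")
        vals = pdat.get("activity_class").slice(day0, day0 + pd.Timedelta(days=1), "day")
        if len(vals) == 0:
            return MISSING
        fa, fb = float(np.mean(vals == codes[ca])), float(np.mean(vals == codes[cb]))
        return fa / fb if fb != 0 else MISSING

    if kind == "double_product":
        sbp, dbp = day_mean("sbp", day0), day_mean("dbp", day0)
        hr = day_mean("hr", day0)
        if np.isnan(sbp) or np.isnan(dbp) or np.isnan(hr):
            return MISSING
        return (sbp + dbp) / 2.0 * hr

    if kind == "ratio_daily":
        a, b = spec.channels
        va, vb = day_mean(a, day0), day_mean(b, day0)
        if np.isnan(va) or np.isnan(vb) or vb == 0:
            return MISSING
        return va / vb

    if kind in ("ex_count", "ex_sum"):
        vals = win_vals(spec.channels[0], spec.window)
        return float(len(vals)) if kind == "ex_count" else (float(np.sum(vals)) if len(vals) else 0.0)

    raise ValueError(f"unknown feature kind {spec.kind!r}")


def extract_features(
    cohort: Cohort,
    reports: pd.DataFrame,
    registry: Sequence[FeatureSpec] | None = None,
    curation: Sequence[ChannelCurationRule] = DEFAULT_CURATION,
) -> pd.DataFrame:
    """Build the feature matrix: one row per FOH report.

    Returns a DataFrame with metadata columns ``patient_id`` and ``date``
    followed by one column per registry entry; missing values are NaN.
    Personal-ratio columns are filled after all base columns, each value
    divided by the patient's study-period aggregate of the base column.
    """
    if registry is None:
        registry = feature_registry(cohort.dialect)
    curated, _ = curate_measurements(cohort.measurements, curation)
    base_specs = [s for s in registry if s.kind != "pratio"]
    pr_specs = [s for s in registry if s.kind == "pratio"]

    reports = reports.copy()
    reports["date"] = pd.to_datetime(reports["date"]).dt.date
    reports = reports.sort_values(["patient_id", "date"]).reset_index(drop=True)

    rows: list[dict] = []
    for pid, rep in reports.groupby("patient_id", sort=True):
        meas = curated[curated["patient_id"] == pid]
        pdat = _PatientData(meas, cohort.dialect)
        for _, r in rep.iterrows():
            entry = pd.Timestamp(r["date"]) + pd.Timedelta(minutes=FOH_ENTRY_MINUTE)
            row = {"patient_id": pid, "date": r["date"]}
            for spec in base_specs:
                row[spec.name] = _compute_spec(spec, pdat, entry)
            rows.append(row)
    matrix = pd.DataFrame(rows)
    for spec in pr_specs:
        agg = "sd" if spec.stat == "sd" else "mean"
        matrix[spec.name] = personal_ratio(
            matrix[spec.extra].to_numpy(), matrix["patient_id"].to_numpy(), agg
        )
    return matrix


def extract_heartman_features(cohort: Cohort, reports: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix under the HeartMan enumeration."""
    return extract_features(cohort, reports, heartman_registry())


def extract_chiron_features(cohort: Cohort, reports: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix under the Chiron enumeration."""
    return extract_features(cohort, reports, chiron_registry())


META_COLUMNS = ("patient_id", "date", "label", "dataset")


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


def compatible_feature_set(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> list[str]:
    """Name-matched intersection of two feature matrices' columns, sorted."""
    common = sorted(set(feature_columns(matrix_a)) & set(feature_columns(matrix_b)))
    if not common:
        raise ValueError("the two matrices share no feature columns")
    return common
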