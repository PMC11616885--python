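"""Synthetic telemonitoring cohorts with known ground truth.

The clinical datasets this pipeline was designed around (daily self-reports
plus chest-strap / wristband / ambient-sensor streams from heart-failure
patients) are not publicly deposited.  This module generates cohorts with the
same statistical structure so the pipeline can be exercised and validated
end to end:

* a per-patient latent daily health state in {worse, same, better} relative
  to the patient's usual state, following a sticky (persistent) Markov
  chain — people tend to feel bad for several days in a row;
* per-patient physiological baselines, with daily channel values shifted by
  the latent state and observed through within-patient noise at a configured
  intra-day sampling frequency;
* daily FOH self-reports in either dialect: HeartMan-style reports encode
  the latent usual-relative state directly, Chiron-style reports encode the
  day-over-day comparison;
* heavy, structured missingness: per-channel day-level dropout, multi-day
  device non-wear blocks, and reporting gaps — all missing completely at
  random (MCAR).

Everything removed or hidden is recorded in :class:`GroundTruth`, so tests
can measure label- and value-recovery exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fohpred.labels import CLASSES, ORDINAL

STATE_DEV = {"worse": -1, "same": 0, "better": 1}

#: Nominal first calendar day of every simulated patient.
EPOCH = date(2020, 1, 1)

#: Time of day (minutes since midnight) at which the FOH entry is made.
FOH_ENTRY_MINUTE = 20 * 60


@dataclass(frozen=True)
class ChannelSpec:
    """Population parameters of one measurement channel.

    ``effect`` is the shift (in channel units) applied on worse days; better
    days get the opposite shift.  ``kind`` determines missingness behaviour:
    ``wearable`` channels are wiped by non-wear blocks, ``manual`` and
    ``ambient`` ones are not.
    """

    name: str
    kind: str  # wearable | manual | ambient
    dialect: str  # chiron | heartman | both
    mean: float
    between_sd: float
    within_sd: float
    samples_per_day: int
    effect: float
    entry_minute: int = 0  # time of day for daily (samples_per_day == 1) channels


def _grid(spec: ChannelSpec) -> np.ndarray:
    """Minutes-since-midnight sampling grid for one channel."""
    if spec.samples_per_day == 1:
        return np.array([spec.entry_minute])
    step = 1440 / spec.samples_per_day
    return (np.arange(spec.samples_per_day) * step + step / 2).astype(int)


# Activity classes per dialect, with heart-rate and energy-expenditure
# offsets (bpm / MET) applied to samples falling in each class, and the
# baseline time-budget fractions that the latent state perturbs.
ACTIVITY_CLASSES: dict[str, list[str]] = {
    "heartman": ["walking", "running", "other_movement", "standing", "rest"],
    "chiron": ["lying", "sitting", "moving"],
}
ACTIVITY_BASE_FRACTIONS: dict[str, list[float]] = {
    "heartman": [0.08, 0.01, 0.06, 0.25, 0.60],
    "chiron": [0.45, 0.35, 0.20],
}
# classes counted as physically active (latent 'worse' suppresses these)
ACTIVE_CLASSES: dict[str, list[str]] = {
    "heartman": ["walking", "running", "other_movement"],
    "chiron": ["moving"],
}
HR_ACTIVITY_OFFSET: dict[str, dict[str, float]] = {
    "heartman": {"walking": 12, "running": 25, "other_movement": 8, "standing": 2, "rest": -4},
    "chiron": {"lying": -5, "sitting": 0, "moving": 12},
}
EE_ACTIVITY_OFFSET: dict[str, dict[str, float]] = {
    "heartman": {"walking": 1.5, "running": 4.0, "other_movement": 1.0, "standing": 0.2, "rest": -0.4},
    "chiron": {"lying": -0.4, "sitting": 0.0, "moving": 1.6},
}


def default_channels(dialect: str) -> dict[str, ChannelSpec]:
    """The default channel registry for one dialect.

    The union of the two studies' channels, each flagged with the dialect it
    belongs to; shared channels carry the same name in both dialects so that
    cross-dialect feature compatibility is computable by name.  Population
    parameters are plausible adult-CHF values; none are claims about the
    real cohorts.
    """
    specs = [
        # wearable continuous                            mean  btw   wthn  n/d  effect
        ChannelSpec("hr", "wearable", "both", 72.0, 8.0, 5.0, 24, 6.0),
        ChannelSpec("skin_temp", "wearable", "both", 33.0, 0.8, 0.4, 24, -0.5),
        ChannelSpec("energy_expenditure", "wearable", "both", 1.6, 0.3, 0.25, 24, -0.25),
        ChannelSpec("gsr", "wearable", "heartman", 5.0, 1.5, 0.8, 24, 0.8),
        ChannelSpec("body_humidity", "wearable", "chiron", 60.0, 8.0, 4.0, 24, 3.0),
        ChannelSpec("pr_interval", "wearable", "chiron", 160.0, 12.0, 6.0, 24, 4.0),
        ChannelSpec("qrs_duration", "wearable", "chiron", 95.0, 8.0, 4.0, 24, 3.0),
        ChannelSpec("qt_interval", "wearable", "chiron", 400.0, 20.0, 10.0, 24, 8.0),
        ChannelSpec("t_wave_amp", "wearable", "chiron", 0.30, 0.06, 0.03, 24, -0.03),
        ChannelSpec("r_wave_amp", "wearable", "chiron", 1.00, 0.15, 0.08, 24, -0.05),
        # manual daily entries
        ChannelSpec("weight", "manual", "both", 80.0, 12.0, 0.3, 1, 0.4, entry_minute=8 * 60),
        ChannelSpec("sbp", "manual", "both", 125.0, 12.0, 7.0, 1, 5.0, entry_minute=510),
        ChannelSpec("dbp", "manual", "both", 78.0, 8.0, 5.0, 1, 3.0, entry_minute=510),
        ChannelSpec("spo2", "manual", "chiron", 96.5, 1.0, 0.6, 1, -0.8, entry_minute=540),
        # ambient: daily manual entry in chiron, continuous sensor in heartman
        ChannelSpec("air_temp", "ambient", "chiron", 21.0, 2.0, 1.5, 1, 0.0, entry_minute=720),
        ChannelSpec("air_humidity", "ambient", "chiron", 45.0, 6.0, 5.0, 1, 0.0, entry_minute=720),
        ChannelSpec("air_temp", "ambient", "heartman", 21.0, 2.0, 1.5, 24, 0.0),
        ChannelSpec("air_humidity", "ambient", "heartman", 45.0, 6.0, 5.0, 24, 0.0),
        ChannelSpec("air_pressure", "ambient", "heartman", 1013.0, 5.0, 3.0, 24, 0.0),
    ]
    out: dict[str, ChannelSpec] = {}
    for s in specs:
        if s.dialect in (dialect, "both"):
            out[s.name] = s
    return out


@dataclass
class SyntheticConfig:
    """All the dials of the cohort generator.

    ``n_days`` may be a single integer (every patient observed that long) or
    an inclusive ``(lo, hi)`` range sampled per patient, mirroring the very
    uneven participation seen in telemonitoring studies.  ``effect_size``
    multiplies every channel's latent-state shift; ``effect_mode``
    ``"patient_specific"`` gives each patient an independent random sign per
    channel, which destroys any population-level feature-to-label link while
    preserving the within-patient one.
    """

    n_patients: int = 20
    n_days: int | tuple[int, int] = 120
    dialect: str = "heartman"
    state_persistence: float = 0.8
    state_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    effect_size: float = 1.0
    effect_mode: str = "shared"  # shared | patient_specific
    channel_params: Mapping[str, ChannelSpec] | None = None
    missing_rate_channel: float | Mapping[str, float] = 0.15
    nonwear_block_prob: float = 0.03
    nonwear_block_len: tuple[int, int] = (2, 4)
    report_prob: float = 0.8
    exercise_prob: float = 0.5
    include_activity: bool = True
    seed: int = 0

    def channels(self) -> dict[str, ChannelSpec]:
        if self.channel_params is not None:
            return dict(self.channel_params)
        return default_channels(self.dialect)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = (self.n_days, self.n_days) if isinstance(self.n_days, int) else self.n_days
        if lo < 1 or hi < lo:
            raise ValueError("n_days must be >= 1 (and lo <= hi for a range)")
        if self.dialect not in ("chiron", "heartman"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not np.isclose(sum(self.state_probs), 1.0):
            raise ValueError("state_probs must sum to 1")
        probs = list(self.state_probs) + [
            self.state_persistence,
            self.report_prob,
            self.nonwear_block_prob,
            self.exercise_prob,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        rates = (
            self.missing_rate_channel.values()
            if isinstance(self.missing_rate_channel, Mapping)
            else [self.missing_rate_channel]
        )
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("missing rates must lie in [0, 1]")
        if self.effect_mode not in ("shared", "patient_specific"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")


@dataclass
class Cohort:
    """Long-format measurements and FOH reports for a simulated cohort."""

    measurements: pd.DataFrame  # patient_id, timestamp, channel, value
    reports: pd.DataFrame  # patient_id, date, raw_value, dialect
    dialect: str


@dataclass
class GroundTruth:
    """The generator's hidden state, for recovery tests only."""

    latent_state: pd.DataFrame  # patient_id, date, state
    masked_values: pd.DataFrame  # patient_id, timestamp, channel, value
    baselines: pd.DataFrame  # patient_id, channel, baseline
    effect_signs: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_latent_foh(
    n_days: int,
    persistence: float,
    probs: Sequence[float],
    rng_seed: int | np.random.Generator,
) -> list[str]:
    """Simulate the sticky latent health-state chain for one patient.

    Day 0 is drawn from ``probs`` (over worse/same/better); each later day
    repeats the previous day's state with probability ``persistence`` and is
    redrawn from ``probs`` otherwise.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0) or (probs < 0).any():
        raise ValueError("probs must be a non-negative triple summing to 1")
    if not 0.0 <= persistence <= 1.0:
        raise ValueError("persistence must lie in [0, 1]")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    states = np.empty(n_days, dtype=int)
    states[0] = rng.choice(3, p=probs)
    repeat = rng.random(n_days) < persistence
    redraw = rng.choice(3, size=n_days, p=probs)
    for i in range(1, n_days):
        states[i] = states[i - 1] if repeat[i] else redraw[i]
    return [CLASSES[s] for s in states]


def latent_stationary_distribution(
    persistence: float, probs: Sequence[float]
) -> np.ndarray:
    """Stationary distribution of the sticky chain (equals ``probs``).

    The transition matrix is ``persistence * I + (1 - persistence) * 1 probs``,
    whose stationary vector is ``probs`` itself; kept as a function so tests
    can assert the identity from the transition matrix rather than by fiat.
    """
    probs = np.asarray(probs, dtype=float)
    T = persistence * np.eye(3) + (1 - persistence) * np.ones((3, 1)) * probs
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    return pi / pi.sum()


def derive_yesterday_relative(
    dates: Sequence[date], latent: Sequence[str]
) -> list[str]:
    """Chiron-dialect (yesterday-relative) labels implied by latent states.

    For a reported day whose previous calendar day was also reported, the
    label reflects whether the latent state's ordinal went down (worse),
    stayed (same) or went up (better).  The first day of any run of
    consecutive reported days is ``same``: the patient has no reported
    yesterday to compare against.
    """
    dates = list(dates)
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("dates must be strictly increasing")
    out: list[str] = []
    for i, d in enumerate(dates):
        if i == 0 or dates[i - 1] != d - timedelta(days=1):
            out.append("same")
        else:
            diff = ORDINAL[latent[i]] - ORDINAL[latent[i - 1]]
            out.append("worse" if diff < 0 else "better" if diff > 0 else "same")
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _raw_from_canonical(canon: Sequence[str], dialect: str, rng: np.random.Generator) -> np.ndarray:
    """Emit 5-point raw answers: extremes split randomly into their two grades."""
    raw = np.empty(len(canon), dtype=int)
    for i, c in enumerate(canon):
        grade = int(rng.integers(0, 2))  # 0 = moderate, 1 = extreme
        if c == "same":
            raw[i] = 3
        elif dialect == "chiron":
            raw[i] = (2 - grade) if c == "worse" else (4 + grade)
        else:  # heartman scale runs the other way
            raw[i] = (4 + grade) if c == "worse" else (2 - grade)
    return raw


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a fully structured cohort plus its ground truth.

    Missingness (channel dropout, non-wear blocks) is injected by
    :func:`apply_missingness`; reporting gaps are applied here.  Identical
    config and seed give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    channels = config.channels()
    dialect = config.dialect
    act_classes = ACTIVITY_CLASSES[dialect]
    act_base = np.log(np.asarray(ACTIVITY_BASE_FRACTIONS[dialect]))
    active = [act_classes.index(c) for c in ACTIVE_CLASSES[dialect]]
    rest_like = [i for i in range(len(act_classes)) if i not in active]

    meas_frames: list[pd.DataFrame] = []
    report_rows: list[pd.DataFrame] = []
    latent_rows: list[pd.DataFrame] = []
    baseline_rows: list[dict] = []
    sign_rows: list[dict] = []

    lo, hi = (
        (config.n_days, config.n_days)
        if isinstance(config.n_days, int)
        else config.n_days
    )

    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        n_days = int(rng.integers(lo, hi + 1))
        days = [EPOCH + timedelta(days=i) for i in range(n_days)]
        states = simulate_latent_foh(
            n_days, config.state_persistence, config.state_probs, rng
        )
        dev = np.array([STATE_DEV[s] for s in states], dtype=float)
        latent_rows.append(
            pd.DataFrame({"patient_id": pid, "date": days, "state": states})
        )

        # per-patient activity time budget, perturbed daily by the state
        act_logit_base = act_base + rng.normal(0, 0.3, size=len(act_classes))
        logits = np.tile(act_logit_base, (n_days, 1))
        shift = 0.5 * config.effect_size * dev
        logits[:, active] -= shift[:, None]
        logits[:, rest_like] += shift[:, None] * len(active) / max(len(rest_like), 1)
        fracs = _softmax(logits)

        act_samples: np.ndarray | None = None
        if config.include_activity:
            spd = 24
            u = rng.random((n_days, spd))
            act_samples = (u[:, :, None] > np.cumsum(fracs, axis=1)[:, None, :]).sum(
                axis=2
            )
            step = 1440 // spd
            minutes = np.arange(spd) * step + step // 2
            ts = [
                pd.Timestamp(d) + pd.Timedelta(minutes=int(m))
                for d in days
                for m in minutes
            ]
            meas_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "timestamp": ts,
                        "channel": "activity_class",
                        "value": act_samples.ravel().astype(float),
                    }
                )
            )

        for name, spec in channels.items():
            baseline = spec.mean + spec.between_sd * rng.normal()
            sign = 1.0
            if config.effect_mode == "patient_specific" and spec.effect != 0:
                sign = float(rng.choice([-1.0, 1.0]))
            baseline_rows.append(
                {"patient_id": pid, "channel": name, "baseline": baseline}
            )
            sign_rows.append({"patient_id": pid, "channel": name, "sign": sign})
            # worse days shift by +effect, better days by -effect
            day_level = (
                baseline
                - sign * spec.effect * config.effect_size * dev
                + spec.within_sd * rng.normal(size=n_days)
            )
            grid = _grid(spec)
            spd = len(grid)
            values = np.repeat(day_level, spd) + (spec.within_sd / 2) * rng.normal(
                size=n_days * spd
            )
            if name in ("hr", "energy_expenditure") and act_samples is not None and spd == 24:
                offs = np.array(
                    [HR_ACTIVITY_OFFSET[dialect][c] for c in act_classes]
                    if name == "hr"
                    else [EE_ACTIVITY_OFFSET[dialect][c] for c in act_classes]
                )
                values = values + offs[act_samples.ravel()]
            if name in ("energy_expenditure", "gsr"):
                values = np.maximum(values, 0.05)
            ts = [
                pd.Timestamp(d) + pd.Timedelta(minutes=int(m))
                for d in days
                for m in grid
            ]
            meas_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "timestamp": ts,
                        "channel": name,
                        "value": values,
                    }
                )
            )

        if dialect == "heartman" and config.exercise_prob > 0:
            ex_rows = []
            for i, d in enumerate(days):
                if rng.random() >= config.exercise_prob:
                    continue
                for slot in range(int(rng.integers(1, 3))):
                    t = pd.Timestamp(d) + pd.Timedelta(minutes=600 + 420 * slot)
                    dur = float(max(5.0, rng.normal(20, 5)))
                    ex_rows.append((t, "exercise_duration", dur))
                    ex_rows.append((t, "exercise_type", float(rng.integers(0, 2))))
                    ex_rows.append(
                        (t, "exercise_validity", float(rng.random() < 0.8))
                    )
            if ex_rows:
                ts, ch, vals = zip(*ex_rows)
                meas_frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": pid,
                            "timestamp": list(ts),
                            "channel": list(ch),
                            "value": list(vals),
                        }
                    )
                )

        # FOH reports on a random subset of days
        reported = rng.random(n_days) < config.report_prob
        rep_days = [d for d, r in zip(days, reported) if r]
        rep_states = [s for s, r in zip(states, reported) if r]
        if rep_days:
            if dialect == "heartman":
                canon = rep_states
            else:
                canon = derive_yesterday_relative(rep_days, rep_states)
            raw = _raw_from_canonical(canon, dialect, rng)
            report_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "date": rep_days,
                        "raw_value": raw,
                        "dialect": dialect,
                    }
                )
            )

    measurements = (
        pd.concat(meas_frames, ignore_index=True)
        if meas_frames
        else pd.DataFrame(columns=["patient_id", "timestamp", "channel", "value"])
    )
    measurements = measurements.sort_values(
        ["patient_id", "channel", "timestamp"], kind="stable"
    ).reset_index(drop=True)
    reports = (
        pd.concat(report_rows, ignore_index=True)
        if report_rows
        else pd.DataFrame(columns=["patient_id", "date", "raw_value", "dialect"])
    )
    truth = GroundTruth(
        latent_state=pd.concat(latent_rows, ignore_index=True),
        masked_values=pd.DataFrame(
            columns=["patient_id", "timestamp", "channel", "value"]
        ),
        baselines=pd.DataFrame(baseline_rows),
        effect_signs=pd.DataFrame(sign_rows),
    )
    return Cohort(measurements, reports, dialect), truth


def apply_missingness(
    cohort: Cohort, config: SyntheticConfig, rng_seed: int
) -> tuple[Cohort, pd.DataFrame]:
    """Inject MCAR missingness into a fully observed cohort.

    Two mechanisms: per-channel day-level Bernoulli dropout (a forgotten
    manual entry, a sensor not synced) and contiguous multi-day non-wear
    blocks that wipe all wearable channels at once.  Returns the masked
    cohort and the removed values (the ``masked_values`` ground truth).
    """
    rng = np.random.default_rng(rng_seed)
    meas = cohort.measurements
    if meas.empty:
        return Cohort(meas.copy(), cohort.reports.copy(), cohort.dialect), meas.copy()
    channels = config.channels()
    rate = config.missing_rate_channel
    rate_for = (
        (lambda ch: rate.get(ch, 0.0))
        if isinstance(rate, Mapping)
        else (lambda ch: float(rate))
    )

    day = meas["timestamp"].dt.normalize()
    drop = np.zeros(len(meas), dtype=bool)

    # iterate over patient-days deterministically (sorted) for reproducibility
    for pid, grp in meas.groupby("patient_id", sort=True):
        days = np.sort(day.loc[grp.index].unique())
        # non-wear blocks
        nonwear = np.zeros(len(days), dtype=bool)
        if config.nonwear_block_prob > 0:
            starts = rng.random(len(days)) < config.nonwear_block_prob
            lens = rng.integers(
                config.nonwear_block_len[0],
                config.nonwear_block_len[1] + 1,
                size=len(days),
            )
            for i in np.flatnonzero(starts):
                nonwear[i : i + lens[i]] = True
        nonwear_days = set(days[nonwear])
        for ch in sorted(grp["channel"].unique()):
            spec = channels.get(ch)
            kind = spec.kind if spec is not None else "wearable"
            if ch in ("activity_class",):
                kind = "wearable"
            if ch.startswith("exercise_"):
                kind = "manual"
            r = rate_for(ch)
            bern = rng.random(len(days)) < r
            bad = set(days[bern])
            if kind == "wearable":
                bad |= nonwear_days
            if not bad:
                continue
            idx = grp.index[grp["channel"] == ch]
            drop[meas.index.get_indexer(idx)] |= day.loc[idx].isin(bad).to_numpy()

    masked_values = meas.loc[drop].reset_index(drop=True)
    kept = meas.loc[~drop].reset_index(drop=True)
    return Cohort(kept, cohort.reports.copy(), cohort.dialect), masked_values
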