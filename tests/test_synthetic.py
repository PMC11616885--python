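"""The cohort generator: latent chain, dialect labels, missingness."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from fohpred import synthetic
from fohpred.synthetic import (
    SyntheticConfig,
    apply_missingness,
    derive_yesterday_relative,
    generate_cohort,
    latent_stationary_distribution,
    simulate_latent_foh,
)

D0 = date(2021, 3, 1)


class TestLatentChain:
    def test_full_persistence_is_constant(self):
        seq = simulate_latent_foh(10, 1.0, (0.2, 0.6, 0.2), rng_seed=1)
        assert len(set(seq)) == 1

    def test_point_mass_probs(self):
        assert simulate_latent_foh(5, 0.0, (0, 1, 0), rng_seed=2) == ["same"] * 5

    def test_marginal_matches_stationary_distribution(self):
        # long-run marginals converge to the stationary vector; the chain is
        # autocorrelated (effective sample size ~ n(1-p)/(1+p)), so the run
        # is long enough to make the 2% band several MC standard errors wide
        persistence, probs = 0.8, (0.2, 0.6, 0.2)
        n = 50000
        seq = simulate_latent_foh(n, persistence, probs, rng_seed=3)
        pi = latent_stationary_distribution(persistence, probs)
        emp = np.array([seq.count(c) for c in ("worse", "same", "better")]) / n
        assert np.all(np.abs(emp - pi) < 0.02)

    def test_stationary_equals_redraw_probs(self):
        # the sticky chain's stationary vector is the redraw distribution
        pi = latent_stationary_distribution(0.9, (0.3, 0.4, 0.3))
        assert np.allclose(pi, (0.3, 0.4, 0.3))

    @pytest.mark.parametrize("probs", [(0.5, 0.5, 0.5), (-0.1, 0.6, 0.5)])
    def test_invalid_probs_rejected(self, probs):
        with pytest.raises(ValueError):
            simulate_latent_foh(5, 0.5, probs, rng_seed=0)

    def test_seed_determinism(self):
        a = simulate_latent_foh(50, 0.7, (0.25, 0.5, 0.25), rng_seed=9)
        b = simulate_latent_foh(50, 0.7, (0.25, 0.5, 0.25), rng_seed=9)
        assert a == b


class TestYesterdayRelative:
    def test_hand_worked_example(self):
        ds = [D0 + timedelta(days=i) for i in range(4)]
        got = derive_yesterday_relative(ds, ["same", "worse", "worse", "better"])
        assert got == ["same", "worse", "same", "better"]

    def test_constant_latent_is_all_same(self):
        ds = [D0 + timedelta(days=i) for i in range(5)]
        assert derive_yesterday_relative(ds, ["worse"] * 5) == ["same"] * 5

    def test_gap_starts_a_new_run(self):
        ds = [D0, D0 + timedelta(days=2)]
        assert derive_yesterday_relative(ds, ["same", "worse"]) == ["same", "same"]


class TestGenerateCohort:
    def test_determinism(self):
        cfg = SyntheticConfig(n_patients=2, n_days=10, seed=5)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.measurements, c2.measurements)
        pd.testing.assert_frame_equal(c1.reports, c2.reports)
        pd.testing.assert_frame_equal(t1.latent_state, t2.latent_state)

    def test_no_missingness_limit(self):
        cfg = SyntheticConfig(
            n_patients=2, n_days=12, report_prob=1.0,
            missing_rate_channel=0.0, nonwear_block_prob=0.0, seed=6,
        )
        cohort, _ = generate_cohort(cfg)
        masked, masked_values = apply_missingness(cohort, cfg, 1)
        assert masked_values.empty
        pd.testing.assert_frame_equal(
            masked.measurements.reset_index(drop=True), cohort.measurements
        )
        # FOH on every day for every patient
        assert len(cohort.reports) == 2 * 12

    def test_chiron_labels_match_latent_day_over_day(self, chiron_cohort):
        _cfg, cohort, truth = chiron_cohort
        from fohpred.labels import canonicalize_reports

        rep = canonicalize_reports(cohort.reports)
        for pid, grp in rep.groupby("patient_id"):
            lat = truth.latent_state.query("patient_id == @pid").set_index("date")["state"]
            expected = derive_yesterday_relative(
                list(grp["date"]), [lat.loc[d] for d in grp["date"]]
            )
            assert list(grp["canonical"]) == expected

    def test_heartman_labels_encode_latent_directly(self, heartman_cohort):
        _cfg, cohort, truth = heartman_cohort
        from fohpred.labels import canonicalize_reports

        rep = canonicalize_reports(cohort.reports)
        merged = rep.merge(truth.latent_state, on=["patient_id", "date"])
        assert (merged["canonical"] == merged["state"]).all()

    def test_latent_state_covers_every_day(self, heartman_cohort):
        cfg, _cohort, truth = heartman_cohort
        counts = truth.latent_state.groupby("patient_id").size()
        assert (counts == cfg.n_days).all()

    def test_effect_shifts_worse_days(self):
        # large effect: HR on worse days clearly above HR on better days
        cfg = SyntheticConfig(n_patients=4, n_days=60, effect_size=3.0, seed=8)
        cohort, truth = generate_cohort(cfg)
        hr = cohort.measurements.query("channel == 'hr'").copy()
        hr["date"] = hr["timestamp"].dt.date
        daily = hr.groupby(["patient_id", "date"])["value"].mean().reset_index()
        merged = daily.merge(truth.latent_state, on=["patient_id", "date"])
        base = truth.baselines.query("channel == 'hr'").set_index("patient_id")["baseline"]
        merged["centered"] = merged["value"] - base.loc[merged["patient_id"]].to_numpy()
        worse = merged.query("state == 'worse'")["centered"].mean()
        better = merged.query("state == 'better'")["centered"].mean()
        assert worse > better + 10

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_patients=0).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(state_probs=(0.5, 0.2, 0.2)).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(report_prob=1.5).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(effect_mode="weird").validate()


class TestApplyMissingness:
    def test_conservation(self, heartman_cohort, masked_heartman):
        # observed plus masked equals the fully observed cohort, disjointly
        _cfg, cohort, _truth = heartman_cohort
        _cfg2, masked, masked_values = masked_heartman
        combined = pd.concat([masked.measurements, masked_values])
        key = ["patient_id", "channel", "timestamp"]
        combined = combined.sort_values(key, kind="stable").reset_index(drop=True)
        original = cohort.measurements.sort_values(key, kind="stable").reset_index(drop=True)
        pd.testing.assert_frame_equal(combined, original)
        assert len(masked.measurements) + len(masked_values) == len(cohort.measurements)

    def test_masked_fraction_within_binomial_bounds(self):
        rate = 0.3
        cfg = SyntheticConfig(
            n_patients=10, n_days=100, missing_rate_channel=rate,
            nonwear_block_prob=0.0, channel_params={"weight": synthetic.default_channels("heartman")["weight"]},
            include_activity=False, exercise_prob=0.0, seed=12,
        )
        cohort, _ = generate_cohort(cfg)
        _, masked_values = apply_missingness(cohort, cfg, 13)
        n = len(cohort.measurements)  # 1000 patient-days, one entry each
        frac = len(masked_values) / n
        # binomial 99% interval around the nominal rate
        half = 2.576 * np.sqrt(rate * (1 - rate) / n)
        assert abs(frac - rate) < half

    def test_nonwear_wipes_wearables_only(self):
        cfg = SyntheticConfig(
            n_patients=1, n_days=40, missing_rate_channel=0.0,
            nonwear_block_prob=0.08, nonwear_block_len=(3, 3), seed=14,
        )
        cohort, _ = generate_cohort(cfg)
        masked, masked_values = apply_missingness(cohort, cfg, 15)
        assert len(masked_values) > 0
        # manual-entry channels are untouched by non-wear
        assert set(masked_values["channel"]) <= {
            "hr", "skin_temp", "gsr", "energy_expenditure", "activity_class",
        }
        # wiped days are contiguous runs of length >= 3 for each channel
        days = sorted(set(masked_values["timestamp"].dt.date))
        runs, cur = [], [days[0]]
        for d in days[1:]:
            if (d - cur[-1]).days == 1:
                cur.append(d)
            else:
                runs.append(cur)
                cur = [d]
        runs.append(cur)
        # blocks are >= 3 consecutive days except when truncated by the end
        # of the observation period
        last_day = cohort.measurements["timestamp"].dt.date.max()
        assert all(len(r) >= 3 or r[-1] == last_day for r in runs)

    def test_zero_rates_identity(self, heartman_cohort):
        cfg, cohort, _ = heartman_cohort
        from dataclasses import replace

        quiet = replace(cfg, missing_rate_channel=0.0, nonwear_block_prob=0.0)
        masked, masked_values = apply_missingness(cohort, quiet, 1)
        assert masked_values.empty
        assert len(masked.measurements) == len(cohort.measurements)
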