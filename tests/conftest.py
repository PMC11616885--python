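"""Shared fixtures: small synthetic cohorts, generated at test time."""

from __future__ import annotations

import pytest

from fohpred.synthetic import SyntheticConfig, apply_missingness, generate_cohort


@pytest.fixture(scope="session")
def heartman_cohort():
    """Fully observed 5-patient HeartMan cohort (plus ground truth)."""
    cfg = SyntheticConfig(n_patients=5, n_days=30, dialect="heartman", seed=42)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def chiron_cohort():
    """Fully observed 5-patient Chiron cohort (plus ground truth)."""
    cfg = SyntheticConfig(n_patients=5, n_days=30, dialect="chiron", seed=43)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def masked_heartman(heartman_cohort):
    """The HeartMan cohort with default missingness injected."""
    cfg, cohort, _truth = heartman_cohort
    masked, masked_values = apply_missingness(cohort, cfg, rng_seed=7)
    return cfg, masked, masked_values
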