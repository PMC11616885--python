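"""CSV interchange formats, run configuration, and run manifests.

Everything is plain CSV so fixtures stay reviewable: long-format
measurements (``patient_id, timestamp, channel, value`` with ISO-8601
timestamps and no timezone — single-site semantics), FOH reports
(``patient_id, date, raw_value, dialect``), feature matrices (header row,
missing values as empty fields), and the ground-truth tables of the
synthetic generator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from fohpred.preprocess import ImputationPlan
from fohpred.synthetic import Cohort, GroundTruth, SyntheticConfig

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["patient_id", "timestamp", "channel", "value"]
REPORT_COLUMNS = ["patient_id", "date", "raw_value", "dialect"]


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a long-format measurements CSV; malformed rows are logged and dropped."""
    df = pd.read_csv(path, dtype={"patient_id": str, "channel": str})
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurements file missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = ts.isna() | vals.isna()
    if bad.any():
        for line in (df.index[bad] + 2).tolist():  # +2: header and 1-based lines
            logger.warning("%s: rejected malformed row at line %d", path, line)
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    df["value"] = vals[~bad]
    return df.reset_index(drop=True)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    out = df[MEASUREMENT_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_reports(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "dialect": str})
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reports file missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["raw_value"] = df["raw_value"].astype(int)
    return df


def write_reports(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_cohort(cohort: Cohort, truth: GroundTruth | None, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_measurements(cohort.measurements, outdir / "measurements.csv")
    write_reports(cohort.reports, outdir / "reports.csv")
    if truth is not None:
        truth.latent_state.to_csv(outdir / "truth_latent_state.csv", index=False)
        truth.baselines.to_csv(outdir / "truth_baselines.csv", index=False)
        if len(truth.masked_values):
            write_measurements(truth.masked_values, outdir / "truth_masked_values.csv")


def read_cohort(indir: str | Path, dialect: str | None = None) -> Cohort:
    indir = Path(indir)
    meas = read_measurements(indir / "measurements.csv")
    reps = read_reports(indir / "reports.csv")
    if dialect is None:
        dialect = str(reps["dialect"].iloc[0]) if len(reps) else "heartman"
    return Cohort(meas, reps, dialect)


# ---------------------------------------------------------------------------
# run configuration

_SCHEMA: dict[str, type | tuple] = {
    "dialect": str,
    "n_classes": int,
    "transform": bool,
    "prevday": bool,
    "schemes": list,
    "missing_threshold": (int, float),
    "imputation_method": str,
    "imputation_scope": str,
    "seed": int,
    "synthetic": dict,
}

DEFAULT_RUN_CONFIG = {
    "dialect": "heartman",
    "n_classes": 3,
    "transform": True,
    "prevday": False,
    "schemes": ["kfold10", "leave_half", "loso"],
    "missing_threshold": 0.6,
    "imputation_method": "knn",
    "imputation_scope": "personalized",
    "seed": 0,
    "synthetic": {},
}


def load_run_config(path: str | Path) -> dict:
    """Load and validate a YAML run config against the published schema."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    cfg = dict(DEFAULT_RUN_CONFIG)
    for key, value in raw.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config field {key!r}")
        if not isinstance(value, _SCHEMA[key]):
            raise ValueError(
                f"config field {key!r} has wrong type: expected "
                f"{_SCHEMA[key]}, got {type(value).__name__}"
            )
        cfg[key] = value
    if cfg["dialect"] not in ("chiron", "heartman"):
        raise ValueError(f"config field 'dialect' must be chiron or heartman")
    if cfg["n_classes"] not in (2, 3):
        raise ValueError("config field 'n_classes' must be 2 or 3")
    unknown_schemes = set(cfg["schemes"]) - {"kfold10", "loso", "leave_half"}
    if unknown_schemes:
        raise ValueError(f"config field 'schemes' has unknown entries: {sorted(unknown_schemes)}")
    return cfg


def synthetic_config_from_dict(d: dict, seed: int, dialect: str) -> SyntheticConfig:
    cfg = SyntheticConfig(seed=seed, dialect=dialect)
    for key, value in d.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown synthetic config field {key!r}")
        if key in ("n_days", "nonwear_block_len", "state_probs") and isinstance(value, list):
            value = tuple(value)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def imputation_plan_from_config(cfg: dict) -> ImputationPlan:
    return ImputationPlan(method=cfg["imputation_method"], scope=cfg["imputation_scope"])


def write_manifest(outdir: str | Path, config: dict, seed: int) -> Path:
    """Record what produced a run: config hash, seed, package versions."""
    import sklearn

    import fohpred

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "fohpred": fohpred.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
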