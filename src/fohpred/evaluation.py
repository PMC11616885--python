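"""Split schemes, metrics, experiment orchestration, recovery experiments.

Three cross-validation protocols probe how much personalization matters:

* ``kfold10`` — random 10-fold CV; each subject's days appear on both sides
  of the split, the easiest setting;
* ``loso`` — leave-one-subject-out; the model must generalize to a person it
  has never seen;
* ``leave_half`` — per-patient temporal split: each patient's earlier half
  (dates up to the midpoint of their observed span, ties to training) trains
  together with everyone else's data, the later half tests.

Metrics are plain accuracy and per-class one-vs-rest F1 with the macro
(equal-class-weight) average as the canonical aggregate; a
frequency-weighted average is available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from fohpred import labels as labels_mod
from fohpred import synthetic as synth_mod
from fohpred.features import (
    FeatureSpec,
    extract_features,
    feature_columns,
    feature_registry,
)
from fohpred.modeling import fit_classifier, oversample_train
from fohpred.preprocess import (
    FittedImputation,
    ImputationPlan,
    add_prevday_foh,
    filter_by_missingness,
)
from fohpred.synthetic import SyntheticConfig, apply_missingness, generate_cohort

logger = logging.getLogger(__name__)

SCHEMES = ("kfold10", "loso", "leave_half")


# ---------------------------------------------------------------------------
# split plans


@dataclass
class SplitPlan:
    scheme: str
    splits: list[tuple[np.ndarray, np.ndarray, str]]  # (train, test, provenance)
    excluded: list = field(default_factory=list)


def make_splits(
    metadata: pd.DataFrame, scheme: str, seed: int = 0, n_folds: int = 10
) -> SplitPlan:
    """Build the train/test row-index partitions for one scheme.

    ``metadata`` needs ``patient_id`` and ``date`` columns; row indices in
    the returned plan are positional (0..n-1).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    pids = metadata["patient_id"].to_numpy()
    dates = pd.to_datetime(metadata["date"])
    n = len(metadata)
    splits: list[tuple[np.ndarray, np.ndarray, str]] = []
    excluded: list = []

    if scheme == "kfold10":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        for fold, test in enumerate(np.array_split(perm, n_folds)):
            test = np.sort(test)
            train = np.setdiff1d(perm, test)
            splits.append((train, test, f"fold{fold}"))
    elif scheme == "loso":
        patients = pd.unique(pids)
        if len(patients) < 2:
            raise ValueError("leave-one-subject-out needs at least 2 patients")
        for pid in patients:
            test = np.flatnonzero(pids == pid)
            train = np.flatnonzero(pids != pid)
            splits.append((train, test, str(pid)))
    else:  # leave_half
        train_parts, test_parts = [], []
        for pid in pd.unique(pids):
            rows = np.flatnonzero(pids == pid)
            if len(rows) < 2:
                excluded.append(pid)
                logger.info("leave_half: patient %s has < 2 reports, excluded", pid)
                continue
            d = dates.iloc[rows]
            mid = d.min() + (d.max() - d.min()) / 2
            mid = mid.floor("D")  # midpoint day itself trains (ties to training)
            train_parts.append(rows[(d <= mid).to_numpy()])
            test_parts.append(rows[(d > mid).to_numpy()])
        splits.append(
            (np.concatenate(train_parts), np.concatenate(test_parts), "halves")
        )
    return SplitPlan(scheme, splits, excluded)


# ---------------------------------------------------------------------------
# metrics


def accuracy(y_true, y_pred) -> float:
    """Correct predictions divided by total predictions."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between true and predicted labels")
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(y_true == y_pred))


def confusion_matrix(y_true, y_pred, classes=None) -> pd.DataFrame:
    """True x predicted counts (rows = truth)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def f1_scores(y_true, y_pred, classes=None, average: str = "macro") -> dict:
    """Per-class one-vs-rest precision/recall/F1 and their aggregate.

    F1 is the harmonic mean of precision and recall; a class absent from
    both vectors contributes F1 = 0 (and is logged).  ``average`` selects
    the aggregate: ``macro`` (equal class weights, the canonical choice) or
    ``weighted`` (by true-class frequency).
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between true and predicted labels")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    per_class: dict = {}
    f1s, weights = [], []
    for cls in classes:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        if tp + fp + fn == 0:
            logger.info("class %r absent from both vectors; F1 set to 0", cls)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
        f1s.append(f1)
        weights.append(int(np.sum(y_true == cls)))
    macro = float(np.mean(f1s)) if f1s else 0.0
    total = sum(weights)
    weighted = (
        float(np.sum(np.asarray(f1s) * np.asarray(weights)) / total) if total else 0.0
    )
    return {
        "per_class": per_class,
        "macro_f1": macro,
        "weighted_f1": weighted,
        "f1": macro if average == "macro" else weighted,
    }


def compare_scores_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Welch's unpaired two-sample t-test on fold-level scores."""
    a, b = np.asarray(scores_a, dtype=float), np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each score list needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn("degenerate variance in both samples; p reported as 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# experiment orchestration


@dataclass
class ExperimentConfig:
    """One cell of the experiment grid."""

    dialect: str = "heartman"
    n_classes: int = 3
    transform: bool = True
    prevday: bool = False
    scheme: str = "kfold10"
    n_folds: int = 10
    missing_threshold: float = 0.6  # 0.3 is the customary Chiron setting
    imputation: ImputationPlan = field(default_factory=ImputationPlan)
    oversample: bool = True
    seed: int = 0


@dataclass
class EvalResult:
    config: ExperimentConfig
    scheme: str
    predictions: pd.DataFrame  # row, split, true, pred
    per_split: pd.DataFrame  # split, n_test, accuracy, macro_f1
    confusion: pd.DataFrame
    accuracy: float
    macro_f1: float
    weighted_f1: float
    per_class: dict
    excluded_patients: list = field(default_factory=list)


def build_matrix(
    cohort: synth_mod.Cohort,
    n_classes: int = 3,
    transform: bool = True,
    prevday: bool = False,
    registry: list[FeatureSpec] | None = None,
) -> pd.DataFrame:
    """Extract features and attach the (possibly transformed, reduced) label.

    Returns a feature matrix with metadata ``patient_id``/``date`` and a
    ``label`` column; for ``n_classes=2`` the ``same`` rows are dropped.
    With ``prevday`` the previous-day FOH is appended one-hot encoded (it is
    always complete, so it never enters imputation).
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    reports = labels_mod.transform_reports(cohort.reports)
    matrix = extract_features(cohort, reports, registry)
    key = ["patient_id", "date"]
    lab = reports[key + ["canonical", "transformed"]].copy()
    matrix = matrix.merge(lab, on=key, validate="one_to_one")
    matrix["label"] = matrix["transformed"] if transform else matrix["canonical"]
    matrix = matrix.drop(columns=["canonical", "transformed"])
    if prevday:
        matrix = add_prevday_foh(matrix, reports)
        onehot = pd.get_dummies(matrix["prevday_foh"], prefix="prevday").astype(float)
        matrix = pd.concat([matrix.drop(columns=["prevday_foh"]), onehot], axis=1)
    if n_classes == 2:
        keep = labels_mod.drop_same_class(matrix["label"].to_numpy())
        matrix = matrix.iloc[keep].reset_index(drop=True)
    return matrix


def run_experiment(matrix: pd.DataFrame, config: ExperimentConfig) -> EvalResult:
    """Split / impute / oversample / fit / predict / score, with leakage guards.

    The matrix must carry a ``label`` column.  Imputers are fitted on the
    training rows of each split only; SMOTE runs on training rows only.
    """
    matrix = matrix.reset_index(drop=True)
    y_all = matrix["label"].to_numpy()
    classes = sorted(set(y_all))
    plan = make_splits(matrix, config.scheme, seed=config.seed, n_folds=config.n_folds)
    filtered, _ = filter_by_missingness(matrix.drop(columns=["label"]), config.missing_threshold)

    pred_rows = []
    split_rows = []
    for train, test, prov in plan.splits:
        imp = FittedImputation(config.imputation, seed=config.seed)
        imp.fit(filtered, filtered.index.to_numpy()[train])
        completed = imp.transform(filtered)
        X_train, y_train = completed.iloc[train], y_all[train]
        if config.oversample and len(set(y_train)) >= 2:
            X_train, y_train, _synth = oversample_train(X_train, y_train, seed=config.seed)
        model = fit_classifier(X_train, y_train, seed=config.seed)
        y_hat = model.predict(completed.iloc[test])
        y_true = y_all[test]
        split_rows.append(
            {
                "split": prov,
                "n_test": len(test),
                "accuracy": accuracy(y_true, y_hat),
                "macro_f1": f1_scores(y_true, y_hat, classes)["macro_f1"],
            }
        )
        for r, t, p in zip(test, y_true, y_hat):
            pred_rows.append({"row": int(r), "split": prov, "true": t, "pred": p})

    preds = pd.DataFrame(pred_rows)
    scores = f1_scores(preds["true"], preds["pred"], classes)
    return EvalResult(
        config=config,
        scheme=config.scheme,
        predictions=preds,
        per_split=pd.DataFrame(split_rows),
        confusion=confusion_matrix(preds["true"], preds["pred"], classes),
        accuracy=accuracy(preds["true"], preds["pred"]),
        macro_f1=scores["macro_f1"],
        weighted_f1=scores["weighted_f1"],
        per_class=scores["per_class"],
        excluded_patients=plan.excluded,
    )


def run_synthetic_experiment(
    synth_config: SyntheticConfig,
    config: ExperimentConfig,
    registry: list[FeatureSpec] | None = None,
) -> EvalResult:
    """Generate a cohort, inject missingness, and run one experiment cell."""
    cohort, _truth = generate_cohort(synth_config)
    masked, _vals = apply_missingness(cohort, synth_config, synth_config.seed + 1)
    matrix = build_matrix(
        masked, config.n_classes, config.transform, config.prevday, registry
    )
    return run_experiment(matrix, config)


# ---------------------------------------------------------------------------
# recovery experiments (ground-truth-aware, used by tests and reporting)


def transformation_recovery(
    n_seeds: int = 10,
    n_patients: int = 20,
    n_days: int = 120,
    persistence: float = 0.8,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Does the yesterday->usual transformation recover the latent state?

    Generates Chiron-dialect label cohorts (measurement channels disabled:
    only reports matter here) and measures agreement of the untransformed
    and transformed canonical labels with the latent usual-relative state.
    """
    rows = []
    for s in range(n_seeds):
        cfg = SyntheticConfig(
            n_patients=n_patients,
            n_days=n_days,
            dialect="chiron",
            state_persistence=persistence,
            channel_params={},
            include_activity=False,
            seed=base_seed + s,
        )
        cohort, truth = generate_cohort(cfg)
        reports = labels_mod.transform_reports(cohort.reports)
        merged = reports.merge(
            truth.latent_state, on=["patient_id", "date"], validate="one_to_one"
        )
        rows.append(
            {
                "seed": base_seed + s,
                "n_reports": len(merged),
                "agree_untransformed": float(
                    np.mean(merged["canonical"] == merged["state"])
                ),
                "agree_transformed": float(
                    np.mean(merged["transformed"] == merged["state"])
                ),
            }
        )
    return pd.DataFrame(rows)


def _rescaled_channels(between_scale: float) -> dict:
    """HeartMan channel set with between-patient SD = scale x within-patient SD."""
    out = {}
    for name, spec in synth_mod.default_channels("heartman").items():
        out[name] = replace(spec, between_sd=between_scale * spec.within_sd)
    return out


def _day_level_registry(dialect: str) -> list[FeatureSpec]:
    """Day-window mean/value features only (no personal ratios): the compact
    registry used by the value-recovery experiment."""
    return [
        s
        for s in feature_registry(dialect)
        if s.window == "day"
        and s.kind in ("window_stat", "daily_value")
        and s.stat in ("mean", "value")
    ]


def imputation_recovery(
    between_scale: float = 3.0,
    missing_rate: float = 0.3,
    method: str = "knn",
    n_seeds: int = 10,
    n_patients: int = 10,
    n_days: int = 60,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Global vs. personalized imputation measured against held-back truth.

    A fully observed cohort yields the true feature matrix; 30% day-level
    MCAR masking is then injected and both imputation scopes complete the
    resulting matrix.  The error on cells that were masked is reported as
    RMSE normalized per column by the true column SD (channels have wildly
    different units).
    """
    rows = []
    registry = _day_level_registry("heartman")
    for s in range(n_seeds):
        cfg = SyntheticConfig(
            n_patients=n_patients,
            n_days=n_days,
            dialect="heartman",
            channel_params=_rescaled_channels(between_scale),
            missing_rate_channel=missing_rate,
            nonwear_block_prob=0.0,
            exercise_prob=0.0,
            include_activity=True,
            seed=base_seed + s,
        )
        cohort, _truth = generate_cohort(cfg)
        reports = cohort.reports
        true_matrix = extract_features(cohort, reports, registry)
        masked, _vals = apply_missingness(cohort, cfg, cfg.seed + 1)
        obs_matrix = extract_features(masked, reports, registry)
        obs_matrix, _dropped = filter_by_missingness(obs_matrix, 0.9)
        cols = feature_columns(obs_matrix)

        res = {"seed": cfg.seed}
        for scope in ("global", "personalized"):
            plan = ImputationPlan(method=method, scope=scope)
            imp = FittedImputation(plan, seed=cfg.seed)
            imp.fit(obs_matrix, obs_matrix.index.to_numpy())
            completed = imp.transform(obs_matrix)
            sq, n_cells = 0.0, 0
            for c in cols:
                hole = obs_matrix[c].isna() & true_matrix[c].notna()
                if not hole.any():
                    continue
                sd = true_matrix[c].std(ddof=0)
                if not sd or np.isnan(sd):
                    continue
                err = (completed.loc[hole, c] - true_matrix.loc[hole, c]) / sd
                sq += float(np.sum(err**2))
                n_cells += int(hole.sum())
            res[f"rmse_{scope}"] = float(np.sqrt(sq / n_cells)) if n_cells else np.nan
            res["n_cells"] = n_cells
        rows.append(res)
    return pd.DataFrame(rows)


def personalization_gap(
    n_seeds: int = 10,
    n_patients: int = 10,
    n_days: int = 60,
    effect_size: float = 1.5,
    base_seed: int = 0,
    n_classes: int = 3,
) -> pd.DataFrame:
    """Leave-half vs. LOSO macro F1 on patient-specific feature-label links.

    Each patient's channel effect signs are drawn independently, so the
    population-level feature-label relation cancels while the
    within-patient one stays strong: models evaluated subject-wise (LOSO)
    should collapse, personalized evaluation (leave_half) should not.
    """
    rows = []
    registry = _day_level_registry("heartman")
    for s in range(n_seeds):
        cfg = SyntheticConfig(
            n_patients=n_patients,
            n_days=n_days,
            dialect="heartman",
            effect_size=effect_size,
            effect_mode="patient_specific",
            missing_rate_channel=0.1,
            exercise_prob=0.0,
            seed=base_seed + s,
        )
        cohort, _truth = generate_cohort(cfg)
        masked, _vals = apply_missingness(cohort, cfg, cfg.seed + 1)
        matrix = build_matrix(masked, n_classes=n_classes, transform=True, registry=registry)
        res = {"seed": cfg.seed}
        for scheme in ("leave_half", "loso"):
            ec = ExperimentConfig(
                dialect="heartman",
                n_classes=n_classes,
                scheme=scheme,
                missing_threshold=0.6,
                seed=cfg.seed,
            )
            res[scheme] = run_experiment(matrix, ec).macro_f1
        rows.append(res)
    return pd.DataFrame(rows)


def negative_control(
    n_patients: int = 8,
    n_days: int = 40,
    seed: int = 11,
    schemes=SCHEMES,
    n_perm: int = 200,
) -> pd.DataFrame:
    """Zero-signal cohort: every scheme's macro F1 vs. its chance band.

    With ``effect_size=0`` the latent state leaves no trace in the channels,
    so the pipeline must not score beyond the no-day-level-signal null (see
    :func:`chance_band`); the returned z-scores should stay within
    Monte-Carlo noise.
    """
    cfg = SyntheticConfig(
        n_patients=n_patients,
        n_days=n_days,
        effect_size=0.0,
        exercise_prob=0.0,
        seed=seed,
    )
    cohort, _truth = generate_cohort(cfg)
    masked, _vals = apply_missingness(cohort, cfg, cfg.seed + 1)
    matrix = build_matrix(masked, registry=_day_level_registry("heartman"))
    rows = []
    for scheme in schemes:
        ec = ExperimentConfig(scheme=scheme, seed=seed)
        res = run_experiment(matrix, ec)
        groups = matrix["patient_id"].to_numpy()[res.predictions["row"].to_numpy()]
        mu, sd = chance_band(
            res.predictions["true"], res.predictions["pred"], groups, n_perm, seed
        )
        rows.append(
            {
                "scheme": scheme,
                "macro_f1": res.macro_f1,
                "chance_mean": mu,
                "chance_sd": sd,
                "z": (res.macro_f1 - mu) / sd if sd else np.nan,
            }
        )
    return pd.DataFrame(rows)


def chance_band(
    y_true, y_pred, groups=None, n_perm: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo mean and SD of macro F1 under the no-day-level-signal null.

    Labels are permuted within each group (patient) so the null preserves
    everything a model could learn from patient identity alone — baselines
    are identifiable and per-patient label frequencies are uneven under a
    persistent latent state — while destroying any day-level feature-label
    link.  With ``groups=None`` the permutation is global.
    """
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = sorted(set(y_true) | set(y_pred))
    if groups is None:
        blocks = [np.arange(len(y_true))]
    else:
        groups = np.asarray(groups)
        blocks = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    vals = []
    for _ in range(n_perm):
        perm_true = y_true.copy()
        for b in blocks:
            perm_true[b] = y_true[b][rng.permutation(len(b))]
        vals.append(f1_scores(perm_true, y_pred, classes)["macro_f1"])
    return float(np.mean(vals)), float(np.std(vals))
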