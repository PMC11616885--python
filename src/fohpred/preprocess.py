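"""Missingness filtering, global vs. personalized imputation, prev-day FOH.

Telemonitoring feature matrices are riddled with missing values (non-wear,
skipped manual entries).  The pipeline first drops features whose missing
fraction exceeds a threshold, then completes the rest with KNN or
chained-equation (MICE) imputation, either *globally* (one imputer fitted on
all training rows) or *personalized* (one imputer per patient, fitted on
that patient's training rows only).  A per-patient column with no observed
values at all falls back to the global mean.

Imputers are always fitted on an explicit set of fit rows — inside
evaluation these are the training rows, so no test-set statistics leak into
the completed matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer

from fohpred.features import feature_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationPlan:
    """How to complete a filtered feature matrix."""

    method: str = "knn"  # knn | mice
    scope: str = "global"  # global | personalized
    k_neighbors: int = 5
    max_iter: int = 10

    def __post_init__(self) -> None:
        if self.method not in ("knn", "mice"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.scope not in ("global", "personalized"):
            raise ValueError(f"unknown imputation scope {self.scope!r}")
        if self.k_neighbors < 1 or self.max_iter < 1:
            raise ValueError("k_neighbors and max_iter must be positive")


def filter_by_missingness(
    matrix: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, list[str]]:
    """Drop feature columns whose missing fraction strictly exceeds ``threshold``.

    Rows are untouched.  Returns the reduced matrix and the dropped names.
    A column at exactly the threshold is kept ("more than X% missing").
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    dropped = [
        c
        for c in feature_columns(matrix)
        if matrix[c].isna().mean() > threshold
    ]
    if dropped:
        logger.info("missingness filter dropped %d columns: %s", len(dropped), dropped)
    return matrix.drop(columns=dropped), dropped


def _make_imputer(plan: ImputationPlan, seed: int):
    if plan.method == "knn":
        return KNNImputer(n_neighbors=plan.k_neighbors)
    return IterativeImputer(max_iter=plan.max_iter, random_state=seed)


class FittedImputation:
    """Frozen state of a fitted imputation: scalers, imputers, fallbacks.

    Features are standardized with the fit-scope mean/SD before KNN distance
    computation (heterogeneous units would otherwise dominate distances) and
    de-standardized afterwards.
    """

    def __init__(self, plan: ImputationPlan, seed: int = 0):
        self.plan = plan
        self.seed = seed
        self.columns: list[str] = []
        self.global_mean: pd.Series | None = None
        self.global_sd: pd.Series | None = None
        self.global_imputer = None
        self.per_patient: dict = {}
        self.fallback_events: list[tuple[str, str]] = []

    # -- fitting -----------------------------------------------------------

    def fit(self, matrix: pd.DataFrame, fit_rows: np.ndarray) -> "FittedImputation":
        self.columns = feature_columns(matrix)
        fit = matrix.loc[fit_rows, self.columns]
        if fit.empty:
            raise ValueError("no fit rows given")
        all_missing = [c for c in self.columns if fit[c].isna().all()]
        if all_missing:
            raise ValueError(
                f"columns with zero observed values in the fit rows: {all_missing}"
            )
        self.global_mean = fit.mean()
        sd = fit.std(ddof=0)
        self.global_sd = sd.replace(0.0, 1.0).fillna(1.0)
        self.global_imputer = _make_imputer(self.plan, self.seed)
        self.global_imputer.fit(self._scale(fit))
        if self.plan.scope == "personalized":
            for pid, grp in fit.groupby(matrix.loc[fit_rows, "patient_id"], sort=True):
                observed = [c for c in self.columns if grp[c].notna().any()]
                if not observed or len(grp) < 1:
                    self.per_patient[pid] = None
                    continue
                imputer = _make_imputer(self.plan, self.seed)
                imputer.fit(self._scale(grp[observed]))
                self.per_patient[pid] = (imputer, observed)
        return self

    def _scale(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df - self.global_mean[df.columns]) / self.global_sd[df.columns]

    def _unscale(self, arr: np.ndarray, cols: list[str]) -> np.ndarray:
        return arr * self.global_sd[cols].to_numpy() + self.global_mean[cols].to_numpy()

    # -- application -------------------------------------------------------

    def _apply_global(self, block: pd.DataFrame) -> pd.DataFrame:
        out = self.global_imputer.transform(self._scale(block[self.columns]))
        return pd.DataFrame(
            self._unscale(out, self.columns), index=block.index, columns=self.columns
        )

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Complete the matrix; observed cells are passed through untouched."""
        result = matrix.copy()
        feats = matrix[self.columns]
        if self.plan.scope == "global":
            completed = self._apply_global(matrix)
        else:
            completed = pd.DataFrame(
                index=matrix.index, columns=self.columns, dtype=float
            )
            for pid, grp in matrix.groupby("patient_id", sort=True):
                state = self.per_patient.get(pid)
                if state is None:
                    # unseen patient (e.g. a held-out subject): global imputer
                    completed.loc[grp.index] = self._apply_global(grp).to_numpy()
                    if pid not in self.per_patient:
                        self.fallback_events.append((str(pid), "<unseen patient>"))
                    continue
                imputer, observed = state
                part = imputer.transform(self._scale(grp[observed]))
                completed.loc[grp.index, observed] = self._unscale(part, observed)
                for c in self.columns:
                    if c not in observed:
                        completed.loc[grp.index, c] = self.global_mean[c]
                        self.fallback_events.append((str(pid), c))
        # keep observed values exactly; fill only the holes
        filled = feats.where(feats.notna(), completed)
        # KNN can leave a cell empty if all neighbours miss it; finish with means
        filled = filled.fillna(self.global_mean)
        result[self.columns] = filled
        return result


def impute(
    matrix: pd.DataFrame,
    plan: ImputationPlan,
    fit_rows: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit on ``fit_rows`` (default: all rows) and complete the whole matrix."""
    if fit_rows is None:
        fit_rows = matrix.index.to_numpy()
    return FittedImputation(plan, seed).fit(matrix, fit_rows).transform(matrix)


def add_prevday_foh(matrix: pd.DataFrame, reports: pd.DataFrame) -> pd.DataFrame:
    """Add a categorical ``prevday_foh`` column (optional extra feature).

    For each row, yesterday's canonical label if the patient reported on the
    previous calendar day; otherwise ``same`` — with multi-day reporting
    gaps this is the only assumption-free default, and it is also the modal
    state.  The first-ever report of a patient gets ``same`` by the same
    rule.
    """
    if "canonical" not in reports.columns:
        raise ValueError("reports must be canonicalized first")
    rep = reports.copy()
    rep["date"] = pd.to_datetime(rep["date"]).dt.date
    lookup = {
        (p, d): c
        for p, d, c in zip(rep["patient_id"], rep["date"], rep["canonical"])
    }
    out = matrix.copy()
    dates = pd.to_datetime(out["date"]).dt.date
    out["prevday_foh"] = [
        lookup.get((p, d - timedelta(days=1)), "same")
        for p, d in zip(out["patient_id"], dates)
    ]
    return out
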