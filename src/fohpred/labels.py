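"""Canonicalization and harmonization of feeling-of-health (FOH) labels.

Two report schemas ("dialects") are in use.  The Chiron dialect asks how the
patient feels *compared to yesterday* (1 = much worse than yesterday … 5 =
much better than yesterday); the HeartMan dialect asks how they feel
*compared to usual* with the scale running the opposite way (1 = much better
than usual … 5 = much worse than usual).  Both are merged to three canonical
classes (``worse`` / ``same`` / ``better``), and yesterday-relative label
sequences can be transformed to usual-relative ones with a small rule system
that exploits the temporal persistence of health states.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical 3-class labels, in ordinal order (worse < same < better).
CLASSES = ("worse", "same", "better")

#: Ordinal encoding used when comparing states day over day.
ORDINAL = {"worse": 0, "same": 1, "better": 2}

#: Maximum length (in days, counting the trigger day) of a propagation run.
PROPAGATION_CAP = 5

_CHIRON_MAP = {1: "worse", 2: "worse", 3: "same", 4: "better", 5: "better"}
_HEARTMAN_MAP = {1: "better", 2: "better", 3: "same", 4: "worse", 5: "worse"}

DIALECTS = ("chiron", "heartman")


def merge_five_to_three(raw_value: int, dialect: str) -> str:
    """Merge a raw 1-5 FOH answer into the canonical 3-class label.

    The two dialects run in opposite directions (Chiron: 1 = much worse than
    yesterday; HeartMan: 1 = much better than usual); that difference is
    absorbed here, so downstream code only ever sees canonical labels.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if raw_value not in (1, 2, 3, 4, 5):
        raise ValueError(f"raw FOH value must be in 1..5, got {raw_value!r}")
    table = _CHIRON_MAP if dialect == "chiron" else _HEARTMAN_MAP
    return table[raw_value]


def _consecutive_runs(dates: Sequence[date]) -> list[list[int]]:
    """Split sorted report indices into maximal runs of consecutive days."""
    runs: list[list[int]] = []
    current = [0]
    for i in range(1, len(dates)):
        if dates[i] == dates[i - 1] + timedelta(days=1):
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    runs.append(current)
    return runs


def transform_yesterday_to_usual(
    dates: Sequence[date], labels: Sequence[str]
) -> list[str]:
    """Transform yesterday-relative canonical labels to usual-relative ones.

    The transformation rests on the observation that the usual state is the
    modal one, so a deviation reported relative to yesterday usually marks a
    deviation from usual that then *persists* while the patient keeps
    reporting "same as yesterday".  Rules, applied left-to-right within each
    maximal run of consecutive calendar days (never across reporting gaps):

    * default: worse/same/better-than-yesterday map to the same label
      relative to usual;
    * a ``worse`` followed by ``same`` days propagates ``worse`` over at most
      :data:`PROPAGATION_CAP` consecutive days, counting the triggering day;
    * propagation halts early at any non-``same`` label; a new ``worse``
      restarts the window;
    * a ``worse`` immediately followed by ``better`` turns that second day
      into ``same`` (back to baseline), and halts propagation;
    * all of the above applied symmetrically to ``better``.

    The output has exactly the length of the input; no records are dropped.
    """
    dates = list(dates)
    labels = list(labels)
    if len(dates) != len(labels):
        raise ValueError("dates and labels must have equal length")
    if len(dates) == 0:
        return []
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("dates must be strictly increasing (one report per date)")
    for lab in labels:
        if lab not in CLASSES:
            raise ValueError(f"unknown canonical label {lab!r}")

    out = list(labels)
    for run in _consecutive_runs(dates):
        direction: str | None = None
        remaining = 0
        for pos, idx in enumerate(run):
            lab = labels[idx]
            prev = labels[run[pos - 1]] if pos > 0 else None
            if lab == "same":
                if remaining > 0:
                    out[idx] = direction  # type: ignore[assignment]
                    remaining -= 1
                else:
                    out[idx] = "same"
            elif (lab == "better" and prev == "worse") or (
                lab == "worse" and prev == "better"
            ):
                # an immediate reversal reads as a return to baseline
                out[idx] = "same"
                direction, remaining = None, 0
            else:  # a fresh worse/better: keep it and open a propagation window
                out[idx] = lab
                direction = lab
                remaining = PROPAGATION_CAP - 1
    return out


def drop_same_class(labels: Sequence[str]) -> np.ndarray:
    """Row indices that survive the 3-to-2 class reduction (``same`` removed)."""
    return np.flatnonzero(np.asarray(labels, dtype=object) != "same")


def canonicalize_reports(reports: pd.DataFrame) -> pd.DataFrame:
    """Add a ``canonical`` column to a FOH reports table.

    Expects columns ``patient_id``, ``date``, ``raw_value``, ``dialect``.
    """
    required = {"patient_id", "date", "raw_value", "dialect"}
    missing = required - set(reports.columns)
    if missing:
        raise ValueError(f"reports table missing columns: {sorted(missing)}")
    out = reports.copy()
    out["canonical"] = [
        merge_five_to_three(int(v), d)
        for v, d in zip(out["raw_value"], out["dialect"])
    ]
    return out


def transform_reports(reports: pd.DataFrame) -> pd.DataFrame:
    """Add a ``transformed`` (usual-relative) column, per patient.

    HeartMan-dialect reports are already usual-relative, so their
    ``transformed`` label equals the canonical one; Chiron-dialect report
    sequences go through :func:`transform_yesterday_to_usual`.
    """
    if "canonical" not in reports.columns:
        reports = canonicalize_reports(reports)
    out = reports.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out = out.sort_values(["patient_id", "date"]).reset_index(drop=True)
    transformed = pd.Series(index=out.index, dtype=object)
    for _, grp in out.groupby("patient_id", sort=False):
        if grp["date"].duplicated().any():
            raise ValueError("duplicate report dates for a patient")
        if (grp["dialect"] == "chiron").all():
            transformed.loc[grp.index] = transform_yesterday_to_usual(
                list(grp["date"]), list(grp["canonical"])
            )
        else:
            transformed.loc[grp.index] = grp["canonical"].to_numpy()
    out["transformed"] = transformed
    return out


def mirror(labels: Iterable[str]) -> list[str]:
    """Swap worse and better; used by symmetry checks."""
    table = {"worse": "better", "same": "same", "better": "worse"}
    return [table[lab] for lab in labels]
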