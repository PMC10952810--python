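"""Outcome classification and tracking metrics from a session log.

Per measurement, the detector's answer is compared with ground truth:

- the balloon is *present* when its sphere overlaps at least one acquired
  slice slab by a minimum volume fraction;
- a detection is *correct* when the estimated balloon center falls within
  the true balloon region, with half a slice thickness of through-plane
  slack because detections are reported on slice center planes.

present and correct -> TP; present, not found -> FN; absent, not found ->
TN; absent but found -> FP. A found-but-mislocalized detection while the
balloon is present also counts FP (the detector latched onto something
that is not the balloon at that location); such measurements are flagged
separately. Detection accuracy is 100*(TP+TN)/N per mode.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import Mode, TrackingParams
from .session import SessionLog

__all__ = [
    "Outcome",
    "classify_outcome",
    "add_outcomes",
    "detection_accuracy",
    "outcome_percentages",
    "visibility_rate",
    "mode_fractions",
    "summarize",
]

DEFAULT_VISIBILITY_MIN_OVERLAP = 0.05


class Outcome(str, enum.Enum):
    TP = "TP"
    TN = "TN"
    FP = "FP"
    FN = "FN"


def classify_outcome(
    record,
    balloon_true_radius: float,
    slice_thickness: float,
    visibility_min_overlap: float = DEFAULT_VISIBILITY_MIN_OVERLAP,
) -> tuple[Outcome, bool]:
    """Classify one session record; returns (outcome, mislocalized).

    ``record`` may be a SessionRecord or a mapping with the session-log
    column names. Requires ground truth.
    """
    row = record.to_row() if hasattr(record, "to_row") else dict(record)
    if not np.isfinite(row["true_x"]) or not np.isfinite(row["max_overlap"]):
        raise ValueError("record lacks ground truth; cannot classify")
    present = row["max_overlap"] >= visibility_min_overlap
    found = bool(row["found"])
    if not present:
        return (Outcome.FP if found else Outcome.TN), False
    if not found:
        return Outcome.FN, False
    err = np.linalg.norm(
        np.array([row["x"], row["y"], row["z"]])
        - np.array([row["true_x"], row["true_y"], row["true_z"]])
    )
    tol = balloon_true_radius + slice_thickness / 2.0
    if err <= tol:
        return Outcome.TP, False
    return Outcome.FP, True  # mislocalization


def add_outcomes(
    log: SessionLog,
    balloon_true_radius: float,
    params: Optional[TrackingParams] = None,
    visibility_min_overlap: float = DEFAULT_VISIBILITY_MIN_OVERLAP,
) -> pd.DataFrame:
    """Session log -> DataFrame with ``outcome`` and ``mislocalized``.

    The through-plane slack uses the mode's slice thickness.
    """
    params = params or log.params or TrackingParams()
    df = log.to_dataframe()
    outcomes, misloc = [], []
    for _, row in df.iterrows():
        thick = (params.d_cal if row["mode"] == Mode.CALIBRATION.value
                 else params.d_run)
        o, m = classify_outcome(row, balloon_true_radius, thick,
                                visibility_min_overlap)
        outcomes.append(o.value)
        misloc.append(m)
    df["outcome"] = outcomes
    df["mislocalized"] = misloc
    return df


def _mode_subset(df: pd.DataFrame, mode: Optional[Mode]) -> pd.DataFrame:
    if mode is None:
        return df
    return df[df["mode"] == Mode(mode).value]


def detection_accuracy(df: pd.DataFrame, mode: Optional[Mode] = None) -> float:
    """100 * (TP + TN) / N over the mode's measurements (percent)."""
    sub = _mode_subset(df, mode)
    n = len(sub)
    if n == 0:
        raise ValueError(f"no measurements in mode {mode}")
    good = sub["outcome"].isin([Outcome.TP.value, Outcome.TN.value]).sum()
    return 100.0 * float(good) / n


def outcome_percentages(df: pd.DataFrame, mode: Optional[Mode] = None) -> dict:
    """Percentages of TP/TN/FP/FN outcomes; sums to 100 by construction."""
    sub = _mode_subset(df, mode)
    n = len(sub)
    if n == 0:
        raise ValueError(f"no measurements in mode {mode}")
    return {
        o.value: 100.0 * float((sub["outcome"] == o.value).sum()) / n
        for o in Outcome
    }


def visibility_rate(
    df: pd.DataFrame,
    visibility_min_overlap: float = DEFAULT_VISIBILITY_MIN_OVERLAP,
) -> float:
    """Percent of Runtime measurements in which the balloon was visible."""
    sub = df[df["mode"] == Mode.RUNTIME.value]
    if len(sub) == 0:
        raise ValueError("no Runtime measurements in log")
    visible = (sub["max_overlap"] >= visibility_min_overlap).sum()
    return 100.0 * float(visible) / len(sub)


def mode_fractions(
    df: pd.DataFrame,
    params: Optional[TrackingParams] = None,
    duration_weighted: bool = True,
) -> tuple[float, float]:
    """(Calibration %, Runtime %) of session time; sums to 100.

    A Calibration measurement acquires n_cal slices versus n_run for a
    Runtime one, so by default each measurement is weighted by its slice
    count as a proxy for duration. ``duration_weighted=False`` gives
    plain measurement-count fractions.
    """
    if len(df) == 0:
        raise ValueError("empty log")
    params = params or TrackingParams()
    is_cal = df["mode"] == Mode.CALIBRATION.value
    if duration_weighted:
        w_cal = float(params.n_cal) / float(params.n_run)
        cal_t = w_cal * is_cal.sum()
        run_t = float((~is_cal).sum())
    else:
        cal_t = float(is_cal.sum())
        run_t = float((~is_cal).sum())
    total = cal_t + run_t
    return 100.0 * cal_t / total, 100.0 * run_t / total


def summarize(
    log: SessionLog,
    balloon_true_radius: float,
    params: Optional[TrackingParams] = None,
    visibility_min_overlap: float = DEFAULT_VISIBILITY_MIN_OVERLAP,
) -> pd.DataFrame:
    """One-row metrics table: accuracy per mode, Runtime outcome
    percentages, visibility rate, mode-time fractions, measurement count.

    Outcome denominators pool *all* measurements of the mode in the log.
    """
    params = params or log.params or TrackingParams()
    df = add_outcomes(log, balloon_true_radius, params, visibility_min_overlap)
    has_run = (df["mode"] == Mode.RUNTIME.value).any()
    has_cal = (df["mode"] == Mode.CALIBRATION.value).any()
    pct = (outcome_percentages(df, Mode.RUNTIME) if has_run
           else dict.fromkeys(["TP", "TN", "FP", "FN"], float("nan")))
    cal_frac, run_frac = mode_fractions(df, params)
    out = {
        "n_measurements": len(df),
        "accuracy_calibration_pct": (
            detection_accuracy(df, Mode.CALIBRATION) if has_cal else float("nan")
        ),
        "accuracy_runtime_pct": (
            detection_accuracy(df, Mode.RUNTIME) if has_run else float("nan")
        ),
        "tp_pct": pct["TP"], "tn_pct": pct["TN"],
        "fp_pct": pct["FP"], "fn_pct": pct["FN"],
        "visibility_rate_pct": (visibility_rate(df, visibility_min_overlap)
                                if has_run else float("nan")),
        "time_calibration_pct": cal_frac,
        "time_runtime_pct": run_frac,
        "n_mislocalized": int(df["mislocalized"].sum()),
    }
    return pd.DataFrame([out])
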