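"""Derived spirometry, analysis-group classification, and FEV1 slopes.

The analysis groups follow the borderline-obstruction design: among
subjects with normal post-bronchodilator FEV1,

* ``discordant``           ever-smokers with LLN < FEV1/FVC < 0.70
* ``smoker_normal``        ever-smokers with FEV1/FVC > 0.70 (and >= LLN)
* ``neversmoker_normal``   never-smokers with FEV1/FVC > 0.70 (and >= LLN)
* ``below_lln_top_quartile``  assigned only at cohort level: the least
  obstructed quartile of subjects whose ratio falls below their LLN
* ``other``                everything else

"Normal FEV1" defaults to post-bronchodilator FEV1 >= LLN(FEV1) from the
same reference equations; a percent-predicted rule (>= 80%) is available
as a configuration switch.  Boundary ties (ratio exactly 0.70 or exactly
the LLN) follow the strict inequalities of the group definitions and are
logged.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .nhanes3 import predicted_and_lln

__all__ = [
    "GROUP_LABELS",
    "percent_predicted",
    "classify_group",
    "derive_spirometry",
    "assign_groups",
    "annual_fev1_slope",
    "cohort_slopes",
]

log = logging.getLogger(__name__)

GROUP_LABELS = (
    "discordant",
    "smoker_normal",
    "neversmoker_normal",
    "below_lln_top_quartile",
    "other",
)

FIXED_RATIO_THRESHOLD = 0.70


def percent_predicted(measured: float, predicted: float) -> float:
    """100 x measured / predicted.  ``predicted`` must be positive."""
    predicted = np.asarray(predicted, dtype=float)
    if np.any(predicted <= 0):
        raise ValueError("predicted value must be positive")
    out = 100.0 * np.asarray(measured, dtype=float) / predicted
    return float(out) if out.ndim == 0 else out


def _normal_fev1(
    fev1: float,
    lln_fev1: float,
    fev1_pct_pred: float | None,
    rule: str,
) -> bool:
    if rule == "lln":
        return fev1 >= lln_fev1
    if rule == "pct80":
        if fev1_pct_pred is None:
            raise ValueError("pct80 rule requires fev1_pct_pred")
        return fev1_pct_pred >= 80.0
    raise ValueError(f"unknown normal-FEV1 rule {rule!r}")


def classify_group(
    ever_smoker: bool,
    ratio: float,
    lln_ratio: float,
    fev1: float,
    lln_fev1: float,
    *,
    fev1_pct_pred: float | None = None,
    normal_fev1_rule: str = "lln",
    require_ratio_above_lln_for_normal: bool = True,
) -> str:
    """Assign one analysis-group label from smoking history and spirometry.

    Ratio comparisons are strict on both sides; a ratio exactly at 0.70
    or exactly at the LLN therefore never qualifies for the discordant
    group (logged when it occurs).  ``below_lln_top_quartile`` requires
    cohort context and is assigned by :func:`assign_groups`.
    """
    if not (0.0 < ratio < 1.0) or not (0.0 < lln_ratio < 1.0):
        raise ValueError("ratio and lln_ratio must lie in (0, 1)")
    if ratio == FIXED_RATIO_THRESHOLD or ratio == lln_ratio:
        log.info(
            "ratio %.4f exactly at a classification boundary (lln=%.4f); "
            "strict inequalities applied",
            ratio,
            lln_ratio,
        )
    normal_fev1 = _normal_fev1(fev1, lln_fev1, fev1_pct_pred, normal_fev1_rule)
    if not normal_fev1:
        return "other"
    above_fixed = ratio > FIXED_RATIO_THRESHOLD
    above_lln = ratio > lln_ratio
    if ever_smoker and above_lln and ratio < FIXED_RATIO_THRESHOLD:
        return "discordant"
    unobstructed = above_fixed and (ratio >= lln_ratio or not require_ratio_above_lln_for_normal)
    if unobstructed:
        return "smoker_normal" if ever_smoker else "neversmoker_normal"
    return "other"


def derive_spirometry(
    subjects: pd.DataFrame,
    *,
    race_fallback: str | None = "caucasian",
) -> pd.DataFrame:
    """Append predicted / LLN / percent-predicted columns to a subject table.

    Expects columns ``age, sex, race, height_cm, fev1_l, fvc_l`` and
    optionally ``fef2575_ls``.  Returns a copy with ``ratio``,
    ``pred_fev1``, ``lln_fev1``, ``fev1_pct_pred``, ``pred_fvc``,
    ``lln_fvc``, ``lln_ratio``, ``pred_ratio`` and (when flow is present)
    ``pred_fef2575``, ``fef2575_pct_pred`` appended.
    """
    out = subjects.copy()
    n = len(out)
    cols = {
        k: np.empty(n)
        for k in (
            "pred_fev1",
            "lln_fev1",
            "pred_fvc",
            "lln_fvc",
            "pred_ratio",
            "lln_ratio",
            "pred_fef2575",
        )
    }
    for i, row in enumerate(out.itertuples(index=False)):
        args = (row.age, row.sex, row.race, row.height_cm)
        cols["pred_fev1"][i], cols["lln_fev1"][i] = predicted_and_lln(
            *args, "FEV1", race_fallback=race_fallback
        )
        cols["pred_fvc"][i], cols["lln_fvc"][i] = predicted_and_lln(
            *args, "FVC", race_fallback=race_fallback
        )
        cols["pred_ratio"][i], cols["lln_ratio"][i] = predicted_and_lln(
            *args, "FEV1/FVC", race_fallback=race_fallback
        )
        cols["pred_fef2575"][i], _ = predicted_and_lln(
            *args, "FEF25-75", race_fallback=race_fallback
        )
    for k, v in cols.items():
        out[k] = v
    out["ratio"] = out["fev1_l"] / out["fvc_l"]
    out["fev1_pct_pred"] = percent_predicted(out["fev1_l"], out["pred_fev1"])
    if "fef2575_ls" in out.columns:
        out["fef2575_pct_pred"] = percent_predicted(
            out["fef2575_ls"], out["pred_fef2575"]
        )
    return out


def assign_groups(
    derived: pd.DataFrame,
    *,
    normal_fev1_rule: str = "lln",
    group4_mode: str | None = "top_quartile",
) -> pd.Series:
    """Cohort-level group assignment, including the below-LLN quartile group.

    ``group4_mode`` selects how "the least-obstructed quartile of subjects
    below their LLN" is read: ``"top_quartile"`` labels ratios strictly
    above the within-stratum 75th percentile, ``"cutpoint"`` labels
    ratios at or above that percentile value, ``None`` skips group 4.
    """
    labels = pd.Series(
        [
            classify_group(
                bool(r.ever_smoker),
                float(r.ratio),
                float(r.lln_ratio),
                float(r.fev1_l),
                float(r.lln_fev1),
                fev1_pct_pred=float(r.fev1_pct_pred),
                normal_fev1_rule=normal_fev1_rule,
            )
            for r in derived.itertuples(index=False)
        ],
        index=derived.index,
        name="group",
    )
    if group4_mode is not None:
        below = derived["ratio"] < derived["lln_ratio"]
        if below.any():
            q3 = derived.loc[below, "ratio"].quantile(0.75)
            if group4_mode == "top_quartile":
                sel = below & (derived["ratio"] > q3)
            elif group4_mode == "cutpoint":
                sel = below & (derived["ratio"] >= q3)
            else:
                raise ValueError(f"unknown group4_mode {group4_mode!r}")
            labels[sel] = "below_lln_top_quartile"
    return labels


def annual_fev1_slope(
    visit_days: Sequence[float],
    fev1_l: Sequence[float],
    *,
    min_span_days: float = 200.0,
) -> float:
    """OLS slope of FEV1 (ml) on time (years) across a subject's visits.

    Requires at least two visits spanning ``min_span_days`` or more; a
    violation raises ``ValueError`` so the caller can exclude the subject
    with a logged reason.  Years are days / 365.25.
    """
    days = np.asarray(visit_days, dtype=float)
    fev1 = np.asarray(fev1_l, dtype=float)
    if days.shape != fev1.shape or days.ndim != 1:
        raise ValueError("visit_days and fev1_l must be 1-D and equal length")
    if len(days) < 2:
        raise ValueError("at least two spirometry visits are required")
    span = days.max() - days.min()
    if span < min_span_days:
        raise ValueError(
            f"visit span {span:g} days is below the required {min_span_days:g}"
        )
    years = days / 365.25
    ml = fev1 * 1000.0
    slope, _ = np.polyfit(years, ml, 1)
    return float(slope)


def cohort_slopes(
    visits: pd.DataFrame,
    *,
    subject_col: str = "subject_id",
    day_col: str = "visit_day",
    fev1_col: str = "fev1_l",
    min_span_days: float = 200.0,
) -> pd.Series:
    """Per-subject annual FEV1 slope (ml/year) from a long visit table.

    Subjects failing the two-visit / minimum-span precondition are
    excluded with a logged reason and appear as NaN.
    """
    slopes = {}
    for sid, grp in visits.groupby(subject_col, sort=False):
        try:
            slopes[sid] = annual_fev1_slope(
                grp[day_col], grp[fev1_col], min_span_days=min_span_days
            )
        except ValueError as exc:
            log.info("subject %s excluded from slope analysis: %s", sid, exc)
            slopes[sid] = np.nan
    return pd.Series(slopes, name="fev1_slope_ml_per_year")
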