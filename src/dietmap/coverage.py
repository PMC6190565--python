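"""Coverage aggregation: per-subject-day ratios and food-group summaries.

The central quantities are, per subject per survey day,

    freq_ratio   = sum(1 - coverage_fraction) / number of eating occasions
    amount_ratio = sum(amount_g * (1 - coverage_fraction)) / total grams

i.e. the share of habitual consumption (by count and by weight) that the
questionnaire fails to capture. Days are treated as independent.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AggregateSummary, ValidationError

COVERAGE_COLUMNS = (
    "subject_id", "day_index", "weekday", "total_freq", "noncov_freq",
    "total_amount_g", "noncov_amount_g", "freq_ratio", "amount_ratio",
    "amount_ratio_missing",
)


def daily_coverage_ratios(augmented: pd.DataFrame) -> pd.DataFrame:
    """One row per (subject, day) with non-covered frequency/amount ratios.

    A zero-intake day (total grams 0) has no defined amount ratio; the row
    is kept with ``amount_ratio`` missing and flagged, never dropped.
    """
    if augmented.empty:
        raise ValidationError("augmented database is empty")
    if (augmented["amount_g"] < 0).any():
        raise ValidationError("negative amount_g in augmented database")

    df = augmented.copy()
    df["noncov_w"] = 1.0 - df["coverage_fraction"]
    df["noncov_g"] = df["amount_g"] * df["noncov_w"]
    g = df.groupby(["subject_id", "day_index"], sort=True)
    out = g.agg(
        weekday=("weekday", "first"),
        total_freq=("food_code", "size"),
        noncov_freq=("noncov_w", "sum"),
        total_amount_g=("amount_g", "sum"),
        noncov_amount_g=("noncov_g", "sum"),
    ).reset_index()
    out["freq_ratio"] = out["noncov_freq"] / out["total_freq"]
    zero = out["total_amount_g"] == 0
    out["amount_ratio"] = np.where(zero, np.nan, out["noncov_amount_g"] / out["total_amount_g"])
    out["amount_ratio_missing"] = zero
    return out[list(COVERAGE_COLUMNS)]


def aggregate_summary(values: Sequence[float]) -> AggregateSummary:
    """Mean, IQR (linear interpolation), extrema, sample SD and SEM."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    q25, q75 = np.percentile(x, [25, 75])
    if x.size >= 2:
        sd = float(np.std(x, ddof=1))
        sem = sd / np.sqrt(x.size)
    else:
        sd = sem = None
    return AggregateSummary(
        n=int(x.size), mean=float(np.mean(x)), sd=sd, sem=sem,
        q25=float(q25), q75=float(q75), min=float(np.min(x)), max=float(np.max(x)),
    )


def mean_daily_intake(
    augmented: pd.DataFrame,
    food_group: str,
    n_days: int,
    consumers_only: bool = False,
) -> tuple[pd.Series, float, Optional[float]]:
    """Grams/day of one catalogue food group, per subject and sample mean.

    A subject's value is the group's total grams over the survey divided by
    ``n_days`` (absent days count as zero). ``consumers_only`` restricts
    the sample mean/SD to subjects who consumed the group at least once.
    """
    if food_group not in set(augmented["food_group"]):
        raise ValidationError(f"unknown food group: {food_group!r}")
    sub = augmented[augmented["food_group"] == food_group]
    per_subject = sub.groupby("subject_id")["amount_g"].sum() / n_days
    if not consumers_only:
        all_subjects = augmented["subject_id"].unique()
        per_subject = per_subject.reindex(all_subjects, fill_value=0.0).sort_index()
    per_subject.name = "g_per_day"
    sd = float(per_subject.std(ddof=1)) if len(per_subject) >= 2 else None
    return per_subject, float(per_subject.mean()), sd


def consumption_frequency(
    augmented: pd.DataFrame, food: str, n_days: int, by: str = "food_code"
) -> tuple[pd.Series, float]:
    """Appearances per day of a food code (or group): count / n_days."""
    if by not in ("food_code", "food_group"):
        raise ValidationError("by must be 'food_code' or 'food_group'")
    sub = augmented[augmented[by] == food]
    all_subjects = augmented["subject_id"].unique()
    per_subject = (
        sub.groupby("subject_id").size().reindex(all_subjects, fill_value=0).sort_index() / n_days
    )
    per_subject.name = "per_day"
    sample_wide = len(sub) / n_days
    return per_subject, sample_wide


def group_noncovered_report(
    augmented: pd.DataFrame, n_days: int, consumers_only: bool = True
) -> pd.DataFrame:
    """Per catalogue food group: EO count, mean amount (g/day), SD, % non-covered.

    Rows sorted by eating-occasion count descending; only groups with a
    positive non-covered share appear (a fully covered group does not
    belong in a non-covered-items table). Mean amount is per consuming
    subject per day by default, pairing naturally with the EO counts.
    """
    if augmented.empty:
        raise ValidationError("augmented database is empty")
    rows = []
    for grp, sub in augmented.groupby("food_group", sort=True):
        noncov_w = 1.0 - sub["coverage_fraction"]
        pct_noncov = 100.0 * noncov_w.sum() / len(sub)
        if pct_noncov <= 0:
            continue
        per_subject, mean_gpd, sd_gpd = mean_daily_intake(
            augmented, grp, n_days, consumers_only=consumers_only
        )
        rows.append(
            {
                "food_group": grp,
                "eo_count": len(sub),
                "mean_amount_g_per_day": mean_gpd,
                "sd_amount_g_per_day": sd_gpd,
                "pct_noncovered": pct_noncov,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "food_group", "eo_count", "mean_amount_g_per_day",
            "sd_amount_g_per_day", "pct_noncovered",
        ],
    )
    return out.sort_values(
        ["eo_count", "food_group"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def pooled_coverage_ratios(augmented: pd.DataFrame) -> tuple[float, float]:
    """Pooled (whole-sample) non-covered fractions, by count and by grams.

    Distinct from averaging per-subject-day ratios: pooling divides the
    grand totals instead, which weights heavy days more. Exposed for
    comparison; the subject-day average is the headline definition.
    """
    noncov_w = 1.0 - augmented["coverage_fraction"]
    freq = float(noncov_w.sum() / len(augmented))
    total_g = float(augmented["amount_g"].sum())
    amount = float((augmented["amount_g"] * noncov_w).sum() / total_g) if total_g > 0 else float("nan")
    return freq, amount
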