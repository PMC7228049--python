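"""Longitudinal aggregation and group statistics on ROI marker tables.

Each subject contributes 18 serial scans (6 pre-injection, 12 post).  The
pre/post summary averages the 6 first and the 6 last scans per subject, ROI
and marker; the time course partitions the 18 scans in acquisition order
into six consecutive triples (15-minute resolution).  Before group-level
time-course averaging, a single-pass z-score filter (|z| > 3 against the
group's mean and SD at that time point) excludes outlying subjects.

Statistics: paired two-sided t-tests pre vs post within each group, Welch
two-sample tests between groups for the pre and post window means
(Holm-corrected within each marker's comparison family) and uncorrected
Welch tests per time point.  Degenerate cases (single subject, zero
variance) are reported as not-computable (NaN) rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import TimecourseError

__all__ = [
    "PrePostSummary",
    "TimeCourse",
    "StatsReport",
    "prepost_average",
    "build_timecourse",
    "exclude_outliers",
    "run_stats",
    "MARKERS",
]

logger = logging.getLogger(__name__)

MARKERS = ("sindex", "sadc")


@dataclass(frozen=True)
class PrePostSummary:
    """Per-subject pre/post window means and per-group paired statistics.

    ``per_subject`` columns: subject_id, group, roi, marker, pre, post.
    ``per_group`` columns: group, roi, marker, n, pre_mean, post_mean,
    mean_change, pct_change, t, p.
    """

    per_subject: pd.DataFrame
    per_group: pd.DataFrame
    excluded_subjects: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TimeCourse:
    """Triple-averaged marker values per subject, ROI, marker, time point.

    ``values`` columns: subject_id, group, roi, marker, time_point (1..6),
    time_min (center of the triple), value, excluded (bool, from the
    z-score filter applied across subjects at each time point).
    """

    values: pd.DataFrame
    n_time_points: int = 6


@dataclass(frozen=True)
class StatsReport:
    """Assembled test results.

    ``paired``: paired pre/post t-tests per (group, roi, marker).
    ``between``: Welch tests vehicle vs tgn020 for the pre and post window
    means, with Holm-corrected p-values within each marker family.
    ``per_timepoint``: uncorrected Welch tests per (roi, marker, time point).
    """

    paired: pd.DataFrame
    between: pd.DataFrame
    per_timepoint: pd.DataFrame
    posthoc_method: str = "holm"
    excluded_log: pd.DataFrame | None = None


def _window_means(sub: pd.DataFrame, n_window: int = 6):
    """Pre = first ``n_window`` scans, post = last ``n_window`` scans.

    Selection is order-based on scan_index, never timestamp-interpolated.
    Returns None if either window is incomplete.
    """
    sub = sub.sort_values("scan_index")
    pre = sub[sub["time_min"] < 0]
    post = sub[sub["time_min"] >= 0]
    if len(pre) < n_window or len(post) < n_window:
        return None
    return (
        pre.iloc[:n_window],
        post.iloc[-n_window:],
    )


def prepost_average(table: pd.DataFrame, n_window: int = 6) -> PrePostSummary:
    """Average the 6 first and 6 last scans per subject/ROI/marker and test.

    Subjects with an incomplete pre or post window are excluded and logged.
    The group-level paired t-test is two-sided; with fewer than two subjects
    or zero variance the p-value is reported as NaN.
    """
    subj_rows = []
    excluded: list[str] = []
    for (sid, roi), sub in table.groupby(["subject_id", "roi"], sort=True):
        windows = _window_means(sub, n_window)
        if windows is None:
            if sid not in excluded:
                excluded.append(sid)
                logger.warning(
                    "subject %s excluded from pre/post summary "
                    "(incomplete window)",
                    sid,
                )
            continue
        pre, post = windows
        for marker in MARKERS:
            subj_rows.append(
                {
                    "subject_id": sid,
                    "group": sub["group"].iloc[0],
                    "roi": roi,
                    "marker": marker,
                    "pre": pre[marker].mean(),
                    "post": post[marker].mean(),
                }
            )
    per_subject = pd.DataFrame(
        subj_rows,
        columns=["subject_id", "group", "roi", "marker", "pre", "post"],
    )

    group_rows = []
    for (group, roi, marker), sub in per_subject.groupby(
        ["group", "roi", "marker"], sort=True
    ):
        pre = sub["pre"].to_numpy()
        post = sub["post"].to_numpy()
        if len(sub) >= 2 and np.std(post - pre) > 0:
            t, p = stats.ttest_rel(post, pre)
        else:
            t, p = np.nan, np.nan
        group_rows.append(
            {
                "group": group,
                "roi": roi,
                "marker": marker,
                "n": len(sub),
                "pre_mean": pre.mean(),
                "post_mean": post.mean(),
                "mean_change": (post - pre).mean(),
                "pct_change": float(
                    np.mean((post - pre) / pre) * 100.0
                ),
                "t": float(t),
                "p": float(p),
            }
        )
    per_group = pd.DataFrame(
        group_rows,
        columns=[
            "group",
            "roi",
            "marker",
            "n",
            "pre_mean",
            "post_mean",
            "mean_change",
            "pct_change",
            "t",
            "p",
        ],
    )
    return PrePostSummary(
        per_subject=per_subject,
        per_group=per_group,
        excluded_subjects=excluded,
    )


def build_timecourse(
    table: pd.DataFrame,
    scans_per_point: int = 3,
    drop_trailing: bool = False,
) -> TimeCourse:
    """Average consecutive scan triples into time points per subject/ROI.

    Scans are taken in acquisition (scan_index) order; each time point is
    the mean of ``scans_per_point`` consecutive scans and is stamped with
    the mean of their acquisition times.  A scan count that is not a
    multiple of ``scans_per_point`` raises unless ``drop_trailing``.
    """
    rows = []
    for (sid, roi), sub in table.groupby(["subject_id", "roi"], sort=True):
        sub = sub.sort_values("scan_index")
        n = len(sub)
        n_points, rem = divmod(n, scans_per_point)
        if rem:
            if not drop_trailing:
                raise TimecourseError(
                    f"subject {sid}: {n} scans not divisible into triples "
                    f"of {scans_per_point}"
                )
            logger.warning(
                "subject %s: dropping %d trailing scan(s)", sid, rem
            )
            sub = sub.iloc[: n_points * scans_per_point]
        for tp in range(n_points):
            chunk = sub.iloc[tp * scans_per_point : (tp + 1) * scans_per_point]
            for marker in MARKERS:
                rows.append(
                    {
                        "subject_id": sid,
                        "group": sub["group"].iloc[0],
                        "roi": roi,
                        "marker": marker,
                        "time_point": tp + 1,
                        "time_min": chunk["time_min"].mean(),
                        "value": chunk[marker].mean(),
                        "excluded": False,
                    }
                )
    values = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "roi",
            "marker",
            "time_point",
            "time_min",
            "value",
            "excluded",
        ],
    )
    n_points = int(values["time_point"].max()) if len(values) else 0
    return TimeCourse(values=values, n_time_points=n_points)


def exclude_outliers(
    values: np.ndarray, z_cutoff: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass |z| filter over one group's values at one time point.

    z is computed against the sample mean and SD with every candidate
    included (no re-iteration).  Zero SD means z is undefined and nothing
    is excluded; fewer than 3 values skips the filter with a warning.
    Returns (retained values, boolean exclusion flags).
    """
    values = np.asarray(values, dtype=float)
    flags = np.zeros(values.shape, dtype=bool)
    if values.size < 3:
        logger.warning(
            "z-score filter skipped: only %d value(s)", values.size
        )
        return values, flags
    sd = values.std(ddof=1)
    if sd == 0:
        return values, flags
    z = (values - values.mean()) / sd
    flags = np.abs(z) > z_cutoff
    return values[~flags], flags


def _apply_timecourse_filter(course: TimeCourse, z_cutoff: float) -> TimeCourse:
    """Flag outlying subjects per (group, roi, marker, time point)."""
    df = course.values.copy()
    for key, sub in df.groupby(
        ["group", "roi", "marker", "time_point"], sort=False
    ):
        _, flags = exclude_outliers(sub["value"].to_numpy(), z_cutoff)
        if flags.any():
            df.loc[sub.index[flags], "excluded"] = True
    return TimeCourse(values=df, n_time_points=course.n_time_points)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2 or (np.std(a) == 0 and np.std(b) == 0):
        return np.nan, np.nan
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def run_stats(
    summary: PrePostSummary,
    course: TimeCourse,
    posthoc_method: str = "holm",
    z_cutoff: float = 3.0,
    groups: tuple[str, str] = ("vehicle", "tgn020"),
) -> StatsReport:
    """Assemble the full statistical report.

    (a) the paired pre/post tests come straight from ``summary``;
    (b) between-group Welch tests on the pre and the post window means,
    corrected with ``posthoc_method`` within each marker's family
    (family = {pre, post} × ROIs for that marker);
    (c) per-time-point Welch tests on the outlier-filtered time course,
    uncorrected.
    """
    paired = summary.per_group.copy()

    # (b) between-group window tests
    rows = []
    ps = summary.per_subject
    for marker in MARKERS:
        for window in ("pre", "post"):
            for roi in sorted(ps["roi"].unique()):
                sel = ps[(ps["marker"] == marker) & (ps["roi"] == roi)]
                a = sel[sel["group"] == groups[0]][window].to_numpy()
                b = sel[sel["group"] == groups[1]][window].to_numpy()
                t, p = _welch(a, b)
                rows.append(
                    {
                        "marker": marker,
                        "window": window,
                        "roi": roi,
                        "n_0": len(a),
                        "n_1": len(b),
                        "t": t,
                        "p_raw": p,
                    }
                )
    between = pd.DataFrame(
        rows, columns=["marker", "window", "roi", "n_0", "n_1", "t", "p_raw"]
    )
    between["p_corr"] = np.nan
    for marker in MARKERS:
        fam = between.index[
            (between["marker"] == marker) & between["p_raw"].notna()
        ]
        if len(fam) == 1:
            between.loc[fam, "p_corr"] = between.loc[fam, "p_raw"]
        elif len(fam) > 1:
            _, corr, _, _ = multipletests(
                between.loc[fam, "p_raw"].to_numpy(), method=posthoc_method
            )
            between.loc[fam, "p_corr"] = corr
    between["method"] = posthoc_method

    # (c) per-time-point tests on the filtered course
    filtered = _apply_timecourse_filter(course, z_cutoff)
    tp_rows = []
    tv = filtered.values
    for (roi, marker, tp), sub in tv.groupby(
        ["roi", "marker", "time_point"], sort=True
    ):
        kept = sub[~sub["excluded"]]
        a = kept[kept["group"] == groups[0]]["value"].to_numpy()
        b = kept[kept["group"] == groups[1]]["value"].to_numpy()
        t, p = _welch(a, b)
        tp_rows.append(
            {
                "roi": roi,
                "marker": marker,
                "time_point": tp,
                "time_min": sub["time_min"].mean(),
                "n_0": len(a),
                "n_1": len(b),
                "n_excluded": int(sub["excluded"].sum()),
                "t": t,
                "p": p,
            }
        )
    per_timepoint = pd.DataFrame(
        tp_rows,
        columns=[
            "roi",
            "marker",
            "time_point",
            "time_min",
            "n_0",
            "n_1",
            "n_excluded",
            "t",
            "p",
        ],
    )
    excluded_log = tv[tv["excluded"]][
        ["subject_id", "group", "roi", "marker", "time_point", "value"]
    ].reset_index(drop=True)
    return StatsReport(
        paired=paired,
        between=between,
        per_timepoint=per_timepoint,
        posthoc_method=posthoc_method,
        excluded_log=excluded_log,
    )
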