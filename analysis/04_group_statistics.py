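#!/usr/bin/env python
"""Pre/post summaries, time courses and group statistics of the markers.

Reads results/roi_markers.csv, averages the 6 first and 6 last scans per
subject, builds the six 15-minute time points with the z-score outlier
filter, and runs the paired, between-group (Holm-corrected) and
per-time-point tests.  Writes the statistical tables under results/ and a
time-course figure under scratch/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from dwimarkers.cohort import build_timecourse, prepost_average, run_stats

ROOT = Path(__file__).resolve().parents[1]


def plot_timecourse(values: pd.DataFrame, path: Path) -> None:
    rois = sorted(values["roi"].unique())
    fig, axes = plt.subplots(2, len(rois), figsize=(4 * len(rois), 6),
                             sharex=True)
    for j, roi in enumerate(rois):
        for i, marker in enumerate(("sindex", "sadc")):
            ax = axes[i, j]
            sel = values[(values["roi"] == roi)
                         & (values["marker"] == marker)
                         & ~values["excluded"]]
            for group, color in (("vehicle", "tab:blue"),
                                 ("tgn020", "tab:orange")):
                g = sel[sel["group"] == group].groupby("time_min")["value"]
                ax.errorbar(g.mean().index, g.mean(), yerr=g.std(),
                            label=group, color=color, capsize=2)
            ax.axvline(0, ls="--", c="k", lw=0.8)
            ax.set_title(f"{roi} — {marker}")
            if i == 1:
                ax.set_xlabel("time (min)")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--markers", type=Path,
                    default=ROOT / "results" / "roi_markers.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    table = pd.read_csv(args.markers)
    summary = prepost_average(table)
    course = build_timecourse(table)
    report = run_stats(summary, course)

    args.out.mkdir(parents=True, exist_ok=True)
    summary.per_subject.to_csv(args.out / "prepost_per_subject.csv", index=False)
    report.paired.to_csv(args.out / "prepost_paired_tests.csv", index=False)
    report.between.to_csv(args.out / "between_group_tests.csv", index=False)
    report.per_timepoint.to_csv(args.out / "per_timepoint_tests.csv", index=False)
    course.values.to_csv(args.out / "timecourse.csv", index=False)
    (ROOT / "scratch").mkdir(exist_ok=True)
    plot_timecourse(course.values, ROOT / "scratch" / "timecourse.png")

    print("paired pre/post tests (per group, ROI, marker):")
    cols = ["group", "roi", "marker", "pct_change", "p"]
    print(report.paired[cols].to_string(
        index=False, float_format=lambda v: f"{v:.4g}"))
    sig = report.paired[report.paired["p"] < 0.05]
    print(
        f"\nsignificant paired changes: "
        f"{[f'{r.group}/{r.roi}/{r.marker}' for r in sig.itertuples()]}"
    )


if __name__ == "__main__":
    main()
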