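"""End-to-end orchestration: cohort → QC → ROI markers → statistics.

Two entry points cover the two ways a cohort exists: in memory (generated
by :mod:`~dwimarkers.phantom`, used by the test suite and calibration
studies) and on disk (the file layout :func:`~dwimarkers.phantom.simulate_cohort`
writes and :mod:`~dwimarkers.io` reads).  Both run the same stages:

1. per scan: direction averaging and b0 normalization;
2. per session: temporal stability QC, then whole-session discard if any
   flagged voxel falls inside an analysis ROI;
3. per scan × ROI: signal averaging and the two markers;
4. cohort level: pre/post windows, triple-averaged time course with the
   z-score outlier filter, and the group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import (
    PrePostSummary,
    StatsReport,
    TimeCourse,
    build_timecourse,
    prepost_average,
    run_stats,
)
from .io import (
    LabelVolume,
    StudyManifest,
    read_dwi,
    read_labels,
    read_manifest,
    read_scheme,
)
from .markers import roi_marker_table
from .phantom import PhantomSpec, iter_cohort, make_atlas
from .preprocess import (
    StabilityReport,
    apply_discard_rule,
    flag_unstable_voxels,
    normalize_and_average,
)
from .signature import SignatureLibrary, default_library

__all__ = ["CohortResult", "analyze_cohort", "analyze_cohort_dir", "ANALYSIS_ROIS"]

#: ROIs entering the group analysis (the study's three report regions).
ANALYSIS_ROIS = ("cortex", "striatum", "hippocampus")


@dataclass(frozen=True)
class CohortResult:
    """Everything the cohort analysis produces."""

    roi_table: pd.DataFrame
    summary: PrePostSummary
    timecourse: TimeCourse
    stats: StatsReport
    qc_reports: dict[str, StabilityReport]
    qc_log: pd.DataFrame
    n_subjects_analyzed: int


def _analyze_sessions(
    sessions,
    labels: LabelVolume,
    library: SignatureLibrary,
    roi_names,
    manifest: StudyManifest | None,
    qc_threshold_pct: float,
    qc_fwhm_vox: float,
    run_qc: bool,
    posthoc_method: str,
    z_cutoff: float,
) -> CohortResult:
    """Common second half of both entry points.

    ``sessions`` yields (subject_id, group, list-of-ShellSignalMaps).
    """
    qc_reports: dict[str, StabilityReport] = {}
    tables = []
    rows_for_manifest = []
    for sid, group, shell_maps in sessions:
        if run_qc:
            qc_reports[sid] = flag_unstable_voxels(
                shell_maps,
                threshold_pct=qc_threshold_pct,
                smoothing_fwhm_vox=qc_fwhm_vox,
            )
        tables.append(
            roi_marker_table(shell_maps, labels, library, roi_names, group)
        )
        for m in shell_maps:
            rows_for_manifest.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "scan_index": m.scan_index,
                    "path": "",
                    "time_min": m.acquisition_time,
                }
            )
    roi_table = pd.concat(tables, ignore_index=True)
    if manifest is None:
        manifest = StudyManifest(rows=pd.DataFrame(rows_for_manifest))
    if run_qc:
        manifest, qc_log = apply_discard_rule(
            qc_reports, labels, manifest, roi_names=roi_names
        )
        kept = set(manifest.rows["subject_id"].unique())
        roi_table = roi_table[roi_table["subject_id"].isin(kept)].reset_index(
            drop=True
        )
    else:
        qc_log = pd.DataFrame(columns=["subject_id", "roi", "n_flagged"])
    summary = prepost_average(roi_table)
    course = build_timecourse(roi_table)
    stats = run_stats(
        summary, course, posthoc_method=posthoc_method, z_cutoff=z_cutoff
    )
    return CohortResult(
        roi_table=roi_table,
        summary=summary,
        timecourse=course,
        stats=stats,
        qc_reports=qc_reports,
        qc_log=qc_log,
        n_subjects_analyzed=len(manifest.subjects) if len(manifest.rows) else 0,
    )


def analyze_cohort(
    spec: PhantomSpec,
    n_per_group: int = 16,
    master_seed: int | None = None,
    library: SignatureLibrary | None = None,
    roi_names=ANALYSIS_ROIS,
    qc_threshold_pct: float = 4.0,
    qc_fwhm_vox: float = 1.0,
    run_qc: bool = True,
    posthoc_method: str = "holm",
    z_cutoff: float = 3.0,
) -> CohortResult:
    """Simulate a phantom cohort in memory and run the full analysis."""
    if library is None:
        library = default_library()
    labels = make_atlas(spec)

    def sessions():
        for sid, group, scans, _, _ in iter_cohort(
            spec, n_per_group, master_seed
        ):
            yield sid, group, [normalize_and_average(s) for s in scans]

    return _analyze_sessions(
        sessions(),
        labels,
        library,
        roi_names,
        None,
        qc_threshold_pct,
        qc_fwhm_vox,
        run_qc,
        posthoc_method,
        z_cutoff,
    )


def analyze_cohort_dir(
    cohort_dir,
    library: SignatureLibrary | None = None,
    roi_names=ANALYSIS_ROIS,
    qc_threshold_pct: float = 4.0,
    qc_fwhm_vox: float = 1.0,
    run_qc: bool = True,
    posthoc_method: str = "holm",
    z_cutoff: float = 3.0,
    key_low_b: float = 250.0,
    key_high_b: float = 1750.0,
) -> CohortResult:
    """Run the full analysis on a cohort directory written by the simulator
    (or assembled by hand in the same layout)."""
    if library is None:
        library = default_library()
    root = Path(cohort_dir)
    scheme = read_scheme(
        root / "cohort.bval",
        root / "cohort.bvec",
        key_low_b=key_low_b,
        key_high_b=key_high_b,
    )
    labels = read_labels(root / "labels.nii", root / "labels.json")
    manifest = read_manifest(root / "manifest.csv")

    def sessions():
        for sid in manifest.subjects:
            sub = manifest.for_subject(sid).sort_values("scan_index")
            maps = []
            for _, row in sub.iterrows():
                scan = read_dwi(
                    root / row["path"],
                    scheme,
                    subject_id=sid,
                    scan_index=int(row["scan_index"]),
                    acquisition_time=float(row["time_min"]),
                )
                maps.append(normalize_and_average(scan))
            yield sid, manifest.group_of(sid), maps

    return _analyze_sessions(
        sessions(),
        labels,
        library,
        roi_names,
        manifest,
        qc_threshold_pct,
        qc_fwhm_vox,
        run_qc,
        posthoc_method,
        z_cutoff,
    )
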