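"""Direction averaging, b0 normalization and the voxel-stability filter.

A scan is reduced to three shell maps: the mean b≈0 intensity ``s0`` and the
direction-averaged signals at the two key shells, both raw and normalized by
``s0``.  The stability filter evaluates, per shell, the temporal coefficient
of variation of the (spatially smoothed) raw shell intensity across the
scans of a session and flags voxels whose CV exceeds a percentage threshold
in any shell.  Raw rather than normalized intensities are used because
scan-level instabilities (motion, drift) scale all volumes of a scan
together and would cancel exactly under b0 normalization.

Sessions whose flagged voxels intersect an analysis ROI are discarded
wholesale: the temporal CV is a session-level statistic, so the discard unit
is the subject session (per-scan discard is offered as a config option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ShapeMismatchError
from .io import DwiSeries, LabelVolume, StudyManifest

__all__ = [
    "ShellSignalMaps",
    "StabilityReport",
    "normalize_and_average",
    "flag_unstable_voxels",
    "apply_discard_rule",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Shells entering the stability filter, in reporting order.
_QC_SHELLS = ("b0", "lb", "hb")


@dataclass(frozen=True)
class ShellSignalMaps:
    """Per-scan shell maps: s0, raw shell means, and normalized signals.

    ``s_lb``/``s_hb`` are the direction-averaged signals divided by ``s0``
    (dimensionless, defined only where ``mask`` is true); ``raw_lb``/
    ``raw_hb`` are the un-normalized direction means used by the stability
    filter.
    """

    s0: np.ndarray
    raw_lb: np.ndarray
    raw_hb: np.ndarray
    s_lb: np.ndarray
    s_hb: np.ndarray
    mask: np.ndarray
    scan_index: int = 0
    subject_id: str = ""
    acquisition_time: float = 0.0

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.s0.shape


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the temporal stability filter for one session.

    ``cv_pct`` maps shell name → per-voxel temporal CV in percent;
    ``flagged`` is true where CV exceeded the threshold in at least one
    shell; ``degenerate`` marks voxels with non-positive temporal mean
    (flagged and noted).  ``discarded`` is filled by
    :func:`apply_discard_rule`.
    """

    flagged: np.ndarray
    cv_pct: dict[str, np.ndarray]
    threshold_pct: float
    smoothing_fwhm_vox: float
    subject_id: str = ""
    degenerate: np.ndarray | None = None
    discarded: list[str] = field(default_factory=list)


def normalize_and_average(
    scan: DwiSeries, noise_floor: float = 1e-12
) -> ShellSignalMaps:
    """Collapse a scan to direction-averaged shell maps normalized by b0.

    Raw direction volumes are averaged first, then divided by the mean b≈0
    intensity (for arithmetic means this equals normalizing per direction
    and then averaging).  Voxels with ``s0`` at or below ``noise_floor`` are
    masked out rather than raising.
    """
    data = scan.intensities
    scheme = scan.scheme
    s0 = data[..., scheme.b0_indices].mean(axis=3)
    raw_lb = data[..., scheme.lb_indices].mean(axis=3)
    raw_hb = data[..., scheme.hb_indices].mean(axis=3)
    mask = np.isfinite(s0) & (s0 > noise_floor)
    if not mask.any():
        logger.warning(
            "scan %s/%d: all voxels at or below the noise floor; fully masked",
            scan.subject_id,
            scan.scan_index,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        s_lb = np.where(mask, raw_lb / np.where(mask, s0, 1.0), np.nan)
        s_hb = np.where(mask, raw_hb / np.where(mask, s0, 1.0), np.nan)
    return ShellSignalMaps(
        s0=s0,
        raw_lb=raw_lb,
        raw_hb=raw_hb,
        s_lb=s_lb,
        s_hb=s_hb,
        mask=mask,
        scan_index=scan.scan_index,
        subject_id=scan.subject_id,
        acquisition_time=scan.acquisition_time,
    )


def flag_unstable_voxels(
    session: list[ShellSignalMaps],
    threshold_pct: float = 4.0,
    smoothing_fwhm_vox: float = 1.0,
) -> StabilityReport:
    """Flag voxels whose temporal CV exceeds ``threshold_pct`` in any shell.

    For each shell (b0 mean, raw Lb mean, raw Hb mean) every scan's map is
    smoothed with an isotropic Gaussian of the given FWHM (in voxels), then
    the standard deviation across scans divided by the mean across scans is
    computed per voxel.  A voxel is flagged iff its CV is strictly greater
    than the threshold in at least one shell; voxels with non-positive
    temporal mean are flagged and marked degenerate.
    """
    if len(session) < 3:
        raise ShapeMismatchError(
            f"stability filter needs at least 3 scans, got {len(session)}"
        )
    shapes = {m.grid_shape for m in session}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"inconsistent grids in session: {shapes}")
    sigma = smoothing_fwhm_vox * FWHM_TO_SIGMA
    cv_pct: dict[str, np.ndarray] = {}
    flagged = np.zeros(session[0].grid_shape, dtype=bool)
    degenerate = np.zeros_like(flagged)
    for shell, attr in zip(_QC_SHELLS, ("s0", "raw_lb", "raw_hb")):
        stack = np.stack(
            [gaussian_filter(getattr(m, attr), sigma) for m in session]
        )
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        bad = mean <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(bad, np.inf, sd / np.where(bad, 1.0, mean) * 100.0)
        cv_pct[shell] = cv
        flagged |= cv > threshold_pct
        degenerate |= bad
    if degenerate.any():
        logger.warning(
            "%d voxels with non-positive temporal mean flagged as degenerate",
            int(degenerate.sum()),
        )
    return StabilityReport(
        flagged=flagged,
        cv_pct=cv_pct,
        threshold_pct=threshold_pct,
        smoothing_fwhm_vox=smoothing_fwhm_vox,
        subject_id=session[0].subject_id,
        degenerate=degenerate,
    )


def apply_discard_rule(
    reports: dict[str, StabilityReport],
    rois: LabelVolume,
    manifest: StudyManifest,
    roi_names: tuple[str, ...] | None = None,
) -> tuple[StudyManifest, pd.DataFrame]:
    """Drop subjects whose flagged voxels intersect any analysis ROI.

    ``reports`` maps subject_id → session stability report.  Returns the
    filtered manifest (whole sessions removed) and a log table with one row
    per removed subject (ROI hit and flagged-voxel count).  Flags confined
    to background never cause removal.  An empty result is allowed (with a
    warning).
    """
    if roi_names is None:
        roi_names = tuple(
            n for n in dict.fromkeys(rois.dictionary.values())
        )
    log_rows = []
    keep = []
    for sid in manifest.subjects:
        report = reports.get(sid)
        drop = False
        if report is not None:
            if report.flagged.shape != rois.labels.shape:
                raise ShapeMismatchError(
                    f"stability report grid {report.flagged.shape} does not "
                    f"match label grid {rois.labels.shape}"
                )
            for roi in roi_names:
                n_hit = int(report.flagged[rois.mask(roi)].sum())
                if n_hit > 0:
                    log_rows.append(
                        {"subject_id": sid, "roi": roi, "n_flagged": n_hit}
                    )
                    drop = True
        if not drop:
            keep.append(sid)
        else:
            logger.info("discarding subject %s (unstable voxels in ROI)", sid)
    log = pd.DataFrame(log_rows, columns=["subject_id", "roi", "n_flagged"])
    kept_rows = manifest.rows[manifest.rows["subject_id"].isin(keep)]
    if kept_rows.empty:
        logger.warning("discard rule removed every subject")
        filtered = StudyManifest.__new__(StudyManifest)
        object.__setattr__(filtered, "rows", kept_rows.reset_index(drop=True))
        object.__setattr__(
            filtered, "scans_per_subject", manifest.scans_per_subject
        )
        object.__setattr__(filtered, "n_pre", manifest.n_pre)
        return filtered, log
    return (
        StudyManifest(
            rows=kept_rows.reset_index(drop=True),
            scans_per_subject=manifest.scans_per_subject,
            n_pre=manifest.n_pre,
        ),
        log,
    )
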