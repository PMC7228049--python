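"""Readers, writers and validated domain containers for all external formats.

Volumes are NIfTI-1 (via nibabel); gradient tables use the whitespace row
dialect (one row of b-values, three rows of direction components, volumes as
columns); label dictionaries are two-column delimited text or JSON; manifests
and marker tables are delimited text with a header.  Every reader validates
into a typed container and raises a subclass of
:class:`~dwimarkers.errors.ValidationError` on malformed input.

Conventions fixed throughout the package: b in s/mm², diffusivities in mm²/s,
0-based voxel indices, spatial correspondence between data and labels asserted
by identical grid shape (inputs are assumed atlas-aligned upstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import LabelError, ManifestError, SchemeError, ShapeMismatchError

__all__ = [
    "AcquisitionScheme",
    "DwiSeries",
    "LabelVolume",
    "StudyManifest",
    "read_scheme",
    "write_scheme",
    "read_dwi",
    "write_dwi",
    "read_labels",
    "write_labels",
    "read_manifest",
    "write_manifest",
    "write_marker_map",
    "read_marker_map",
    "write_table",
    "read_table",
]

GROUPS = ("vehicle", "tgn020")

#: Default parent → children containment for composite ROIs.
ROI_HIERARCHY = {"hippocampus": ("CA3", "DG")}


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell acquisition: per-volume b-values/directions + key shells.

    Every volume must be assignable (within ``shell_tolerance``) to exactly
    one of the three shells b≈0, Lb, Hb; Lb < Hb; direction vectors at b > 0
    must be unit norm.  Directions at b=0 are stored as zero vectors and
    ignored.
    """

    bvalues: np.ndarray
    directions: np.ndarray
    key_low_b: float = 250.0
    key_high_b: float = 1750.0
    shell_tolerance: float = 25.0
    shell_of: np.ndarray = field(init=False, compare=False)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvalues, dtype=float).ravel()
        dirs = np.asarray(self.directions, dtype=float)
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "directions", dirs)
        if dirs.shape != (bvals.size, 3):
            raise SchemeError(
                f"directions shape {dirs.shape} does not match "
                f"{bvals.size} volumes"
            )
        if not (0 <= self.key_low_b < self.key_high_b):
            raise SchemeError("need 0 <= Lb < Hb")
        centers = np.array([0.0, self.key_low_b, self.key_high_b])
        dist = np.abs(bvals[:, None] - centers[None, :])
        within = dist <= self.shell_tolerance
        n_match = within.sum(axis=1)
        if np.any(n_match != 1):
            bad = bvals[n_match != 1]
            raise SchemeError(
                f"b-values {bad.tolist()} not assignable to exactly one of "
                f"the shells (0, {self.key_low_b}, {self.key_high_b}) within "
                f"tolerance {self.shell_tolerance}"
            )
        shell_of = np.argmax(within, axis=1)  # 0 = b0, 1 = Lb, 2 = Hb
        object.__setattr__(self, "shell_of", shell_of)
        for s, name in ((0, "b=0"), (1, "key low-b"), (2, "key high-b")):
            if not np.any(shell_of == s):
                raise SchemeError(f"key shell absent: no {name} volumes")
        norms = np.linalg.norm(dirs, axis=1)
        nonzero_b = shell_of > 0
        if np.any(np.abs(norms[nonzero_b] - 1.0) > 1e-6):
            raise SchemeError("direction vectors at b > 0 must have unit norm")

    def __len__(self) -> int:
        return self.bvalues.size

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.shell_of == 0)

    @property
    def lb_indices(self) -> np.ndarray:
        return np.flatnonzero(self.shell_of == 1)

    @property
    def hb_indices(self) -> np.ndarray:
        return np.flatnonzero(self.shell_of == 2)


@dataclass(frozen=True)
class DwiSeries:
    """One 4-D diffusion-weighted scan tied to a scheme and session slot.

    ``intensities`` is a non-negative finite array indexed (x, y, z, volume);
    ``scan_index`` is the 1-based position within the session and
    ``acquisition_time`` is in minutes relative to injection (negative = pre).
    """

    intensities: np.ndarray
    scheme: AcquisitionScheme
    subject_id: str = ""
    scan_index: int = 0
    acquisition_time: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 4:
            raise ShapeMismatchError(
                f"expected a 4-D volume, got shape {arr.shape}"
            )
        if arr.shape[3] != len(self.scheme):
            raise ShapeMismatchError(
                f"scan has {arr.shape[3]} volumes but scheme expects "
                f"{len(self.scheme)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ShapeMismatchError("scan contains non-finite voxels")
        if np.any(arr < 0):
            raise ShapeMismatchError("scan contains negative intensities")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]


@dataclass(frozen=True)
class LabelVolume:
    """Integer ROI labels on the data grid plus an id → name dictionary.

    0 is background.  Composite ROIs are expressed through ``hierarchy``
    (parent name → child ROI names); :meth:`mask` of a parent includes its
    children, so CA3/DG voxels are by construction subsets of hippocampus.
    """

    labels: np.ndarray
    dictionary: dict[int, str]
    hierarchy: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(ROI_HIERARCHY)
    )

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise LabelError("label grid contains non-integer values")
            labels = labels.astype(np.int32)
        object.__setattr__(self, "labels", labels)
        present = set(np.unique(labels).tolist()) - {0}
        unknown = present - set(self.dictionary)
        if unknown:
            raise LabelError(
                f"label ids {sorted(unknown)} present in grid but absent "
                "from the dictionary"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.dictionary.values())

    def _ids_for(self, roi: str) -> list[int]:
        ids = [i for i, n in self.dictionary.items() if n == roi]
        if not ids:
            raise LabelError(f"unknown ROI name {roi!r}")
        for child in self.hierarchy.get(roi, ()):
            ids += [i for i, n in self.dictionary.items() if n == child]
        return ids

    def mask(self, roi: str) -> np.ndarray:
        """Boolean voxel mask of ``roi`` (composite ROIs include children)."""
        return np.isin(self.labels, self._ids_for(roi))


@dataclass(frozen=True)
class StudyManifest:
    """Table of (subject_id, group, scan_index, path, time_min) rows.

    Each subject must contribute 18 rows of which exactly 6 are
    pre-injection (negative time); both groups must be non-empty when
    ``require_complete`` validation is on.
    """

    rows: pd.DataFrame
    scans_per_subject: int = 18
    n_pre: int = 6

    COLUMNS = ("subject_id", "group", "scan_index", "path", "time_min")

    def __post_init__(self) -> None:
        df = self.rows
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ManifestError(f"manifest missing columns {sorted(missing)}")
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ManifestError(f"unknown groups {sorted(bad_groups)}")
        if df.empty:
            raise ManifestError("manifest is empty")
        for sid, sub in df.groupby("subject_id"):
            if len(sub) != self.scans_per_subject:
                raise ManifestError(
                    f"subject {sid} has {len(sub)} rows, expected "
                    f"{self.scans_per_subject}"
                )
            if sub["scan_index"].duplicated().any():
                raise ManifestError(f"subject {sid} has duplicate scan indices")
            n_pre = int((sub["time_min"] < 0).sum())
            if n_pre != self.n_pre:
                raise ManifestError(
                    f"subject {sid} has {n_pre} pre-injection rows, "
                    f"expected {self.n_pre}"
                )
        object.__setattr__(
            self,
            "rows",
            df.sort_values(["subject_id", "scan_index"]).reset_index(drop=True),
        )

    @property
    def subjects(self) -> list[str]:
        return sorted(self.rows["subject_id"].unique().tolist())

    def for_subject(self, subject_id: str) -> pd.DataFrame:
        return self.rows[self.rows["subject_id"] == subject_id]

    def group_of(self, subject_id: str) -> str:
        return str(self.for_subject(subject_id)["group"].iloc[0])


# ---------------------------------------------------------------------------
# gradient tables


def read_scheme(
    bval_path,
    bvec_path,
    key_low_b: float = 250.0,
    key_high_b: float = 1750.0,
    shell_tolerance: float = 25.0,
) -> AcquisitionScheme:
    """Read an FSL-style row-dialect .bval/.bvec pair into a scheme."""
    try:
        bvals = np.loadtxt(bval_path, ndmin=2)
    except OSError as e:
        raise SchemeError(f"cannot read bval file {bval_path}: {e}") from e
    if bvals.shape[0] != 1:
        raise SchemeError(
            f"bval file must contain exactly one row, got {bvals.shape[0]}"
        )
    try:
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except OSError as e:
        raise SchemeError(f"cannot read bvec file {bvec_path}: {e}") from e
    if bvecs.shape[0] != 3:
        raise SchemeError(
            f"bvec file must contain exactly three rows, got {bvecs.shape[0]}"
        )
    if bvecs.shape[1] != bvals.shape[1]:
        raise SchemeError(
            f"bval row has {bvals.shape[1]} columns but bvec rows have "
            f"{bvecs.shape[1]}"
        )
    return AcquisitionScheme(
        bvalues=bvals[0],
        directions=bvecs.T,
        key_low_b=key_low_b,
        key_high_b=key_high_b,
        shell_tolerance=shell_tolerance,
    )


def write_scheme(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.17g")


# ---------------------------------------------------------------------------
# volumes


def read_dwi(
    path,
    scheme: AcquisitionScheme,
    subject_id: str = "",
    scan_index: int = 0,
    acquisition_time: float = 0.0,
) -> DwiSeries:
    """Load a 4-D NIfTI-1 scan and validate it against ``scheme``."""
    path = Path(path)
    if not path.exists():
        raise ShapeMismatchError(f"missing DWI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ShapeMismatchError(
            f"{path.name}: expected 4 dimensions, got {data.ndim}"
        )
    return DwiSeries(
        intensities=data,
        scheme=scheme,
        subject_id=subject_id,
        scan_index=scan_index,
        acquisition_time=acquisition_time,
    )


def write_dwi(series: DwiSeries, path) -> None:
    """Write a scan as float64 NIfTI-1 (lossless round-trip)."""
    img = nib.Nifti1Image(series.intensities.astype(np.float64), np.eye(4))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# labels


def read_labels(path, dict_path) -> LabelVolume:
    """Read an integer label volume plus its id → name dictionary.

    The dictionary is JSON ({"1": "cortex", ...}) when the file ends in
    .json, otherwise two-column whitespace-delimited text (id name).
    """
    path, dict_path = Path(path), Path(dict_path)
    if not path.exists():
        raise LabelError(f"missing label volume: {path}")
    if not dict_path.exists():
        raise LabelError(f"missing label dictionary: {dict_path}")
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if dict_path.suffix == ".json":
        raw = json.loads(dict_path.read_text())
        dictionary = {int(k): str(v) for k, v in raw.items()}
    else:
        dictionary = {}
        for ln, line in enumerate(dict_path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise LabelError(
                    f"{dict_path.name}:{ln}: expected 'id name', got {line!r}"
                )
            try:
                dictionary[int(parts[0])] = parts[1]
            except ValueError as e:
                raise LabelError(
                    f"{dict_path.name}:{ln}: malformed id {parts[0]!r}"
                ) from e
    return LabelVolume(labels=labels, dictionary=dictionary)


def write_labels(vol: LabelVolume, path, dict_path) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.int16), np.eye(4))
    nib.save(img, str(path))
    dict_path = Path(dict_path)
    if dict_path.suffix == ".json":
        dict_path.write_text(
            json.dumps({str(k): v for k, v in vol.dictionary.items()}, indent=1)
        )
    else:
        dict_path.write_text(
            "".join(f"{k} {v}\n" for k, v in sorted(vol.dictionary.items()))
        )


# ---------------------------------------------------------------------------
# manifests and tables


def read_manifest(path, scans_per_subject: int = 18, n_pre: int = 6) -> StudyManifest:
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"missing manifest: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as e:  # malformed delimited text
        raise ManifestError(f"cannot parse manifest {path}: {e}") from e
    return StudyManifest(
        rows=df, scans_per_subject=scans_per_subject, n_pre=n_pre
    )


def write_manifest(manifest: StudyManifest, path) -> None:
    manifest.rows.to_csv(path, index=False)


def write_marker_map(data: np.ndarray, path) -> None:
    """Write a scalar parametric map as float64 NIfTI-1 (lossless)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))
    nib.save(img, str(path))


def read_marker_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a results table as CSV with header; floats at full precision."""
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
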