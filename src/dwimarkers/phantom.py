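"""Seeded synthetic DWI cohorts emulating the serial AQP4-inhibition study.

The phantom reproduces the study's acquisition and effect structure on a
small grid: 3 b-values (0, 250, 1750 s/mm²) × 6 directions, 18 serial
5-minute scans per subject (6 before, 12 after injection), two groups of 16
subjects, and five nested ROIs whose voxel counts follow the anatomical
ordering DG < CA3 < hippocampus < striatum < cortex.  Tissue is isotropic by
design (the pipeline only consumes direction-averaged signals) and each
ROI's signal follows the kurtosis representation with ROI-specific baseline
parameters near the generic-tissue signature.  Unlabeled voxels are a
uniform tissue bath with the generic-signature parameters, so the only
temporal structure in a phantom is the one injected deliberately.

The injected effect is a per-ROI shift of the kurtosis parameters along the
(negated) B→A signature direction — a *decrease* of diffusion hindrance —
ramping linearly over the first 3 post-injection scans to a plateau
calibrated so the noiseless cortical Sindex drops by a chosen percentage
(default −9%); the hippocampus (with CA3/DG) receives 1.3× the cortical
shift and the striatum none.  Noise is Rician (magnitude of a
complex-Gaussian-corrupted signal) at SNR 40 relative to b0; deliberate
instabilities are sinusoidal scan-level intensity modulations at listed
voxels.  Everything is reproducible from a single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, PhantomError
from .io import (
    AcquisitionScheme,
    DwiSeries,
    LabelVolume,
    StudyManifest,
    write_dwi,
    write_labels,
    write_manifest,
    write_scheme,
)
from .markers import sindex
from .signature import (
    KurtosisParams,
    S_A,
    S_B,
    SignatureLibrary,
    default_library,
    fit_two_point,
    kurtosis_signal,
)

__all__ = [
    "PhantomSpec",
    "default_scheme",
    "make_atlas",
    "simulate_subject",
    "iter_cohort",
    "simulate_cohort",
    "calibrate_effect",
    "default_phantom_spec",
    "scatter_voxels",
]

ROI_LABELS = {1: "cortex", 2: "striatum", 3: "hippocampus", 4: "CA3", 5: "DG"}

#: Small per-ROI offsets from the generic-tissue fit, giving the maps the
#: regional baseline contrast real brains show (hippocampal structures more
#: hindered than cortex, striatum slightly less).
BASELINE_OFFSETS = {
    "bath": (0.0, 0.0),
    "cortex": (0.0, 0.10),
    "striatum": (-2.0e-5, 0.0),
    "hippocampus": (1.0e-5, 0.20),
    "CA3": (1.0e-5, 0.25),
    "DG": (1.0e-5, 0.30),
}


def default_scheme() -> AcquisitionScheme:
    """1 × b0 + 6 × 250 + 6 × 1750 s/mm², six standard directions."""
    dirs6 = np.array(
        [
            [1, 1, 0],
            [1, -1, 0],
            [1, 0, 1],
            [1, 0, -1],
            [0, 1, 1],
            [0, 1, -1],
        ],
        dtype=float,
    )
    dirs6 /= np.linalg.norm(dirs6, axis=1, keepdims=True)
    bvals = np.array([0.0] + [250.0] * 6 + [1750.0] * 6)
    dirs = np.vstack([np.zeros((1, 3)), dirs6, dirs6])
    return AcquisitionScheme(bvalues=bvals, directions=dirs)


def default_baseline() -> dict[str, KurtosisParams]:
    base = fit_two_point(*S_B)
    return {
        roi: base.shifted(*off).validate_against(1750.0)
        for roi, off in BASELINE_OFFSETS.items()
    }


@dataclass(frozen=True)
class EffectModel:
    """Post-injection kurtosis-parameter shift per ROI with a linear ramp.

    ``plateau`` maps ROI name → (Δd, Δk); missing ROIs get no effect.  The
    shift is 0 pre-injection, ramps linearly over ``ramp_scans`` scans and
    stays at plateau; only subjects in ``groups`` are affected.
    """

    plateau: dict[str, tuple[float, float]] = field(default_factory=dict)
    ramp_scans: int = 3
    groups: tuple[str, ...] = ("tgn020",)

    def fraction(self, scan_index: int, n_pre: int) -> float:
        if scan_index <= n_pre:
            return 0.0
        return min((scan_index - n_pre) / self.ramp_scans, 1.0)

    def shift(
        self, roi: str, group: str, scan_index: int, n_pre: int
    ) -> tuple[float, float]:
        if group not in self.groups or roi not in self.plateau:
            return (0.0, 0.0)
        f = self.fraction(scan_index, n_pre)
        dd, dk = self.plateau[roi]
        return (f * dd, f * dk)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort (geometry, signal, effect, noise)."""

    seed: int
    grid_shape: tuple[int, int, int] = (32, 32, 8)
    n_scans: int = 18
    n_pre: int = 6
    scan_interval_min: float = 5.0
    s0_ref: float = 1000.0
    snr: float | None = 40.0
    noise_model: str = "rician"
    baseline: dict[str, KurtosisParams] = field(default_factory=default_baseline)
    effect: EffectModel = field(default_factory=EffectModel)
    instabilities: tuple[tuple[tuple[int, int, int], float], ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PhantomError("phantom seed is mandatory")
        if self.noise_model not in ("rician", "gaussian"):
            raise PhantomError(f"unknown noise model {self.noise_model!r}")
        if self.n_pre >= self.n_scans:
            raise PhantomError("need post-injection scans (n_pre < n_scans)")
        for roi, p in self.baseline.items():
            if not isinstance(p, KurtosisParams):
                raise PhantomError(f"baseline for {roi!r} is not KurtosisParams")

    def acquisition_time(self, scan_index: int) -> float:
        """Minutes relative to injection; injection right after scan n_pre."""
        return (scan_index - 1 - self.n_pre) * self.scan_interval_min

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed,
            "grid_shape": list(self.grid_shape),
            "n_scans": self.n_scans,
            "n_pre": self.n_pre,
            "scan_interval_min": self.scan_interval_min,
            "s0_ref": self.s0_ref,
            "snr": self.snr,
            "noise_model": self.noise_model,
            "baseline": {r: [p.d, p.k] for r, p in self.baseline.items()},
            "effect": {
                "plateau": {r: list(v) for r, v in self.effect.plateau.items()},
                "ramp_scans": self.effect.ramp_scans,
                "groups": list(self.effect.groups),
            },
            "instabilities": [
                [list(v), a] for v, a in self.instabilities
            ],
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=d["seed"],
            grid_shape=tuple(d["grid_shape"]),
            n_scans=d["n_scans"],
            n_pre=d["n_pre"],
            scan_interval_min=d["scan_interval_min"],
            s0_ref=d["s0_ref"],
            snr=d["snr"],
            noise_model=d["noise_model"],
            baseline={
                r: KurtosisParams(*v) for r, v in d["baseline"].items()
            },
            effect=EffectModel(
                plateau={
                    r: tuple(v) for r, v in d["effect"]["plateau"].items()
                },
                ramp_scans=d["effect"]["ramp_scans"],
                groups=tuple(d["effect"]["groups"]),
            ),
            instabilities=tuple(
                (tuple(v), a) for v, a in d["instabilities"]
            ),
        )


def make_atlas(spec: PhantomSpec) -> LabelVolume:
    """Deterministic 5-ROI label volume with anatomically ordered sizes.

    Cortex occupies the lower half-plane, striatum and hippocampus split the
    upper band, CA3 and DG are disjoint boxes nested inside the hippocampus.
    Voxel counts are strictly ordered DG < CA3 < hippocampus < striatum <
    cortex (the ordering the study's ROIs show); an infeasible grid raises.
    """
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    def box(x0, x1, y0, y1, z0, z1, lab):
        labels[x0:x1, y0:y1, z0:z1] = lab

    x0, x1 = max(1, nx // 16), nx - max(1, nx // 16)
    z0, z1 = max(1, nz // 8), nz - max(1, nz // 8)
    y_split = ny // 2
    y_top = ny - max(1, ny // 5)
    try:
        box(x0, x1, max(1, ny // 16), y_split, z0, z1, 1)  # cortex
        box(x0, x0 + (x1 - x0) // 2, y_split + 1, y_top, z0, z1, 2)  # striatum
        hx0 = x0 + (x1 - x0) // 2 + 2
        box(hx0, x1, y_split + 1, y_top, z0, z1, 3)  # hippocampus
        # CA3 and DG: disjoint boxes strictly inside the hippocampus
        box(hx0 + 1, hx0 + 4, y_split + 2, y_split + 5, z0 + 1, z1 - 1, 4)
        box(hx0 + 5, hx0 + 7, y_split + 2, y_split + 4, z0 + 1, z1 - 1, 5)
    except IndexError as e:  # pragma: no cover - guarded below anyway
        raise PhantomError(f"grid {spec.grid_shape} too small for atlas") from e

    counts = {name: int((labels == lab).sum()) for lab, name in ROI_LABELS.items()}
    # hippocampus ROI includes its subfields
    hippo_total = counts["hippocampus"] + counts["CA3"] + counts["DG"]
    ordered = [
        counts["DG"],
        counts["CA3"],
        hippo_total,
        counts["striatum"],
        counts["cortex"],
    ]
    if min(counts.values()) == 0 or any(
        a >= b for a, b in zip(ordered, ordered[1:])
    ):
        raise PhantomError(
            f"grid {spec.grid_shape} infeasible: ROI counts {counts} do not "
            "satisfy DG < CA3 < hippocampus < striatum < cortex"
        )
    return LabelVolume(labels=labels, dictionary=dict(ROI_LABELS))


def _roi_of_label(lab: int) -> str:
    return ROI_LABELS.get(lab, "bath")


def _noiseless_lut(
    spec: PhantomSpec,
    group: str,
    scan_index: int,
    label_ids: np.ndarray,
    shell_bs: np.ndarray,
) -> np.ndarray:
    """Noiseless signal per (label id, shell); shape (n_labels, n_shells)."""
    lut = np.empty((label_ids.size, shell_bs.size))
    for i, lab in enumerate(label_ids):
        roi = _roi_of_label(int(lab))
        params = spec.baseline.get(roi, spec.baseline["bath"])
        dd, dk = spec.effect.shift(roi, group, scan_index, spec.n_pre)
        shifted = params.shifted(dd, dk)
        lut[i] = spec.s0_ref * kurtosis_signal(shifted, shell_bs)
    return lut


def simulate_subject(
    spec: PhantomSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sub",
    labels: LabelVolume | None = None,
    scheme: AcquisitionScheme | None = None,
) -> list[DwiSeries]:
    """Generate the 18 serial scans of one subject.

    Noiseless signals are identical across the 6 directions (isotropy by
    design); deliberate instabilities multiply all volumes of a scan at the
    listed voxels by ``1 + (amp/100)·sin(2π(scan-1)/6)``; Rician noise is
    the magnitude of the noiseless signal plus complex Gaussian noise with
    per-channel SD ``s0_ref / SNR``.
    """
    if labels is None:
        labels = make_atlas(spec)
    if scheme is None:
        scheme = default_scheme()
    label_ids = np.unique(labels.labels)
    dense = np.searchsorted(label_ids, labels.labels)  # grid of lut rows
    shell_bs = np.array([0.0, scheme.key_low_b, scheme.key_high_b])
    sigma = 0.0 if spec.snr is None else spec.s0_ref / spec.snr
    scans = []
    for k in range(1, spec.n_scans + 1):
        lut = _noiseless_lut(spec, group, k, label_ids, shell_bs)
        vol = lut[dense][..., scheme.shell_of]  # (x, y, z, n_volumes)
        if spec.instabilities:
            wave = np.sin(2.0 * np.pi * (k - 1) / 6.0)
            vol = vol.copy()
            for (x, y, z), amp in spec.instabilities:
                vol[x, y, z, :] *= 1.0 + amp / 100.0 * wave
        if sigma > 0:
            if spec.noise_model == "rician":
                vol = np.hypot(
                    vol + rng.normal(0.0, sigma, vol.shape),
                    rng.normal(0.0, sigma, vol.shape),
                )
            else:
                vol = np.clip(
                    vol + rng.normal(0.0, sigma, vol.shape), 0.0, None
                )
        scans.append(
            DwiSeries(
                intensities=vol,
                scheme=scheme,
                subject_id=subject_id,
                scan_index=k,
                acquisition_time=spec.acquisition_time(k),
            )
        )
    return scans


def _subject_ids(n_per_group: int):
    for g, tag in (("vehicle", "veh"), ("tgn020", "tgn")):
        for i in range(1, n_per_group + 1):
            yield f"{tag}{i:02d}", g


def iter_cohort(
    spec: PhantomSpec,
    n_per_group: int = 16,
    master_seed: int | None = None,
):
    """Yield (subject_id, group, scans) for a full two-group cohort.

    Per-subject RNG streams are spawned deterministically from the master
    seed (default: ``spec.seed``), so cohorts are reproducible and subjects
    are independent.
    """
    if n_per_group < 1:
        raise PhantomError("need at least one subject per group")
    seed = spec.seed if master_seed is None else master_seed
    ids = list(_subject_ids(n_per_group))
    children = np.random.SeedSequence(seed).spawn(len(ids))
    labels = make_atlas(spec)
    scheme = default_scheme()
    for (sid, group), ss in zip(ids, children):
        rng = np.random.default_rng(ss)
        yield sid, group, simulate_subject(
            spec, group, rng, subject_id=sid, labels=labels, scheme=scheme
        ), labels, scheme


def simulate_cohort(
    spec: PhantomSpec,
    out_dir,
    n_per_group: int = 16,
    master_seed: int | None = None,
) -> StudyManifest:
    """Write a cohort to disk in exactly the formats the readers consume.

    Layout: ``dwi/<subject>_scan<k>.nii``, ``cohort.bval``/``cohort.bvec``,
    ``labels.nii`` + ``labels.json``, ``manifest.csv`` and the spec itself
    as ``phantom.yaml``.  Refuses to overwrite an existing manifest.
    """
    out = Path(out_dir)
    if (out / "manifest.csv").exists():
        raise PhantomError(f"output {out} already contains a cohort")
    (out / "dwi").mkdir(parents=True, exist_ok=True)
    rows = []
    labels = scheme = None
    for sid, group, scans, labels, scheme in iter_cohort(
        spec, n_per_group, master_seed
    ):
        for scan in scans:
            rel = f"dwi/{sid}_scan{scan.scan_index:02d}.nii"
            write_dwi(scan, out / rel)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "scan_index": scan.scan_index,
                    "path": rel,
                    "time_min": scan.acquisition_time,
                }
            )
    write_scheme(scheme, out / "cohort.bval", out / "cohort.bvec")
    write_labels(labels, out / "labels.nii", out / "labels.json")
    manifest = StudyManifest(
        rows=pd.DataFrame(rows),
        scans_per_subject=spec.n_scans,
        n_pre=spec.n_pre,
    )
    write_manifest(manifest, out / "manifest.csv")
    spec.to_yaml(out / "phantom.yaml")
    return manifest


# ---------------------------------------------------------------------------
# effect calibration


def signature_direction() -> tuple[float, float]:
    """The B→A direction in (d, k) space, negated: a hindrance *decrease*."""
    a = fit_two_point(*S_A)
    b = fit_two_point(*S_B)
    return (b.d - a.d, b.k - a.k)


def _noiseless_roi_sindex(
    params: KurtosisParams, library: SignatureLibrary
) -> float:
    s_lb = float(kurtosis_signal(params, library.lb))
    s_hb = float(kurtosis_signal(params, library.hb))
    return sindex(s_lb, s_hb, library)


def calibrate_effect(
    target_pct: float,
    spec: PhantomSpec,
    roi: str = "cortex",
    library: SignatureLibrary | None = None,
    tol_pct: float = 0.1,
) -> tuple[float, float]:
    """Plateau (Δd, Δk) giving a noiseless ROI Sindex change of ``target_pct``.

    One-dimensional search along the negated B→A signature direction,
    limited to at most one full signature distance (|α| ≤ 1) — beyond that
    the linear signature axis has no meaning in the library frame.  Raises
    :class:`CalibrationError` when the target is unreachable there.
    """
    if library is None:
        library = default_library()
    if target_pct == 0.0:
        return (0.0, 0.0)
    base = spec.baseline[roi]
    s_base = _noiseless_roi_sindex(base, library)
    u = signature_direction()

    def pct(alpha: float) -> float:
        shifted = base.shifted(alpha * u[0], alpha * u[1]).validate_against(
            library.hb
        )
        return (_noiseless_roi_sindex(shifted, library) - s_base) / s_base * 100.0

    # scan the admissible range for a sign-change bracket
    alphas, pcts = [], []
    for a in np.linspace(-1.0, 1.0, 201):
        try:
            alphas.append(a)
            pcts.append(pct(a))
        except Exception:
            alphas.pop()
    f = [p - target_pct for p in pcts]
    bracket = None
    for i in range(len(f) - 1):
        if f[i] == 0.0 or f[i] * f[i + 1] < 0:
            bracket = (alphas[i], alphas[i + 1])
            break
    if bracket is None:
        raise CalibrationError(
            f"Sindex change of {target_pct}% in {roi!r} unreachable along "
            "the signature direction"
        )
    from scipy.optimize import brentq

    alpha = brentq(lambda a: pct(a) - target_pct, *bracket, xtol=1e-12)
    if abs(pct(alpha) - target_pct) > tol_pct:
        raise CalibrationError(
            f"calibration did not converge to within {tol_pct} percentage "
            f"points for target {target_pct}%"
        )
    return (alpha * u[0], alpha * u[1])


def default_phantom_spec(
    seed: int,
    target_cortex_pct: float = -9.0,
    hippocampus_scale: float = 1.3,
    **overrides,
) -> PhantomSpec:
    """The study conditions: −9% cortical Sindex plateau, hippocampus 1.3×,
    striatum untouched, SNR 40, 16 subjects per group expected downstream."""
    spec = PhantomSpec(seed=seed, **overrides)
    dd, dk = calibrate_effect(target_cortex_pct, spec, roi="cortex")
    plateau = {
        "cortex": (dd, dk),
        "hippocampus": (hippocampus_scale * dd, hippocampus_scale * dk),
        "CA3": (hippocampus_scale * dd, hippocampus_scale * dk),
        "DG": (hippocampus_scale * dd, hippocampus_scale * dk),
    }
    return replace(spec, effect=EffectModel(plateau=plateau))


def scatter_voxels(
    labels: LabelVolume,
    n: int,
    seed: int,
    roi: str | None = None,
    min_separation: int = 3,
) -> tuple[tuple[int, int, int], ...]:
    """Deterministically pick ``n`` well-separated voxels (optionally in a ROI)."""
    rng = np.random.default_rng(seed)
    candidates = (
        np.argwhere(labels.mask(roi)) if roi else np.argwhere(labels.labels >= 0)
    )
    order = rng.permutation(len(candidates))
    chosen: list[tuple[int, int, int]] = []
    for idx in order:
        v = tuple(int(c) for c in candidates[idx])
        if all(
            max(abs(v[0] - u[0]), abs(v[1] - u[1]), abs(v[2] - u[2]))
            > min_separation
            for u in chosen
        ):
            chosen.append(v)
        if len(chosen) == n:
            return tuple(chosen)
    raise PhantomError(
        f"could not place {n} voxels with separation {min_separation}"
    )
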