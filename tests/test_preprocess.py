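"""Shell averaging/normalization and the temporal stability filter."""

import numpy as np
import pandas as pd
import pytest

from dwimarkers.errors import ShapeMismatchError
from dwimarkers.io import DwiSeries, StudyManifest
from dwimarkers.phantom import (
    make_atlas,
    scatter_voxels,
    simulate_subject,
)
from dwimarkers.preprocess import (
    apply_discard_rule,
    flag_unstable_voxels,
    normalize_and_average,
)
from dwimarkers.signature import kurtosis_signal
from tests.conftest import SEED


def make_scan(scheme, s0=1000.0, s_lb=0.8, s_hb=0.3, shape=(4, 4, 2)):
    data = np.empty(shape + (len(scheme),))
    data[..., scheme.b0_indices] = s0
    data[..., scheme.lb_indices] = s_lb * s0
    data[..., scheme.hb_indices] = s_hb * s0
    return DwiSeries(data, scheme)


def uniform_session(scheme, s0_values, shape=(4, 4, 2)):
    """Spatially uniform scans whose intensity varies across the session."""
    return [
        normalize_and_average(make_scan(scheme, s0=v, shape=shape))
        for v in s0_values
    ]


class TestNormalizeAndAverage:
    def test_constant_directions_give_ratio(self, scheme):
        maps = normalize_and_average(make_scan(scheme, 200.0, 0.7, 0.25))
        assert np.allclose(maps.s_lb, 0.7)
        assert np.allclose(maps.s_hb, 0.25)
        assert np.allclose(maps.s0, 200.0)

    def test_zero_s0_voxel_masked_without_exception(self, scheme):
        scan = make_scan(scheme)
        data = scan.intensities.copy()
        data[0, 0, 0, :] = 0.0
        maps = normalize_and_average(DwiSeries(data, scheme))
        assert not maps.mask[0, 0, 0]
        assert maps.mask.sum() == maps.mask.size - 1
        assert np.isnan(maps.s_lb[0, 0, 0])

    def test_invariant_under_global_rescaling(self, scheme, rng):
        data = rng.uniform(10.0, 1000.0, (4, 4, 2, len(scheme)))
        a = normalize_and_average(DwiSeries(data, scheme))
        b = normalize_and_average(DwiSeries(data * 7.5, scheme))
        assert np.allclose(a.s_lb, b.s_lb, rtol=1e-12)
        assert np.allclose(a.s_hb, b.s_hb, rtol=1e-12)

    def test_noiseless_phantom_matches_kurtosis_model(self, small_spec):
        """Closed-form oracle: generated signals reproduce the model."""
        rng = np.random.default_rng(0)
        scan = simulate_subject(small_spec, "vehicle", rng)[0]
        maps = normalize_and_average(scan)
        atlas = make_atlas(small_spec)
        for roi in ("cortex", "striatum", "DG"):
            params = small_spec.baseline[roi]
            sel = atlas.labels == {
                "cortex": 1,
                "striatum": 2,
                "DG": 5,
            }[roi]
            assert np.allclose(
                maps.s_lb[sel], kurtosis_signal(params, 250.0), atol=1e-10
            )
            assert np.allclose(
                maps.s_hb[sel], kurtosis_signal(params, 1750.0), atol=1e-10
            )


class TestFlagUnstableVoxels:
    def test_identical_scans_flag_nothing(self, scheme):
        session = uniform_session(scheme, [500.0] * 6)
        report = flag_unstable_voxels(session)
        assert report.flagged.sum() == 0

    def test_threshold_boundary_is_strict(self, scheme):
        session = uniform_session(scheme, [100.0, 104.0, 96.0, 100.0])
        report = flag_unstable_voxels(session, threshold_pct=100.0)
        # spatially uniform session: take the largest per-shell CV
        cv = max(float(report.cv_pct[s][0, 0, 0]) for s in ("b0", "lb", "hb"))
        assert cv > 0
        at = flag_unstable_voxels(session, threshold_pct=cv)
        below = flag_unstable_voxels(
            session, threshold_pct=cv * (1 - 1e-12)
        )
        assert at.flagged.sum() == 0  # CV == threshold → not flagged
        assert below.flagged.all()

    def test_flag_count_monotone_in_threshold(self, scheme, rng):
        sessions = [
            normalize_and_average(
                DwiSeries(
                    rng.uniform(90, 110, (6, 6, 4, len(scheme))), scheme
                )
            )
            for _ in range(6)
        ]
        counts = [
            flag_unstable_voxels(sessions, threshold_pct=t).flagged.sum()
            for t in (1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_degenerate_zero_mean_voxel_flagged(self, scheme):
        session = [make_scan(scheme) for _ in range(4)]
        zeroed = []
        for s in session:
            d = s.intensities.copy()
            d[1, 1, 1, :] = 0.0
            zeroed.append(normalize_and_average(DwiSeries(d, scheme)))
        report = flag_unstable_voxels(zeroed, smoothing_fwhm_vox=0.0)
        assert report.flagged[1, 1, 1]
        assert report.degenerate[1, 1, 1]

    def test_needs_three_scans(self, scheme):
        with pytest.raises(ShapeMismatchError, match="3 scans"):
            flag_unstable_voxels(uniform_session(scheme, [1.0, 2.0]))

    def test_injected_modulation_recovered_at_snr40(self, small_noisy_spec):
        """Deliberately unstable voxels are flagged; stable ones are not."""
        from dataclasses import replace

        atlas = make_atlas(small_noisy_spec)
        voxels = scatter_voxels(atlas, 8, seed=SEED, min_separation=3)
        spec = replace(
            small_noisy_spec, instabilities=tuple((v, 10.0) for v in voxels)
        )
        rng = np.random.default_rng(SEED)
        scans = simulate_subject(spec, "vehicle", rng)
        report = flag_unstable_voxels(
            [normalize_and_average(s) for s in scans]
        )
        injected = np.zeros(spec.grid_shape, bool)
        for v in voxels:
            injected[v] = True
        assert report.flagged[injected].all()
        assert report.flagged[~injected].mean() < 0.01


class TestDiscardRule:
    def _manifest(self, sids):
        rows = []
        for sid in sids:
            for k in range(1, 19):
                rows.append(
                    {
                        "subject_id": sid,
                        "group": "vehicle",
                        "scan_index": k,
                        "path": "",
                        "time_min": (k - 7) * 5.0,
                    }
                )
        return StudyManifest(rows=pd.DataFrame(rows))

    def _report(self, shape, flagged_at=()):
        flagged = np.zeros(shape, bool)
        for v in flagged_at:
            flagged[v] = True
        from dwimarkers.preprocess import StabilityReport

        return StabilityReport(
            flagged=flagged,
            cv_pct={},
            threshold_pct=4.0,
            smoothing_fwhm_vox=1.0,
        )

    def test_no_flags_leaves_manifest_unchanged(self, small_atlas):
        manifest = self._manifest(["s1", "s2"])
        shape = small_atlas.labels.shape
        filtered, log = apply_discard_rule(
            {"s1": self._report(shape), "s2": self._report(shape)},
            small_atlas,
            manifest,
        )
        assert filtered.subjects == ["s1", "s2"]
        assert log.empty

    def test_flag_in_cortex_removes_whole_subject(self, small_atlas):
        manifest = self._manifest(["s1", "s2"])
        shape = small_atlas.labels.shape
        cortex_voxel = tuple(np.argwhere(small_atlas.mask("cortex"))[0])
        filtered, log = apply_discard_rule(
            {
                "s1": self._report(shape, [cortex_voxel]),
                "s2": self._report(shape),
            },
            small_atlas,
            manifest,
        )
        assert filtered.subjects == ["s2"]
        assert len(filtered.rows) == 18
        assert log.iloc[0]["subject_id"] == "s1"
        assert log.iloc[0]["roi"] == "cortex"

    def test_flag_only_in_background_is_ignored(self, small_atlas):
        manifest = self._manifest(["s1"])
        shape = small_atlas.labels.shape
        bg_voxel = tuple(np.argwhere(small_atlas.labels == 0)[0])
        filtered, log = apply_discard_rule(
            {"s1": self._report(shape, [bg_voxel])}, small_atlas, manifest
        )
        assert filtered.subjects == ["s1"]
        assert log.empty
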