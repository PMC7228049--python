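"""Synthetic cohort generator: atlas, signal model, effect, noise, seeding."""

from dataclasses import replace

import numpy as np
import pytest

from dwimarkers.errors import CalibrationError, PhantomError
from dwimarkers.markers import sindex
from dwimarkers.phantom import (
    EffectModel,
    PhantomSpec,
    calibrate_effect,
    default_phantom_spec,
    iter_cohort,
    make_atlas,
    simulate_subject,
)
from dwimarkers.pipeline import analyze_cohort
from dwimarkers.preprocess import normalize_and_average
from dwimarkers.signature import default_library, kurtosis_signal
from tests.conftest import SEED


class TestAtlas:
    def test_roi_counts_follow_anatomical_ordering(self):
        spec = PhantomSpec(seed=1)
        atlas = make_atlas(spec)
        counts = [
            int(atlas.mask(n).sum())
            for n in ("DG", "CA3", "hippocampus", "striatum", "cortex")
        ]
        assert all(c > 0 for c in counts)
        assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_deterministic(self):
        spec = PhantomSpec(seed=1)
        assert np.array_equal(make_atlas(spec).labels, make_atlas(spec).labels)

    def test_infeasible_grid_raises(self):
        with pytest.raises(PhantomError):
            make_atlas(PhantomSpec(seed=1, grid_shape=(4, 4, 1)))


class TestSimulateSubject:
    def test_same_seed_bit_identical(self, small_noisy_spec):
        a = simulate_subject(
            small_noisy_spec, "vehicle", np.random.default_rng(5)
        )
        b = simulate_subject(
            small_noisy_spec, "vehicle", np.random.default_rng(5)
        )
        for x, y in zip(a, b):
            assert np.array_equal(x.intensities, y.intensities)

    def test_noiseless_vehicle_matches_baseline_model(self, small_spec):
        scans = simulate_subject(
            small_spec, "vehicle", np.random.default_rng(0)
        )
        atlas = make_atlas(small_spec)
        cortex = atlas.labels == 1
        for scan in scans[:2] + scans[-2:]:
            maps = normalize_and_average(scan)
            p = small_spec.baseline["cortex"]
            assert np.allclose(
                maps.s_lb[cortex], kurtosis_signal(p, 250.0), atol=1e-10
            )
            assert np.allclose(
                maps.s_hb[cortex], kurtosis_signal(p, 1750.0), atol=1e-10
            )

    def test_noiseless_effect_plateau_lowers_cortex_sindex(self):
        spec = default_phantom_spec(seed=SEED, grid_shape=(16, 16, 6), snr=None)
        library = default_library()
        scans = simulate_subject(spec, "tgn020", np.random.default_rng(0))
        atlas = make_atlas(spec)
        cortex = atlas.labels == 1

        def roi_sindex(scan):
            m = normalize_and_average(scan)
            return sindex(
                m.s_lb[cortex].mean(), m.s_hb[cortex].mean(), library
            )

        pre, plateau = roi_sindex(scans[0]), roi_sindex(scans[-1])
        p_shift = spec.baseline["cortex"].shifted(
            *spec.effect.plateau["cortex"]
        )
        expected = sindex(
            float(kurtosis_signal(p_shift, 250.0)),
            float(kurtosis_signal(p_shift, 1750.0)),
            library,
        )
        assert plateau == pytest.approx(expected, abs=1e-9)
        assert plateau < pre

    def test_effect_ramp_fraction(self):
        eff = EffectModel(plateau={"cortex": (0.0, -0.1)})
        fractions = [eff.fraction(k, n_pre=6) for k in range(1, 19)]
        assert fractions[:6] == [0.0] * 6
        assert fractions[6] == pytest.approx(1 / 3)
        assert fractions[7] == pytest.approx(2 / 3)
        assert fractions[8:] == [1.0] * 10

    def test_vehicle_and_striatum_unaffected(self):
        eff = EffectModel(plateau={"cortex": (1e-5, -0.1)})
        assert eff.shift("cortex", "vehicle", 18, 6) == (0.0, 0.0)
        assert eff.shift("striatum", "tgn020", 18, 6) == (0.0, 0.0)


class TestRicianNoise:
    def test_b0_bias_negligible_at_snr40(self):
        """Mean of ≥10⁴ Rician b0 samples within 0.5% of the noiseless value."""
        spec = PhantomSpec(seed=SEED, grid_shape=(32, 32, 8), snr=40.0)
        scans = simulate_subject(spec, "vehicle", np.random.default_rng(SEED))
        b0 = np.concatenate(
            [s.intensities[..., s.scheme.b0_indices[0]].ravel() for s in scans[:2]]
        )
        assert b0.size >= 10_000
        assert abs(b0.mean() - spec.s0_ref) / spec.s0_ref < 0.005


class TestCohort:
    def test_cohort_size_and_determinism(self, small_noisy_spec):
        def collect():
            out = {}
            for sid, group, scans, _, _ in iter_cohort(
                small_noisy_spec, n_per_group=2
            ):
                out[(sid, group)] = scans
            return out

        a, b = collect(), collect()
        assert len(a) == 4
        for key in a:
            assert len(a[key]) == 18
            for x, y in zip(a[key], b[key]):
                assert np.array_equal(x.intensities, y.intensities)

    def test_expected_scan_arithmetic_at_study_size(self, small_spec):
        n_scans = sum(
            len(scans)
            for _, _, scans, _, _ in iter_cohort(small_spec, n_per_group=16)
        )
        assert n_scans == 32 * 18  # 576 scan volumes for the full study

    def test_single_subject_per_group_degrades_gracefully(self, small_spec):
        result = analyze_cohort(small_spec, n_per_group=1)
        assert result.n_subjects_analyzed == 2
        assert result.stats.paired["p"].isna().all()  # n=1: not computable

    def test_full_null_cohort_is_flat_and_silent(self, small_spec):
        """Zero effect + no noise → flat courses, no significant test."""
        result = analyze_cohort(small_spec, n_per_group=3)
        values = result.timecourse.values
        for _, sub in values.groupby(["subject_id", "roi", "marker"]):
            assert sub["value"].std() == pytest.approx(0.0, abs=1e-12)
        for frame, col in (
            (result.stats.paired, "p"),
            (result.stats.between, "p_raw"),
            (result.stats.per_timepoint, "p"),
        ):
            p = frame[col].dropna()
            assert not (p < 0.05).any()


class TestCalibration:
    def test_zero_target_gives_zero_shift(self):
        assert calibrate_effect(0.0, PhantomSpec(seed=1)) == (0.0, 0.0)

    def test_minus9_percent_verified_by_forward_simulation(self):
        """The calibrated plateau reproduces −9.0% ± 0.1 noiselessly."""
        spec = default_phantom_spec(seed=SEED, grid_shape=(16, 16, 6), snr=None)
        library = default_library()
        atlas = make_atlas(spec)
        cortex = atlas.labels == 1
        scans = simulate_subject(spec, "tgn020", np.random.default_rng(0))

        def roi_sindex(scan):
            m = normalize_and_average(scan)
            return sindex(
                m.s_lb[cortex].mean(), m.s_hb[cortex].mean(), library
            )

        base, plateau = roi_sindex(scans[0]), roi_sindex(scans[-1])
        assert (plateau - base) / base * 100 == pytest.approx(-9.0, abs=0.1)

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_effect(-200.0, PhantomSpec(seed=1))

    def test_hippocampus_plateau_scaled(self):
        spec = default_phantom_spec(seed=SEED, grid_shape=(16, 16, 6))
        c = spec.effect.plateau["cortex"]
        h = spec.effect.plateau["hippocampus"]
        assert h[0] == pytest.approx(1.3 * c[0])
        assert h[1] == pytest.approx(1.3 * c[1])


class TestSpecSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        spec = replace(
            default_phantom_spec(seed=7, grid_shape=(16, 16, 6)),
            instabilities=(((3, 3, 2), 10.0),),
        )
        spec.to_yaml(tmp_path / "p.yaml")
        back = PhantomSpec.from_yaml(tmp_path / "p.yaml")
        assert back.seed == spec.seed
        assert back.grid_shape == spec.grid_shape
        assert back.effect.plateau.keys() == spec.effect.plateau.keys()
        for k in spec.effect.plateau:
            assert back.effect.plateau[k] == pytest.approx(
                spec.effect.plateau[k]
            )
        assert back.instabilities == spec.instabilities
        assert back.baseline["cortex"].d == pytest.approx(
            spec.baseline["cortex"].d
        )

    def test_missing_seed_rejected(self):
        with pytest.raises((PhantomError, TypeError)):
            PhantomSpec(seed=None)
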