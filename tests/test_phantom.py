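"""Phantom generator: schedules, AIF, forward model, PET, histology, cohort."""

import numpy as np
import pytest

from flowmet import (
    AIFParams,
    HistologySectionSpec,
    KineticParams,
    PetPhantomSpec,
    PhantomSpec,
    ValidationError,
    default_injection_protocol,
    default_scan_schedule,
    make_scan_schedule,
    reference_param_table,
    simulate_aif,
    simulate_cohort,
    simulate_dynamic_series,
    simulate_histology_section,
    simulate_pet_volume,
    simulate_tissue_curve,
)
from flowmet.core import TimeCurve
from flowmet.phantom import dense_times, draw_cohort_truth


class TestScanSchedule:
    def test_study_protocol_frames_and_duration(self):
        s = default_scan_schedule()
        assert s.n_frames == 40
        assert s.total_duration == pytest.approx(120.0)
        assert s.frame_times[0] == 2.0

    def test_single_frame(self):
        s = make_scan_schedule([(1, 1.0)], start_offset=0)
        assert s.n_frames == 1
        assert s.frame_times[0] == 0.0
        assert s.total_duration == pytest.approx(1.0)

    def test_two_phase_times_enumerated_by_hand(self):
        s = make_scan_schedule([(3, 2.0), (2, 5.0)], start_offset=0)
        np.testing.assert_allclose(s.frame_times, [0, 2, 4, 9, 14])
        assert s.total_duration == pytest.approx(16.0)

    def test_within_phase_spacing(self):
        s = default_scan_schedule()
        d = np.diff(s.frame_times)
        np.testing.assert_allclose(d[:19], 1.5)
        np.testing.assert_allclose(d[19:29], 3.0)
        np.testing.assert_allclose(d[29:], 6.0)

    @pytest.mark.parametrize(
        "phases,offset",
        [([(0, 1.0)], 0), ([(5, -1.0)], 0), ([(5, 1.0)], -2), ([], 0)],
    )
    def test_invalid_schedule_rejected(self, phases, offset):
        with pytest.raises(ValidationError):
            make_scan_schedule(phases, offset)


class TestInjectionProtocol:
    def test_total_contrast_excludes_flush(self):
        p = default_injection_protocol()
        assert p.total_contrast_volume == pytest.approx(6.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            default_injection_protocol().__class__(
                contrast_phases=((3.0, 0.0),), flush=(1.5, 0.1)
            )


class TestAIF:
    def test_peak_equals_amplitude_without_recirculation(self):
        p = AIFParams(amplitude=300, onset=4, shape=2, scale=3,
                      recirculation_fraction=0.0)
        curve = simulate_aif(dense_times(80, 0.005), p)
        assert curve.peak == pytest.approx(300.0, rel=1e-5)
        assert curve.peak_time == pytest.approx(4 + 2 * 3, abs=0.02)

    def test_zero_before_onset(self):
        p = AIFParams(onset=6.0)
        curve = simulate_aif(np.linspace(0, 6, 50), p)
        assert np.all(curve.values == 0.0)

    def test_pinned_value_regression(self):
        # closed form at t=10 for A=300, t0=4, alpha=2, beta=3:
        # u = 2 == alpha, so value is exactly the peak A
        p = AIFParams(amplitude=300, onset=4, shape=2, scale=3,
                      recirculation_fraction=0.0)
        v = simulate_aif(np.array([0.0, 10.0]), p).values[1]
        assert v == pytest.approx(300.0, rel=1e-12)

    def test_recirculation_plateau_level(self):
        p = AIFParams(amplitude=200, recirculation_fraction=0.3)
        curve = simulate_aif(np.linspace(0, 600, 2000), p)
        assert curve.values[-1] == pytest.approx(0.3 * 200, rel=1e-3)

    @pytest.mark.parametrize("kw", [dict(shape=0), dict(scale=-1),
                                    dict(recirculation_fraction=1.0)])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValidationError):
            AIFParams(**kw)


class TestTissueCurve:
    def test_zero_kinetics_gives_zero_curve(self):
        aif = simulate_aif(dense_times(60), AIFParams())
        kin = KineticParams(bf=0.0, bv=0.0, ps=0.0)
        c = simulate_tissue_curve(aif, kin)
        assert np.all(c.values == 0.0)

    def test_step_aif_early_slope_is_fractional_flow(self):
        # step AIF of height c: for t < MTT and PS=0 the boxcar model
        # gives C_t = f*c*t exactly
        t = dense_times(30, 0.01)
        c = 250.0
        step = TimeCurve(t, np.where(t > 0, c, 0.0), kind="enhancement")
        kin = KineticParams(bf=30.0, mtt=10.0, ps=0.0)
        out = simulate_tissue_curve(step, kin)
        sel = (t > 0.5) & (t < 9.5)
        slopes = np.gradient(out.values, t)[sel]
        np.testing.assert_allclose(slopes, kin.flow_per_second * c, rtol=1e-6)

    def test_patlak_identity_in_late_window(self):
        # late equilibrated window: y = C_t/C_a is linear in
        # x = int(C_a)/C_a with slope PS/6000 and intercept BV/100
        t = dense_times(300, 0.01)
        aif = simulate_aif(t, AIFParams())
        kin = KineticParams(bf=36.16, bv=25.36, ps=9.47)
        ct = simulate_tissue_curve(aif, kin)
        sel = t > 200  # far beyond onset + MTT
        integral = np.concatenate(
            [[0.0], np.cumsum(0.5 * (aif.values[1:] + aif.values[:-1]) * np.diff(t))]
        )
        x = integral[sel] / aif.values[sel]
        y = ct.values[sel] / aif.values[sel]
        slope, intercept = np.polyfit(x, y, 1)
        assert slope * 6000 == pytest.approx(kin.ps, rel=5e-3)
        assert intercept * 100 == pytest.approx(kin.bv, rel=5e-3)

    def test_linearity_in_aif_amplitude(self):
        t = dense_times(60)
        kin = KineticParams(bf=30.0, bv=20.0, ps=10.0)
        a1 = simulate_aif(t, AIFParams(amplitude=150))
        a2 = simulate_aif(t, AIFParams(amplitude=300))
        c1 = simulate_tissue_curve(a1, kin)
        c2 = simulate_tissue_curve(a2, kin)
        np.testing.assert_allclose(c2.values, 2 * c1.values, rtol=1e-10)

    def test_coarse_aif_rejected(self):
        t = np.arange(0, 60, 1.0)
        aif = simulate_aif(t, AIFParams())
        with pytest.raises(ValidationError):
            simulate_tissue_curve(aif, KineticParams(bf=30))


class TestDynamicSeries:
    def test_uniform_voi_mean_matches_tissue_curve(self):
        kin = KineticParams(bf=30.0, bv=20.0, ps=10.0)
        spec = PhantomSpec(kinetics=kin, noise_sigma=0.0)
        series, tumor, _, _ = simulate_dynamic_series(spec)
        voi = series.voi_curve(tumor)
        aif = simulate_aif(dense_times(series.frame_times[-1]), AIFParams())
        expected = simulate_tissue_curve(aif, kin).sample_at(series.frame_times)
        np.testing.assert_allclose(
            voi.values, spec.background_hu + expected.values, rtol=1e-10
        )

    def test_seeded_bit_reproducibility(self):
        spec = PhantomSpec(noise_sigma=3.0, seed=42)
        s1, *_ = simulate_dynamic_series(spec)
        s2, *_ = simulate_dynamic_series(spec)
        assert np.array_equal(s1.data, s2.data)

    def test_different_seeds_differ(self):
        s1, *_ = simulate_dynamic_series(PhantomSpec(noise_sigma=3.0, seed=1))
        s2, *_ = simulate_dynamic_series(PhantomSpec(noise_sigma=3.0, seed=2))
        assert not np.array_equal(s1.data, s2.data)

    def test_ellipsoid_outside_grid_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(tumor_center_mm=(2.0, 22.0, 22.0))


class TestPetPhantom:
    def test_targets_hit_exactly(self):
        vol, mask = simulate_pet_volume(PetPhantomSpec(suv_max=3.73, suv_mean=2.10))
        assert vol[mask].max() == pytest.approx(3.73, rel=1e-12)
        assert vol[mask].mean() == pytest.approx(2.10, rel=1e-12)

    def test_flat_targets_give_constant_tumor(self):
        vol, mask = simulate_pet_volume(
            PetPhantomSpec(suv_max=2.0, suv_mean=2.0, heterogeneity=0.0)
        )
        assert np.all(vol[mask] == 2.0)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValidationError):
            PetPhantomSpec(suv_max=1.0, suv_mean=2.0)

    def test_seeded_reproducibility(self):
        spec = PetPhantomSpec(seed=7)
        v1, _ = simulate_pet_volume(spec)
        v2, _ = simulate_pet_volume(spec)
        assert np.array_equal(v1, v2)


class TestHistologyPhantom:
    def test_empty_field(self):
        img, counts, _ = simulate_histology_section(
            HistologySectionSpec(counts=((0,),), n_hot_spots=1)
        )
        assert img.sum() == 0

    def test_seeded_reproducibility(self):
        spec = HistologySectionSpec(counts=((3, 1), (0, 5)), n_hot_spots=1, seed=3)
        i1, *_ = simulate_histology_section(spec)
        i2, *_ = simulate_histology_section(spec)
        assert np.array_equal(i1, i2)

    def test_hot_spots_are_densest_fields(self):
        spec = HistologySectionSpec(
            counts=((9, 1, 0, 2), (0, 8, 1, 9), (2, 0, 9, 1)), seed=0
        )
        img, counts, hot = simulate_histology_section(spec)
        assert set(hot) == {(0, 0), (1, 1), (1, 3), (2, 2)}

    def test_unplaceable_counts_rejected(self):
        with pytest.raises(ValidationError):
            simulate_histology_section(
                HistologySectionSpec(
                    counts=((500,),), field_shape=(40, 40), n_hot_spots=1
                )
            )


class TestCohortSimulator:
    def test_fixed_mode_pins_group_means(self):
        truth = draw_cohort_truth(
            n_rabbits_per_group=2, days=(0,), groups=("treatment",),
            mode="fixed", seed=0,
        )
        assert np.all(truth["bv"] == 25.36)
        assert np.all(truth["bf"] == 36.16)

    def test_zero_sd_draws_equal_mean(self):
        table = reference_param_table().assign(sd=0.0)
        truth = draw_cohort_truth(
            param_table=table, n_rabbits_per_group=3, days=(14,),
            groups=("control",), mode="stochastic", seed=5,
        )
        assert np.all(truth["suv_max"] == 3.73)

    def test_stochastic_means_match_table(self):
        # law of large numbers: 200 tumors per cell within 3 SE
        truth = draw_cohort_truth(
            n_rabbits_per_group=100, days=(0,), groups=("treatment",),
            mode="stochastic", seed=11,
        )
        assert len(truth) == 200
        for name, mean, sd in [("bv", 25.36, 5.62), ("bf", 36.16, 11.15)]:
            se = sd / np.sqrt(len(truth))
            assert abs(truth[name].mean() - mean) < 3 * se

    def test_missing_table_entry_rejected(self):
        table = reference_param_table()
        table = table[table["parameter"] != "bv"]
        with pytest.raises(ValidationError):
            draw_cohort_truth(param_table=table, n_rabbits_per_group=1,
                              days=(0,), groups=("treatment",), seed=0)

    def test_scan_geometry_matches_drawn_volume(self):
        scans = simulate_cohort(
            n_rabbits_per_group=1, days=(14,), groups=("control",),
            mode="fixed", seed=0,
        )
        for s in scans:
            voxel_cm3 = s.series.voxel_volume_mm3 / 1000.0
            tv = s.tumor_mask.sum() * voxel_cm3
            # voxelized ellipsoid volume approximates the analytic draw
            assert tv == pytest.approx(s.truth["tv_cm3"], rel=0.25)
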