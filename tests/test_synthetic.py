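from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import periodogram

from cardiovar.core import BeatSeries, ValidationError
from cardiovar.synthetic import (
    GROUP_SIZES,
    GROUP_STATS,
    NoiseLevels,
    amplitudes_for_ratio,
    catecholamine_table,
    default_design,
    draw_subject_params,
    make_group_params,
    simulate_baseline_recording,
    simulate_cohort,
    simulate_histology_image,
    simulate_lobeline_response,
    simulate_phenylephrine_response,
)
from cardiovar.variability import resample_beat_series


class TestGroupParams:
    def test_ctl_printed_means(self):
        p = make_group_params("CTL")
        assert p.hr_bpm == 379.0
        assert p.sbp_mmHg == 150.0
        assert p.dbp_mmHg == 111.0
        assert p.collagen_fraction_pct == 59.9
        assert p.brg_bpm_per_mmHg == 0.28
        assert p.delta_rf_cpm == pytest.approx(8.4)
        assert p.lf_hf_target == pytest.approx(1.14)

    def test_dox16_printed_gain(self):
        assert make_group_params("DOX16").brg_bpm_per_mmHg == 0.49

    def test_dox8_delta_rf(self):
        assert make_group_params("DOX8").delta_rf_cpm == pytest.approx(12.5)

    def test_unknown_label_lists_valid(self):
        with pytest.raises(ValidationError, match="CTL"):
            make_group_params("DOX5")

    def test_amplitude_calibration_identity(self):
        lf, hf = amplitudes_for_ratio(1.14, 1.13)
        assert (lf ** 2 / 2) / (hf ** 2 / 2) == pytest.approx(1.14)
        assert hf ** 2 / 2 == pytest.approx(1.13)

    def test_group_sizes_match_design(self):
        assert GROUP_SIZES == {"CTL": 6, "DOX8": 8, "DOX16": 8, "DOX20": 8}


class TestBaseline:
    def test_determinism_under_fixed_seed(self, ctl_params):
        a = simulate_baseline_recording(ctl_params, 180.0, 250.0, seed=5)
        b = simulate_baseline_recording(ctl_params, 180.0, 250.0, seed=5)
        for name in ("ecg", "abp", "tracheal"):
            assert np.array_equal(a.channel(name).samples, b.channel(name).samples)
        assert np.array_equal(a.ground_truth["beat_times"], b.ground_truth["beat_times"])

    def test_seeds_differ(self, ctl_params):
        a = simulate_baseline_recording(ctl_params, 180.0, 250.0, seed=5)
        b = simulate_baseline_recording(ctl_params, 180.0, 250.0, seed=6)
        assert not np.array_equal(a.channel("ecg").samples, b.channel("ecg").samples)

    def test_zero_modulation_gives_constant_rr(self, ctl_params):
        params = replace(ctl_params, hf_amp_bpm=0.0, lf_amp_mmHg=0.0,
                         noise=NoiseLevels.zero())
        bundle = simulate_baseline_recording(params, 180.0, 250.0, seed=1)
        rr = np.diff(bundle.ground_truth["beat_times"])
        assert np.allclose(rr, 60.0 / 379.0, atol=1e-12)

    def test_ground_truth_hr_matches_implicit_construction(self, quiet_baseline):
        gt = quiet_baseline.ground_truth
        rr = np.diff(gt["beat_times"])
        assert np.allclose(60.0 / rr, gt["hr_values"], rtol=1e-12)

    def test_too_short_duration_rejected(self, ctl_params):
        with pytest.raises(ValidationError, match="180"):
            simulate_baseline_recording(ctl_params, 60.0, 250.0)

    def test_lf_band_power_matches_analytic_sinusoid(self, ctl_params):
        # independent oracle: periodogram band integral of the beat series
        params = replace(ctl_params, noise=NoiseLevels.zero())
        bundle = simulate_baseline_recording(params, 180.0, 250.0, seed=2)
        gt = bundle.ground_truth
        series = resample_beat_series(BeatSeries(gt["sbp_times"], gt["sbp_values"]))
        f, pxx = periodogram(series.values, series.fs)
        band = (f >= 0.15) & (f <= 0.6)
        power = np.trapezoid(pxx[band], f[band])
        assert power == pytest.approx(params.lf_amp_mmHg ** 2 / 2, rel=0.02)

    def test_band_confinement_at_zero_noise(self, ctl_params):
        params = replace(ctl_params, noise=NoiseLevels.zero())
        bundle = simulate_baseline_recording(params, 180.0, 250.0, seed=3)
        gt = bundle.ground_truth
        series = resample_beat_series(BeatSeries(gt["sbp_times"], gt["sbp_values"]))
        f, pxx = periodogram(series.values, series.fs)
        near = np.abs(f - params.lf_freq_Hz) <= 0.05
        away = (f > 0.05) & ~near
        ratio = np.trapezoid(pxx[away], f[away]) / np.trapezoid(pxx[near], f[near])
        assert ratio < 0.01


class TestProvocations:
    def test_zero_gain_keeps_hr_flat(self, ctl_params):
        params = replace(ctl_params, brg_bpm_per_mmHg=0.0, hf_amp_bpm=0.0,
                         noise=NoiseLevels.zero())
        bundle = simulate_phenylephrine_response(params, 40.0, 60.0, seed=1,
                                                 sampling_rate=250.0)
        gt = bundle.ground_truth
        assert np.ptp(gt["hr_values"]) < 1e-9

    def test_programmed_hr_fall(self, ctl_params):
        params = replace(ctl_params, hf_amp_bpm=0.0, noise=NoiseLevels.zero())
        bundle = simulate_phenylephrine_response(params, 40.0, 60.0, seed=1,
                                                 sampling_rate=250.0)
        gt = bundle.ground_truth
        fall = gt["hr_values"][0] - gt["hr_values"].min()
        assert fall == pytest.approx(0.28 * 40.0, rel=1e-3)  # 11.2 bpm

    def test_ramp_requires_positive_amplitude(self, ctl_params):
        with pytest.raises(ValidationError):
            simulate_phenylephrine_response(ctl_params, ramp_mmHg=-1.0)

    def test_lobeline_step_frequencies(self):
        params = replace(make_group_params("DOX8", seed=1), noise=NoiseLevels.zero())
        bundle = simulate_lobeline_response(params, seed=1, sampling_rate=250.0)
        assert bundle.event_time("lobeline") == pytest.approx(60.0)
        assert bundle.ground_truth["programmed_delta_rf"] == pytest.approx(12.5)

    def test_lobeline_equal_rates_gives_zero_delta(self, ctl_params):
        params = replace(ctl_params, rf_stim_cpm=ctl_params.rf_basal_cpm)
        bundle = simulate_lobeline_response(params, seed=1, sampling_rate=250.0)
        assert bundle.ground_truth["programmed_delta_rf"] == 0.0


class TestHistologyImages:
    def test_fraction_zero_has_no_collagen(self):
        _, truth = simulate_histology_image(0.0, 128, 128, seed=1)
        assert truth["collagen_mask"].sum() == 0

    def test_fraction_hundred_fills_tissue(self):
        _, truth = simulate_histology_image(100.0, 128, 128, seed=1)
        assert truth["collagen_mask"].sum() == truth["tissue_mask"].sum()

    def test_exact_pixel_count(self):
        _, truth = simulate_histology_image(65.8, 256, 256, seed=1)
        tissue = truth["tissue_mask"].sum()
        assert truth["collagen_mask"].sum() == int(np.floor(0.658 * tissue))

    def test_collagen_is_clustered_not_salt_and_pepper(self):
        # a clustered mask has far fewer connected components than pixels
        from scipy import ndimage

        _, truth = simulate_histology_image(30.0, 256, 256, seed=2)
        _, n_components = ndimage.label(truth["collagen_mask"])
        assert n_components < truth["collagen_mask"].sum() / 50

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            simulate_histology_image(101.0, 64, 64)


class TestCohort:
    def test_zero_sd_gives_identical_subjects(self):
        design = default_design(sd_scale=0.0)
        cohort = simulate_cohort(design, seed=0)
        ctl = [s.params for s in cohort.subjects if s.group == "CTL"]
        assert all(p.hr_bpm == ctl[0].hr_bpm for p in ctl)
        assert all(p.sbp_mmHg == ctl[0].sbp_mmHg for p in ctl)

    def test_group_means_within_two_sem(self):
        # sampling-distribution oracle: SD = SEM*sqrt(n) so the SE of the
        # cohort mean equals the printed SEM
        cohort = simulate_cohort(seed=11)
        for group in ("CTL", "DOX16"):
            params = [s.params for s in cohort.subjects if s.group == group]
            for var, attr in (("hr_bpm", "hr_bpm"), ("sbp_mmHg", "sbp_mmHg"),
                              ("collagen_fraction_pct", "collagen_fraction_pct")):
                mean, sem = GROUP_STATS[group][var]
                got = np.mean([getattr(p, attr) for p in params])
                # SD = SEM*sqrt(n), so the SE of the cohort mean is the SEM
                assert abs(got - mean) < 2.0 * sem

    def test_seeds_change_cohort(self):
        a = simulate_cohort(seed=1)
        b = simulate_cohort(seed=2)
        assert a.subjects[0].params.hr_bpm != b.subjects[0].params.hr_bpm

    def test_subject_seed_offsets(self):
        cohort = simulate_cohort(seed=100)
        seeds = [s.params.seed for s in cohort.subjects]
        assert seeds == list(range(100, 100 + len(seeds)))

    def test_negative_sd_falls_back_to_zero_with_warning(self):
        design = default_design()
        design.stats["CTL"]["hr_bpm"] = (379.0, -1.0)
        with pytest.warns(UserWarning, match="negative SD"):
            design.__post_init__()
        assert design.stats["CTL"]["hr_bpm"][1] == 0.0

    def test_catecholamine_table_shape(self):
        cohort = simulate_cohort(seed=0)
        table = catecholamine_table(cohort)
        assert len(table) == 3 * len(cohort.subjects)
        assert set(table["variable"]) == {"adrenaline", "noradrenaline", "dopamine"}

    def test_draw_respects_pressure_ordering(self):
        for seed in range(25):
            p = draw_subject_params("DOX20", default_design().stats["DOX20"], seed)
            assert p.sbp_mmHg > p.dbp_mmHg
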