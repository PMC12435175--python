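from dataclasses import replace

import numpy as np
import pytest

from ppgbp.cohort import (CohortConfig, CohortConfigurationError, MorphologyMap,
                          cohort_config_from_dict, cohort_config_to_dict,
                          decode_bp, detect_beat_minima, generate_cohort,
                          make_preset, measure_delay_ratio, noiseless_config,
                          sample_subject_profiles, synthesize_ppg_segment,
                          zscore)

MAP = MorphologyMap()


def clean_preset(**over):
    base = make_preset("vitaldb", segments_per_subject=3, segment_seconds=2.1)
    return replace(base, noise_sd=0.0, wander_amp=0.0, hr_jitter_sd=0.0,
                   bandpass_cutoff=55.0, **over)


class TestMorphologyMap:
    def test_delta_strictly_decreasing_in_sbp(self):
        sbp = np.arange(20.0, 261.0)
        d = MAP.delta_frac(sbp)
        assert (np.diff(d) < 0).all()

    def test_ratio_monotone_and_bounded(self):
        dbp = np.arange(20.0, 261.0)
        r = MAP.ratio(dbp)
        assert (np.diff(r) >= 0).all()
        assert r.min() >= MAP.r_min and r.max() <= MAP.r_max

    def test_pulses_stay_inside_beat(self):
        MAP.validate()  # raises if timing leaves the beat window

    def test_inverses(self):
        sbp = np.array([80.0, 120.0, 180.0])
        np.testing.assert_allclose(MAP.invert_delta(MAP.delta_frac(sbp)), sbp)
        dbp = np.array([50.0, 60.0, 90.0])
        np.testing.assert_allclose(MAP.invert_ratio(MAP.ratio(dbp)), dbp)


class TestSubjectProfiles:
    def test_zero_subjects(self):
        preset = replace(clean_preset(), n_subjects=0)
        assert sample_subject_profiles(preset, MAP,
                                       np.random.default_rng(0)) == []

    def test_pulse_pressure_floor(self):
        preset = replace(clean_preset(), n_subjects=200)
        profiles = sample_subject_profiles(preset, MAP, np.random.default_rng(1))
        assert all(p.sbp_setpoint - p.dbp_setpoint >= 15.0 for p in profiles)

    def test_setpoints_match_published_vital_stats(self):
        # emulated VitalDB labels: SBP 115.62 +- 18.92 mmHg
        preset = replace(clean_preset(), n_subjects=2000)
        profiles = sample_subject_profiles(preset, MAP, np.random.default_rng(2))
        sbp = np.array([p.sbp_setpoint for p in profiles])
        assert abs(sbp.mean() - 115.62) < 1.5
        assert abs(sbp.std() - 18.92) < 1.5


class TestSegmentSynthesis:
    def test_length_arithmetic(self):
        preset = clean_preset(segment_seconds=10.0)
        x = synthesize_ppg_segment(120, 60, 70, (0, 0), preset, MAP,
                                   np.random.default_rng(0))
        assert len(x) == 1250

    def test_invalid_bp_ordering(self):
        with pytest.raises(ValueError, match="exceed"):
            synthesize_ppg_segment(80, 90, 70, (0, 0), clean_preset(), MAP,
                                   np.random.default_rng(0))

    def test_ten_beats_at_60_bpm(self):
        preset = clean_preset(segment_seconds=10.0)
        x = synthesize_ppg_segment(120, 60, 60.0, (0, 0), preset, MAP,
                                   np.random.default_rng(0))
        assert len(detect_beat_minima(x, preset.fs)) == 10

    def test_measured_delay_matches_map(self):
        preset = clean_preset(segment_seconds=10.0)
        for sbp in (90.0, 120.0, 170.0):
            x = synthesize_ppg_segment(sbp, 60.0, 72.0, (0, 0), preset, MAP,
                                       np.random.default_rng(0))
            d_frac, _ = measure_delay_ratio(x, preset.fs, MAP)
            T = 60.0 / 72.0
            assert abs(d_frac - MAP.delta_frac(sbp)) * T * preset.fs < 1.0


class TestGenerateCohort:
    def test_counts(self):
        sites = (replace(clean_preset(), name="a", n_subjects=5,
                         segments_per_subject=4),
                 replace(clean_preset(), name="b", n_subjects=5,
                         segments_per_subject=4))
        store = generate_cohort(CohortConfig(sites=sites, seed=0))
        assert store.n == 40
        assert len(np.unique(store.subject_id)) == 10

    def test_determinism(self):
        cfg = noiseless_config(replace(clean_preset(), n_subjects=3), seed=5)
        assert generate_cohort(cfg).equals(generate_cohort(cfg))

    def test_label_distribution_fidelity(self):
        preset = replace(clean_preset(), n_subjects=400,
                         segments_per_subject=2)
        store = generate_cohort(CohortConfig(sites=(preset,), seed=3))
        # mean within 3 standard errors of the preset (between + within var)
        se = np.sqrt(preset.sbp_sd ** 2 / 400 + preset.within_sbp_sd ** 2 / store.n)
        assert abs(store.sbp.mean() - preset.sbp_mean) < 3 * 3 * se

    def test_tail_boost_inflates_tail_mass(self):
        preset = replace(clean_preset(), n_subjects=300, segments_per_subject=1)
        plain = generate_cohort(CohortConfig(sites=(preset,), seed=9))
        boosted = generate_cohort(CohortConfig(
            sites=(preset,), seed=9, tail_boost={preset.name: 0.35}))
        thresh = preset.sbp_mean + 2 * preset.sbp_sd
        assert (boosted.sbp >= thresh).mean() > (plain.sbp >= thresh).mean()

    def test_duplicate_site_names_rejected(self):
        cfg = CohortConfig(sites=(clean_preset(), clean_preset()))
        with pytest.raises(CohortConfigurationError, match="unique"):
            cfg.validate()

    def test_config_dict_roundtrip(self):
        cfg = CohortConfig(sites=(clean_preset(),), seed=11,
                           tail_boost={"vitaldb": 0.2})
        back = cohort_config_from_dict(cohort_config_to_dict(cfg))
        assert back == cfg


class TestInversionOracle:
    def test_noiseless_identifiability(self):
        cfg = noiseless_config(replace(clean_preset(), n_subjects=6), seed=2)
        store = generate_cohort(cfg)
        err_s, err_d = [], []
        for x, sbp, dbp in zip(store.signals, store.sbp, store.dbp):
            s, d = decode_bp(x, store.fs, cfg.morphology)
            err_s.append(abs(s - sbp))
            err_d.append(abs(d - dbp))
        assert np.mean(err_s) < 2.0
        assert np.mean(err_d) < 2.0

    def test_zscoring_preserves_shape_features(self):
        # delta/T and r are shape features: invariant to affine amplitude
        preset = clean_preset(segment_seconds=10.0)
        x = synthesize_ppg_segment(140, 75, 65.0, (0, 0), preset, MAP,
                                   np.random.default_rng(1))
        d1, r1 = measure_delay_ratio(x, preset.fs, MAP)
        d2, r2 = measure_delay_ratio(zscore(x), preset.fs, MAP)
        assert abs(d1 - d2) < 1e-4
        assert abs(r1 - r2) < 1e-3
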