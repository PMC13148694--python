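import numpy as np
import pandas as pd
import pytest

import actcalib as ac
from actcalib.simulate import (
    DEFAULT_PROTOCOL,
    DEVICE_SPECS,
    STRATA,
    TABLE_COEFFICIENTS,
)


class TestGenerateCohort:
    def test_sizes_and_ids(self, cohort56):
        assert len(cohort56) == 56
        assert sum(p.sex == "male" for p in cohort56) == 34
        assert sum(p.sex == "female" for p in cohort56) == 22
        assert len({p.id for p in cohort56}) == 56

    def test_deterministic(self):
        a = ac.generate_cohort(5, 5, seed=42)
        b = ac.generate_cohort(5, 5, seed=42)
        assert a == b
        c = ac.generate_cohort(5, 5, seed=43)
        assert a != c

    def test_age_bounds_respected(self, cohort56):
        for p in cohort56:
            assert 18.0 <= p.age <= 35.0
            assert p.body_mass_kg >= 35.0
            assert p.height_cm >= 120.0

    def test_too_small_cohort_raises(self):
        with pytest.raises(ValueError, match="too small"):
            ac.generate_cohort(1, 0, seed=0)
        with pytest.raises(ValueError, match="non-negative"):
            ac.generate_cohort(-1, 5, seed=0)

    def test_bmi_derived(self):
        p = ac.ParticipantProfile("X", "male", 25.0, 180.0, 81.0)
        assert p.bmi == pytest.approx(25.0)

    def test_invalid_profile_raises(self):
        with pytest.raises(ValueError, match="sex"):
            ac.ParticipantProfile("X", "other", 25.0, 180.0, 80.0)
        with pytest.raises(ValueError, match="mass"):
            ac.ParticipantProfile("X", "male", 25.0, 180.0, -1.0)


class TestTruthParameters:
    def test_defaults_are_published_lines(self, truth):
        for s in STRATA:
            assert truth.b0_true[s] == TABLE_COEFFICIENTS[s][0]
            assert truth.b1_true[s] == TABLE_COEFFICIENTS[s][1]

    def test_validation(self):
        with pytest.raises(ValueError, match="b1_true"):
            ac.TruthParameters(b1_true={s: 0.0 for s in STRATA})
        with pytest.raises(ValueError, match="residual_sd"):
            ac.TruthParameters(residual_sd_sqrt_met=-0.1)
        with pytest.raises(ValueError, match="errant_breath_rate"):
            ac.TruthParameters(errant_breath_rate=1.5)

    def test_between_sd_grows_with_speed(self, truth):
        assert truth.between_sd(9.0) > truth.between_sd(0.0)


class TestObservationTable:
    def test_shape_and_columns(self, obs56):
        assert len(obs56) == 56 * 5 * 4
        assert tuple(obs56.columns) == ac.OBSERVATION_COLUMNS
        assert set(obs56["stratum"]) == set(STRATA)
        assert (obs56["activity_cpm"] >= 0).all()
        assert (obs56["met"] > 0).all()

    def test_deterministic_in_seed(self, cohort56, truth):
        a = ac.simulate_observation_table(cohort56, truth, seed=9)
        b = ac.simulate_observation_table(cohort56, truth, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = ac.simulate_observation_table(cohort56, truth, seed=10)
        assert not a["met"].equals(c["met"])

    def test_noise_free_rows_sit_on_true_lines(self, cohort56):
        """With all noise off, every row satisfies sqrt(MET) = b0 + b1*sqrt(cpm)
        exactly (up to clamping at zero counts)."""
        truth = ac.TruthParameters(
            residual_sd_sqrt_met=0.0, between_sd_base=0.0, between_sd_per_kmh=0.0
        )
        obs = ac.simulate_observation_table(cohort56[:4], truth, seed=0)
        for row in obs.itertuples():
            b0, b1 = TABLE_COEFFICIENTS[row.stratum]
            if row.activity_cpm > 0:
                pred = (b0 + b1 * np.sqrt(row.activity_cpm)) ** 2
                assert pred == pytest.approx(row.met, rel=1e-12)
            else:
                # clamped: latent intensity at/below the line's intercept
                assert np.sqrt(row.met) <= b0 + 1e-12
        # at each speed the noise-free MET is the programmed value
        for speed, met in truth.met_by_speed.items():
            sub = obs[obs["speed"] == speed]
            assert np.allclose(sub["met"], met)

    def test_residual_mode_shared_repeats_met_within_cluster(self, cohort56, truth):
        obs = ac.simulate_observation_table(
            cohort56[:4], truth, seed=5, residual_mode="shared"
        )
        per_cluster = obs.groupby(["participant", "condition"])["met"].nunique()
        assert (per_cluster == 1).all()
        with pytest.raises(ValueError, match="residual_mode"):
            ac.simulate_observation_table(cohort56[:4], truth, seed=5, residual_mode="x")

    def test_counts_increase_with_speed(self, obs56):
        means = obs56.groupby(["stratum", "speed"])["activity_cpm"].mean()
        for s in STRATA:
            assert means[s].is_monotonic_increasing


class TestRawAcceleration:
    def test_shape_rate_and_determinism(self):
        p = ac.ParticipantProfile("X", "male", 25.0, 175.0, 70.0)
        cond = ac.ProtocolCondition("walk5", 5.0, duration_s=60.0)
        spec = DEVICE_SPECS["GT3X_hip"]
        raw1 = ac.simulate_raw_acceleration(p, cond, spec, seed=3)
        raw2 = ac.simulate_raw_acceleration(p, cond, spec, seed=3)
        assert raw1.xyz.shape == (int(60 * spec.sampling_rate_hz), 3)
        np.testing.assert_array_equal(raw1.xyz, raw2.xyz)

    def test_dynamic_range_enforced(self):
        p = ac.ParticipantProfile("X", "male", 25.0, 175.0, 70.0)
        cond = ac.ProtocolCondition("run9", 9.0, duration_s=30.0)
        spec = DEVICE_SPECS["ACTT_wrist"]
        raw = ac.simulate_raw_acceleration(p, cond, spec, seed=1, amplitude_g=10.0)
        assert np.abs(raw.xyz).max() <= 4.0
        nz = raw.xyz[raw.xyz != 0.0]
        assert np.abs(nz).min() >= 0.03  # deadband

    def test_rest_is_low_amplitude(self):
        p = ac.ParticipantProfile("X", "female", 25.0, 165.0, 60.0)
        cond = ac.ProtocolCondition("rest", 0.0, duration_s=30.0)
        raw = ac.simulate_raw_acceleration(p, cond, DEVICE_SPECS["GT3X_hip"], seed=1)
        assert np.abs(raw.xyz).max() < 0.1


class TestEmulateCounts:
    def _raw(self, spec, amplitude_g, duration_s=60.0, noise=0.0):
        p = ac.ParticipantProfile("X", "male", 25.0, 175.0, 70.0)
        cond = ac.ProtocolCondition("walk5", 5.0, duration_s=duration_s)
        return ac.simulate_raw_acceleration(
            p, cond, spec, seed=7, amplitude_g=amplitude_g, sensor_noise_g=noise
        )

    def test_epoch_count_and_nonnegative(self):
        spec = DEVICE_SPECS["GT3X_hip"]
        epochs = ac.emulate_counts(self._raw(spec, 0.5))
        assert len(epochs.counts) == 60
        assert (epochs.counts >= 0).all()
        assert epochs.stratum == "GT3X_hip"

    def test_linear_in_amplitude_away_from_limits(self):
        """Filter + rectify + integrate is homogeneous of degree 1 in the
        (noise-free, unclipped) waveform amplitude."""
        spec = DEVICE_SPECS["GT3X_hip"]
        c1 = ac.emulate_counts(self._raw(spec, 0.3)).counts.sum()
        c2 = ac.emulate_counts(self._raw(spec, 0.6)).counts.sum()
        assert c2 == pytest.approx(2.0 * c1, rel=1e-9)

    def test_too_short_series_raises(self):
        spec = DEVICE_SPECS["GT3X_hip"]
        raw = self._raw(spec, 0.3, duration_s=0.5)
        with pytest.raises(ValueError, match="shorter than one epoch"):
            ac.emulate_counts(raw)

    def test_device_spec_validation(self):
        with pytest.raises(ValueError, match="count_mode"):
            ac.DeviceSpec("GT3X", "hip", 30.0, (0.0, 6.0), (0.25, 2.5), "PIM")
        with pytest.raises(ValueError, match="band_pass"):
            ac.DeviceSpec("GT3X", "hip", 30.0, (0.0, 6.0), (2.5, 0.25), "VM")


class TestSimulateBreaths:
    def test_noise_free_plateau_is_exact_in_central_window(self):
        p = ac.ParticipantProfile("X", "male", 25.0, 175.0, 70.0)
        cond = DEFAULT_PROTOCOL[2]  # walk5, 600 s
        truth = ac.TruthParameters(breath_noise_cv=0.0, errant_breath_rate=0.0)
        b = ac.simulate_breaths(p, cond, truth, seed=1)
        target = truth.met_by_speed[5.0] * ac.VO2_PER_MET * p.body_mass_kg
        t = np.asarray(b.time_s)
        central = (t >= 180.0) & (t < 420.0)
        assert central.sum() > 100
        np.testing.assert_allclose(b.vo2_ml_min[central], target, rtol=1e-12)

    def test_onkinetics_rise(self):
        p = ac.ParticipantProfile("X", "male", 25.0, 175.0, 70.0)
        truth = ac.TruthParameters(breath_noise_cv=0.0, errant_breath_rate=0.0)
        b = ac.simulate_breaths(p, DEFAULT_PROTOCOL[4], truth, seed=1)  # run9
        early = b.vo2_ml_min[np.asarray(b.time_s) < 30.0]
        late = b.vo2_ml_min[np.asarray(b.time_s) >= 180.0]
        assert early.mean() < late.mean()

    def test_times_increasing_and_deterministic(self, truth):
        p = ac.ParticipantProfile("X", "female", 25.0, 165.0, 60.0)
        b1 = ac.simulate_breaths(p, DEFAULT_PROTOCOL[0], truth, seed=11)
        b2 = ac.simulate_breaths(p, DEFAULT_PROTOCOL[0], truth, seed=11)
        assert (np.diff(b1.time_s) > 0).all()
        np.testing.assert_array_equal(b1.vo2_ml_min, b2.vo2_ml_min)

    def test_breath_rate_scales_with_intensity(self, truth):
        p = ac.ParticipantProfile("X", "male", 25.0, 175.0, 70.0)
        rest = ac.simulate_breaths(p, DEFAULT_PROTOCOL[0], truth, seed=2)
        run = ac.simulate_breaths(p, DEFAULT_PROTOCOL[4], truth, seed=2)
        assert len(run.time_s) > 2 * len(rest.time_s)


class TestWriteCohortDataset:
    def test_manifest_and_files(self, raw_dataset):
        out, cohort, truth, manifest = raw_dataset
        assert (out / "participants.csv").exists()
        assert (out / "truth.yaml").exists()
        assert (out / "manifest.json").exists()
        # 4 participants x 5 conditions breaths; x4 strata epochs
        assert len(list((out / "breaths").glob("*.csv"))) == 20
        assert len(list((out / "epochs").glob("*.csv"))) == 80
        assert len(manifest["files"]) == 102

    def test_checksums_match_files(self, raw_dataset):
        import hashlib

        out, _, _, manifest = raw_dataset
        for path, checksum in list(manifest["files"].items())[:5]:
            digest = hashlib.sha256((out / path).read_bytes()).hexdigest()
            assert digest == checksum

    def test_rewrite_is_byte_identical(self, raw_dataset, tmp_path):
        out, cohort, truth, manifest = raw_dataset
        manifest2 = ac.write_cohort_dataset(cohort, truth, tmp_path / "copy")
        assert manifest["files"] == manifest2["files"]
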