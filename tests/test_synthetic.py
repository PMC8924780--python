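"""Ground-truth generator: trajectory shape, beat consistency, device model."""

import numpy as np
import pytest

from hrval.synthetic import (
    DeviceErrorModel,
    Malfunction,
    Protocol,
    ProtocolSegment,
    RealizedHR,
    SubjectParams,
    TruthTrajectory,
    apply_device_model,
    default_exclusion_scenario,
    default_protocol,
    generate_cohort,
    generate_truth,
    synthesize_ecg,
)


class TestTruth:
    def test_constant_target_yields_metronome_beats(self, flat60_protocol, quiet_subject):
        truth, beats = generate_truth(flat60_protocol, quiet_subject)
        assert np.allclose(truth.values, 60.0)
        assert np.allclose(beats.rr_intervals, 1.0)
        assert truth.mask.all()

    def test_deterministic_given_seed(self, two_step_protocol):
        subj = SubjectParams(baseline_hr=65, hrv_sd_ms=25.0, seed=123)
        t1, b1 = generate_truth(two_step_protocol, subj)
        t2, b2 = generate_truth(two_step_protocol, subj)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(b1.peak_times, b2.peak_times)

    def test_exponential_approach_reaches_target(self, two_step_protocol, quiet_subject):
        # tau = 10 s, segment 2 lasts 120 s: the last 30 s are > 9 tau in,
        # so the mean must sit within 1 bpm of the 120 bpm target
        traj = TruthTrajectory(two_step_protocol, quiet_subject)
        tail = traj.hr_at(np.arange(150.0, 180.0))
        assert abs(tail.mean() - 120.0) < 1.0

    def test_beat_hr_consistency_without_jitter(self, two_step_protocol, quiet_subject):
        _, beats = generate_truth(two_step_protocol, quiet_subject)
        traj = TruthTrajectory(two_step_protocol, quiet_subject)
        inst = 60.0 / beats.rr_intervals
        at_beats = traj.hr_at(beats.peak_times[:-1])
        assert np.max(np.abs(inst - at_beats)) < 0.1

    def test_out_of_range_trajectory_rejected(self):
        proto = Protocol(segments=(ProtocolSegment("sprint", 60.0, 219.0),))
        subj = SubjectParams(baseline_hr=40.0, hr_response_tau=5.0)
        # fine: stays inside [30, 220]
        TruthTrajectory(proto, subj)
        with pytest.raises(ValueError, match="target_hr"):
            Protocol(segments=(ProtocolSegment("impossible", 60.0, 230.0),))

    def test_protocol_invariants(self):
        with pytest.raises(ValueError, match="unique"):
            Protocol(
                segments=(
                    ProtocolSegment("a", 10.0, 60.0),
                    ProtocolSegment("a", 10.0, 70.0),
                )
            )
        with pytest.raises(ValueError, match="duration"):
            Protocol(segments=(ProtocolSegment("a", 0.0, 60.0),))

    def test_default_protocol_escalates_then_relaxes(self):
        proto = default_protocol()
        assert len(proto.segments) == 10
        targets = [s.target_hr for s in proto.segments]
        # exercise block rises monotonically; final rest relaxes
        assert targets[4] < targets[6] < targets[7] < targets[8]
        assert targets[9] < targets[8]
        assert proto.total_duration_s == pytest.approx(
            60 * (2 + 1.5 + 1.5 + 1.5 + 1 + 1 + 2 + 1.5 + 1.5 + 1.5)
        )


class TestDeviceModel:
    def _realized(self, protocol, subject):
        _, beats = generate_truth(protocol, subject)
        traj = TruthTrajectory(protocol, subject)
        return RealizedHR(traj, beats)

    def test_identity_model_reproduces_truth(self, two_step_protocol, quiet_subject):
        truth = self._realized(two_step_protocol, quiet_subject)
        stream = apply_device_model(truth, DeviceErrorModel(), seed=0)
        assert np.allclose(stream.t_s, np.arange(180.0))
        assert np.allclose(stream.hr_bpm, truth.hr_at(np.arange(180.0)))

    def test_pure_bias_adds_exactly(self, two_step_protocol, quiet_subject):
        truth = self._realized(two_step_protocol, quiet_subject)
        stream = apply_device_model(
            truth, DeviceErrorModel(bias_bpm=5.0), seed=0
        )
        assert np.allclose(stream.hr_bpm - truth.hr_at(stream.t_s), 5.0)

    def test_flatline_malfunction_overrides_window(self, two_step_protocol, quiet_subject):
        truth = self._realized(two_step_protocol, quiet_subject)
        mf = Malfunction(mode="flatline", start_s=0.0, end_s=120.0, level_bpm=146.0)
        stream = apply_device_model(
            truth, DeviceErrorModel(malfunction=mf), seed=0
        )
        in_win = stream.t_s <= 120.0
        assert np.all(stream.hr_bpm[in_win] == 146.0)
        assert not np.any(stream.hr_bpm[~in_win] == 146.0)

    def test_excess_malfunction_bounded_around_level(self, two_step_protocol, quiet_subject):
        truth = self._realized(two_step_protocol, quiet_subject)
        mf = Malfunction(mode="excess", start_s=0.0, end_s=180.0, level_bpm=150.0)
        stream = apply_device_model(truth, DeviceErrorModel(malfunction=mf), seed=1)
        assert np.all(np.abs(stream.hr_bpm - 150.0) <= 40.0 + 1e-9)

    def test_sparse_gap_law(self, two_step_protocol, quiet_subject):
        truth = self._realized(two_step_protocol, quiet_subject)
        model = DeviceErrorModel(
            sampling_mode="sparse", min_interval_s=1.0, max_interval_s=5.0
        )
        for seed in range(5):
            gaps = np.diff(apply_device_model(truth, model, seed=seed).t_s)
            assert np.all(gaps >= 1.0) and np.all(gaps <= 5.0)

    def test_lag_exceeding_span_rejected(self, flat60_protocol, quiet_subject):
        truth = self._realized(flat60_protocol, quiet_subject)
        with pytest.raises(ValueError, match="lag"):
            apply_device_model(truth, DeviceErrorModel(lag_s=61.0), seed=0)

    def test_bias_recoverable_from_long_constant_run(self):
        # parameter-recovery hook: sample mean of (device - truth) -> bias
        proto = Protocol(segments=(ProtocolSegment("steady", 3000.0, 70.0),))
        subj = SubjectParams(baseline_hr=70.0, hrv_sd_ms=0.0, seed=0)
        truth = self._realized(proto, subj)
        model = DeviceErrorModel(bias_bpm=-2.0, noise_sd_bpm=4.0)
        stream = apply_device_model(truth, model, seed=3)
        err = stream.hr_bpm - truth.hr_at(stream.t_s)
        n = len(err)
        assert abs(err.mean() - (-2.0)) < 3 * 4.0 / np.sqrt(n)

    def test_dropout_thins_stream(self, two_step_protocol, quiet_subject):
        truth = self._realized(two_step_protocol, quiet_subject)
        full = apply_device_model(truth, DeviceErrorModel(), seed=0)
        thin = apply_device_model(
            truth, DeviceErrorModel(dropout_prob=0.5), seed=0
        )
        assert 0 < len(thin) < len(full)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DeviceErrorModel(noise_sd_bpm=-1.0)
        with pytest.raises(ValueError):
            DeviceErrorModel(dropout_prob=1.0)
        with pytest.raises(ValueError):
            DeviceErrorModel(sampling_mode="sparse", min_interval_s=0.5)


class TestCohort:
    def test_cohort_counts_and_determinism(self, two_device_models):
        c1 = generate_cohort(3, two_device_models, master_seed=9)
        c2 = generate_cohort(3, two_device_models, master_seed=9)
        assert len(c1) == 3
        for r1, r2 in zip(c1, c2):
            assert len(r1.annotations) == 10
            assert r1.annotations.equals(r2.annotations)
            assert np.array_equal(r1.beats.peak_times, r2.beats.peak_times)
            for d in two_device_models:
                assert np.array_equal(
                    r1.device_streams[d].hr_bpm, r2.device_streams[d].hr_bpm
                )

    def test_single_subject_matches_manual_path(self, two_device_models):
        subj = SubjectParams(baseline_hr=72.0, hr_response_tau=12.0,
                             hrv_sd_ms=15.0, seed=99)
        rec = generate_cohort(
            1, two_device_models, master_seed=1, subjects=[subj]
        )[0]
        truth, beats = generate_truth(default_protocol(), subj)
        assert np.array_equal(rec.beats.peak_times, beats.peak_times)
        assert np.allclose(rec.truth_hr.values, truth.values)

    def test_exclusion_scenario_shape(self):
        scen = default_exclusion_scenario()
        assert len(scen) == 23
        fully_excluded = [
            pid for pid, st in scen.items() if all(s == "excluded" for s in st)
        ]
        assert len(fully_excluded) == 3

    def test_device_override_applies_to_one_subject(self, two_device_models):
        mf = Malfunction(mode="flatline", start_s=0.0, end_s=400.0, level_bpm=146.0)
        bad = DeviceErrorModel(
            sampling_mode="uniform", rate_hz=1.0, malfunction=mf
        )
        cohort = generate_cohort(
            2, two_device_models, master_seed=4,
            device_overrides={("p02", "watch"): bad},
        )
        w1 = cohort[0].device_streams["watch"].hr_bpm
        w2 = cohort[1].device_streams["watch"].hr_bpm
        assert not np.any(w1 == 146.0)
        assert np.all(w2[cohort[1].device_streams["watch"].t_s <= 400.0] == 146.0)


class TestEcgSynthesis:
    def test_trace_peaks_at_beats_without_noise(self):
        from hrval.series import BeatSequence

        beats = BeatSequence(peak_times=np.array([1.0, 2.0, 3.0]))
        t, mv = synthesize_ecg(beats, rate_hz=256.0, snr_db=None)
        for b in beats.peak_times:
            w = (t > b - 0.4) & (t < b + 0.4)
            apex = t[w][np.argmax(mv[w])]
            assert abs(apex - b) <= 1.0 / 256.0
        assert t[-1] >= beats.peak_times[-1] + 1.0 - 1.0 / 256.0

    def test_empty_beats_rejected(self):
        from hrval.series import BeatSequence

        with pytest.raises(ValueError, match="empty"):
            synthesize_ecg(BeatSequence(peak_times=np.array([])), 256.0)

    def test_low_rate_rejected(self):
        from hrval.series import BeatSequence

        with pytest.raises(ValueError, match="rate"):
            synthesize_ecg(BeatSequence(peak_times=np.array([1.0, 2.0])), 100.0)
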