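import numpy as np
import pytest

from ecgdesk import SyntheticSpec, clean, generate
from ecgdesk.delineation import (
    BeatAnnotation,
    WaveAnnotationSet,
    compute_average_beat,
    compute_hrv,
    compute_measurements,
    delineate_waves,
    detect_qrs,
    rr_scatter,
)
from ecgdesk.errors import InsufficientDataError, NoSignalError

from conftest import FS


def _cleaned(lr):
    return clean(lr.record)


class TestDetectQRS:
    def test_60bpm_count_and_accuracy(self, normal_recording):
        peaks = detect_qrs(_cleaned(normal_recording))
        truth = normal_recording.ground_truth.beat_times
        assert abs(len(peaks) - 30) <= 1
        det = peaks / FS
        for t in truth:
            assert np.min(np.abs(det - t)) <= 0.05

    def test_all_zero_raises(self, zero_record):
        with pytest.raises(NoSignalError):
            detect_qrs(zero_record)

    def test_empty_flag_raises(self, normal_recording):
        with pytest.raises(NoSignalError):
            detect_qrs(normal_recording.record.with_flags("empty"))

    def test_too_short_raises(self, normal_recording):
        short = normal_recording.record.with_samples(
            normal_recording.record.samples[: int(2 * FS)]
        )
        with pytest.raises(InsufficientDataError):
            detect_qrs(short)

    def test_120bpm_count(self):
        lr = generate(SyntheticSpec(duration=30.0, heart_rate=120.0, seed=3))
        peaks = detect_qrs(_cleaned(lr))
        assert abs(len(peaks) - 60) <= 2

    def test_refractory_period(self, normal_recording):
        peaks = detect_qrs(_cleaned(normal_recording))
        assert np.all(np.diff(peaks) >= 0.2 * FS)


class TestDelineateWaves:
    def test_p_peak_accuracy(self, normal_recording):
        rec = _cleaned(normal_recording)
        ann = delineate_waves(rec, detect_qrs(rec))
        truth = normal_recording.ground_truth.beats
        hits = 0
        for beat, tb in zip(ann.beats, truth):
            if beat.has_p and tb.p_peak is not None:
                assert abs(beat.p_peak / FS - tb.p_peak) <= 0.04
                hits += 1
        assert hits >= 0.9 * len(truth)

    def test_af_like_has_no_p(self):
        lr = generate(SyntheticSpec(duration=30.0, heart_rate=90.0, seed=4,
                                    rhythm="irregular_af_like"))
        rec = _cleaned(lr)
        ann = delineate_waves(rec, detect_qrs(rec))
        absent = sum(1 for b in ann.beats if not b.has_p)
        assert absent >= 0.8 * len(ann.beats)

    def test_ordering_invariant(self, noisy_recording):
        rec = _cleaned(noisy_recording)
        ann = delineate_waves(rec, detect_qrs(rec))
        for b in ann.beats:
            assert b.qrs_onset <= b.qrs_peak <= b.qrs_offset
            if b.has_p:
                assert b.p_onset <= b.p_peak <= b.p_offset <= b.qrs_onset
            if b.has_t:
                assert b.qrs_offset <= b.t_onset <= b.t_peak <= b.t_offset

    def test_needs_two_peaks(self, normal_recording):
        with pytest.raises(InsufficientDataError):
            delineate_waves(_cleaned(normal_recording), [100])


def _two_beat_annotations(rr_samples, qt_samples, fs):
    """Hand-built annotation pair with a known RR and QT."""
    beats = []
    for i, r in enumerate([0, rr_samples]):
        beats.append(
            BeatAnnotation(
                beat_index=i,
                qrs_onset=r,
                qrs_peak=r + 2,
                qrs_offset=r + 10,
                t_onset=r + qt_samples - 20,
                t_peak=r + qt_samples - 10,
                t_offset=r + qt_samples,
            )
        )
    return WaveAnnotationSet(beats=beats, sampling_rate=fs)


class TestMeasurements:
    def test_qtc_identity_at_rr_one_second(self):
        # QT 0.36 s with RR 1.0 s: Bazett leaves QT unchanged.
        ann = _two_beat_annotations(rr_samples=1000, qt_samples=360, fs=1000.0)
        rep = compute_measurements(ann)
        assert rep.summary()["qtc_interval_ms"] == pytest.approx(360.0)

    def test_qtc_bazett_exact(self):
        # QT 0.30 s, RR 0.64 s -> 0.30 / sqrt(0.64) = 0.375 s.
        ann = _two_beat_annotations(rr_samples=640, qt_samples=300, fs=1000.0)
        rep = compute_measurements(ann)
        assert rep.summary()["qtc_interval_ms"] == pytest.approx(375.0)

    def test_ventricular_rate_from_constant_rr(self):
        ann = _two_beat_annotations(rr_samples=500, qt_samples=300, fs=1000.0)
        rep = compute_measurements(ann)
        assert rep.ventricular_rate_bpm == pytest.approx(120.0)

    def test_atrial_rate_absent_without_p(self):
        ann = _two_beat_annotations(rr_samples=1000, qt_samples=360, fs=1000.0)
        assert compute_measurements(ann).atrial_rate_bpm is None

    def test_insufficient_beats(self):
        ann = WaveAnnotationSet(
            beats=[BeatAnnotation(0, 0, 2, 10)], sampling_rate=125.0
        )
        with pytest.raises(InsufficientDataError):
            compute_measurements(ann)

    def test_recovery_against_generator(self, normal_recording):
        rec = _cleaned(normal_recording)
        ann = delineate_waves(rec, detect_qrs(rec))
        s = compute_measurements(ann).summary()
        truth = normal_recording.ground_truth.beats
        tru_pr = np.nanmedian(
            [(b.qrs_onset - b.p_onset) * 1000 for b in truth if b.p_onset]
        )
        tru_qrs = np.nanmedian([(b.qrs_offset - b.qrs_onset) * 1000 for b in truth])
        tru_qt = np.nanmedian(
            [(b.t_offset - b.qrs_onset) * 1000 for b in truth if b.t_offset]
        )
        assert abs(s["pr_interval_ms"] - tru_pr) <= 20
        assert abs(s["qrs_interval_ms"] - tru_qrs) <= 20
        assert abs(s["qt_interval_ms"] - tru_qt) <= 20
        assert abs(s["ventricular_rate_bpm"] - 60.0) <= 2


class TestAverageBeat:
    def test_identical_beats_average_to_one_beat(self):
        fs = 125.0
        beat = np.exp(-0.5 * ((np.arange(100) - 37.5) / 3.0) ** 2)
        x = np.tile(beat, 10)
        from ecgdesk import ECGRecord

        rec = ECGRecord(samples=x, sampling_rate=fs)
        peaks = np.argmax(beat) + 100 * np.arange(10)
        ann = WaveAnnotationSet(
            beats=[BeatAnnotation(i, int(p) - 2, int(p), int(p) + 2)
                   for i, p in enumerate(peaks)],
            sampling_rate=fs,
        )
        avg = compute_average_beat(rec, ann)
        pre = avg.pre_samples
        ref = x[int(peaks[4]) - pre : int(peaks[4]) + int(0.5 * fs)]
        assert np.allclose(avg.template, ref, atol=1e-12)

    def test_noise_reduction_rate(self):
        # Averaging n noisy copies reduces noise RMS like sigma / sqrt(n).
        fs, n_beats, sigma = 125.0, 50, 0.05
        rng = np.random.default_rng(0)
        beat = np.exp(-0.5 * ((np.arange(100) - 37.5) / 3.0) ** 2)
        x = np.tile(beat, n_beats) + rng.normal(0, sigma, 100 * n_beats)
        from ecgdesk import ECGRecord

        rec = ECGRecord(samples=x, sampling_rate=fs)
        peaks = np.argmax(beat) + 100 * np.arange(n_beats)
        ann = WaveAnnotationSet(
            beats=[BeatAnnotation(i, int(p) - 2, int(p), int(p) + 2)
                   for i, p in enumerate(peaks)],
            sampling_rate=fs,
        )
        avg = compute_average_beat(rec, ann)
        pre = avg.pre_samples
        clean_ref = np.tile(beat, n_beats)[
            int(peaks[4]) - pre : int(peaks[4]) + int(0.5 * fs)
        ]
        rms_dev = np.sqrt(np.mean((avg.template - clean_ref) ** 2))
        assert rms_dev <= 3 * sigma / np.sqrt(avg.n_beats)

    def test_four_beats_error(self, normal_recording):
        rec = _cleaned(normal_recording)
        peaks = detect_qrs(rec)[:4]
        ann = WaveAnnotationSet(
            beats=[BeatAnnotation(i, int(p) - 2, int(p), int(p) + 2)
                   for i, p in enumerate(peaks)],
            sampling_rate=FS,
        )
        with pytest.raises(InsufficientDataError):
            compute_average_beat(rec, ann)


class TestHRV:
    def test_constant_rr(self):
        peaks = np.arange(10) * 100.0
        h = compute_hrv(peaks, 125.0)
        assert h.sdnn == 0.0 and h.rmssd == 0.0 and h.pnn50 == 0.0

    def test_alternating_rr(self):
        rr = np.array([0.8, 0.6] * 10)
        peaks = np.concatenate(([0.0], np.cumsum(rr))) * 125.0
        h = compute_hrv(peaks, 125.0)
        assert h.rmssd == pytest.approx(0.2)
        assert h.pnn50 == pytest.approx(1.0)

    def test_sdnn_sampling_distribution(self):
        rng = np.random.default_rng(5)
        rr = rng.normal(0.8, 0.05, 300)
        peaks = np.concatenate(([0.0], np.cumsum(rr))) * 125.0
        h = compute_hrv(peaks, 125.0)
        assert 0.04 <= h.sdnn <= 0.06

    def test_brute_force_agreement(self):
        # Independent loop-based recomputation of the three formulas.
        rng = np.random.default_rng(6)
        rr = rng.uniform(0.5, 1.2, 100)
        peaks = np.concatenate(([0.0], np.cumsum(rr))) * 125.0
        h = compute_hrv(peaks, 125.0)
        rr2 = [(peaks[i + 1] - peaks[i]) / 125.0 for i in range(len(peaks) - 1)]
        mean = sum(rr2) / len(rr2)
        sdnn = (sum((v - mean) ** 2 for v in rr2) / (len(rr2) - 1)) ** 0.5
        diffs = [rr2[i + 1] - rr2[i] for i in range(len(rr2) - 1)]
        rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
        pnn50 = sum(1 for d in diffs if abs(d) > 0.05) / len(diffs)
        assert h.mean_rr == pytest.approx(mean, rel=1e-9)
        assert h.sdnn == pytest.approx(sdnn, rel=1e-9)
        assert h.rmssd == pytest.approx(rmssd, rel=1e-9)
        assert h.pnn50 == pytest.approx(pnn50, rel=1e-9)

    def test_insufficient_peaks(self):
        with pytest.raises(InsufficientDataError):
            compute_hrv([0, 100], 125.0)


class TestRRScatter:
    def test_unit_intervals(self):
        s = rr_scatter(np.array([0.0, 1.0, 2.0, 3.0]) * 125.0, 125.0)
        assert np.allclose(s.points, [[1.0, 1.0], [1.0, 1.0]])

    def test_constant_rr_on_diagonal(self):
        s = rr_scatter(np.arange(8) * 100.0, 125.0)
        assert np.allclose(s.points[:, 0], s.points[:, 1])

    def test_count_identity(self):
        for n in (3, 5, 17):
            s = rr_scatter(np.arange(n) * 100.0, 125.0)
            assert len(s.points) == n - 2

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            rr_scatter([0.0, 100.0], 125.0)
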