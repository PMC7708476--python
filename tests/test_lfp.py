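"""LFP featurization, perceptron classification, event detection."""

import numpy as np
import pytest

from lerens import (
    LERParams,
    SessionConfig,
    sample_ler,
    render_session,
    frame_spectra,
    one_over_f_correct,
    perceptron_fit,
    refine_interactive,
    detect_ieds,
    ied_rate,
    detect_spwr,
)
from lerens.lfp import EventSet, SpectrumMatrix, save_events, load_events
from lerens.session import Session

from conftest import make_noise_session


def tone_session(freq=200.0, lfp_rate=1250.0, n_frames=100,
                 samples_per_frame=83, amplitude=1.0, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    n = n_frames * samples_per_frame
    t = np.arange(n) / lfp_rate
    lfp = amplitude * np.sin(2 * np.pi * freq * t) + \
        noise * rng.standard_normal(n)
    return Session(
        dff=np.zeros((1, n_frames)),
        lfp=lfp,
        frame_bounds=np.arange(n_frames + 1, dtype=np.int64) * samples_per_frame,
        labels=np.asarray(["mGC"], dtype=object),
        speed=np.zeros(n_frames),
        frame_rate=lfp_rate / samples_per_frame,
        lfp_rate=lfp_rate,
    )


class TestFrameSpectra:
    def test_pure_tone_peaks_at_its_bin_every_frame(self):
        s = tone_session(freq=200.0)
        spec = frame_spectra(s)
        peak_bins = spec.values.argmax(axis=1)
        expected = np.argmin(np.abs(spec.freqs - 200.0))
        assert np.all(peak_bins == expected)

    def test_zero_signal_gives_zero_spectra(self):
        s = tone_session(amplitude=0.0)
        assert np.all(frame_spectra(s).values == 0)

    def test_white_noise_mean_spectrum_flat(self):
        s = tone_session(amplitude=0.0, noise=1.0, n_frames=1000)
        mean_spec = frame_spectra(s).values.mean(axis=0)
        assert mean_spec.max() / mean_spec.min() < 1.5

    def test_phase_invariance_under_circular_shift(self):
        s = tone_session(freq=150.0, noise=0.5)
        spec = frame_spectra(s)
        shifted = s.lfp.reshape(-1, 83)
        shifted = np.roll(shifted, 17, axis=1).ravel()
        s2 = Session(dff=s.dff, lfp=shifted, frame_bounds=s.frame_bounds,
                     labels=s.labels, speed=s.speed,
                     frame_rate=s.frame_rate, lfp_rate=s.lfp_rate)
        np.testing.assert_allclose(frame_spectra(s2).values, spec.values,
                                   atol=1e-9)

    def test_alignment_beyond_lfp_rejected(self):
        # the container itself refuses an alignment past the LFP extent
        s = tone_session()
        with pytest.raises(ValueError, match="alignment"):
            Session(dff=s.dff, lfp=s.lfp[:-10], frame_bounds=s.frame_bounds,
                    labels=s.labels, speed=s.speed, frame_rate=s.frame_rate,
                    lfp_rate=s.lfp_rate)


class TestOneOverFCorrect:
    def test_inverse_frequency_magnitude_becomes_constant(self):
        freqs = np.linspace(10, 500, 50)
        spec = SpectrumMatrix(values=np.tile(1.0 / freqs, (4, 1)),
                              freqs=freqs, frame_indices=np.arange(4))
        out = one_over_f_correct(spec)
        np.testing.assert_allclose(out.values, 1.0, atol=1e-9)

    def test_dc_bin_rejected(self):
        spec = SpectrumMatrix(values=np.ones((2, 3)),
                              freqs=np.asarray([0.0, 1.0, 2.0]),
                              frame_indices=np.arange(2))
        pytest.raises(ValueError, one_over_f_correct, spec)

    def test_pink_noise_corrected_power_is_flat(self):
        params = LERParams(K=2, N=4, M=10)
        gt = sample_ler(params, seed=0, n_frames=520)
        s = render_session(gt, SessionConfig(seed=1, ied_amplitude=0.0,
                                             duration=520 / 15.0))
        spec = frame_spectra(s)
        power = SpectrumMatrix(values=spec.values ** 2, freqs=spec.freqs,
                               frame_indices=spec.frame_indices)
        corrected = one_over_f_correct(power).values[:500].mean(axis=0)
        slope = np.polyfit(np.log(spec.freqs), np.log(corrected), 1)[0]
        assert abs(slope) < 0.3


class TestPerceptron:
    def separable_spectra(self, n=40, bins=20, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, bins)) * 0.1
        y = np.arange(n) % 2 == 0
        X[y, 3] += 5.0
        X[~y, 12] += 5.0
        freqs = np.linspace(10, 200, bins)
        return SpectrumMatrix(values=X, freqs=freqs,
                              frame_indices=np.arange(n)), y

    def test_separable_classes_converge_to_perfect_training_accuracy(self):
        spec, y = self.separable_spectra()
        idx = np.arange(20)
        model = perceptron_fit(spec, (idx, y[:20]))
        assert np.array_equal(model.predict(spec.values[idx]), y[:20])

    def test_query_equal_to_labeled_example_matches_its_label(self):
        spec, y = self.separable_spectra(n=4)
        model = perceptron_fit(spec, (np.asarray([0, 1]), y[:2]))
        assert model.predict(spec.values[[0]])[0] == y[0]
        assert model.predict(spec.values[[1]])[0] == y[1]

    def test_one_class_labels_rejected(self):
        spec, _ = self.separable_spectra()
        with pytest.raises(ValueError, match="each class"):
            perceptron_fit(spec, (np.asarray([0, 2]), np.asarray([True, True])))

    def test_unlabeled_frame_permutation_leaves_predictions_unchanged(self):
        spec, y = self.separable_spectra(n=40)
        labeled = np.arange(10)
        model1 = perceptron_fit(spec, (labeled, y[:10]))
        # permute only unlabeled frames (standardization stats are a set
        # statistic; labeled visiting order is unchanged)
        perm = np.concatenate([labeled, 10 + np.random.default_rng(0).permutation(30)])
        spec2 = SpectrumMatrix(values=spec.values[perm], freqs=spec.freqs,
                               frame_indices=np.arange(40))
        model2 = perceptron_fit(spec2, (labeled, y[:10]))
        np.testing.assert_allclose(
            model1.decision_function(spec.values),
            model2.decision_function(spec.values), atol=1e-12)

    def test_refine_no_corrections_is_identity(self):
        spec, y = self.separable_spectra()
        model = perceptron_fit(spec, (np.arange(20), y[:20]))
        model2 = refine_interactive(model, spec, {})
        np.testing.assert_array_equal(model.predict(spec.values),
                                      model2.predict(spec.values))

    def test_contradictory_corrections_rejected(self):
        spec, y = self.separable_spectra()
        model = perceptron_fit(spec, (np.arange(20), y[:20]))
        with pytest.raises(ValueError, match="contradictory"):
            refine_interactive(model, spec,
                               (np.asarray([5, 5]), np.asarray([True, False])))

    def test_out_of_range_correction_rejected(self):
        spec, y = self.separable_spectra()
        model = perceptron_fit(spec, (np.arange(20), y[:20]))
        with pytest.raises(IndexError):
            refine_interactive(model, spec, {999: True})


class TestDetectIEDs:
    def test_planted_events_recovered(self, small_planted, seed_labels_factory):
        gt, session = small_planted
        idx, y = seed_labels_factory(gt, session)
        oracle = lambda f: bool(np.min(np.abs(gt.event_frames - f)) == 0)
        ev = detect_ieds(session, (idx, y), refine_rounds=2, oracle=oracle)
        # ±1 frame tolerance: a transient near a frame boundary may peak in
        # the neighbouring frame
        prec = (np.min(np.abs(ev.frames[:, None] - gt.event_frames[None, :]),
                       axis=1) <= 1).mean()
        rec = (np.min(np.abs(gt.event_frames[:, None] - ev.frames[None, :]),
                      axis=1) <= 1).mean()
        assert prec >= 0.9
        assert rec >= 0.9

    def test_oracle_refinement_never_increases_false_positives(
            self, small_planted, seed_labels_factory):
        gt, session = small_planted
        idx, y = seed_labels_factory(gt, session, seed=8)
        truth = set(gt.event_frames.tolist())
        fps = []
        for rounds in range(3):
            ev = detect_ieds(session, (idx, y), refine_rounds=rounds,
                             oracle=lambda f: f in truth)
            fps.append(sum(f not in truth and min(abs(gt.event_frames - f)) > 1
                           for f in ev.frames))
        assert fps[1] <= fps[0] and fps[2] <= fps[1]

    def test_null_session_with_donor_labels_flags_almost_nothing(
            self, small_planted, seed_labels_factory):
        gt, session = small_planted
        idx, y = seed_labels_factory(gt, session)
        donor_spec = frame_spectra(session)
        model = perceptron_fit(donor_spec, (idx, y))
        # annotator-corrected donor model, as in the interactive workflow
        truth = set(gt.event_frames.tolist())
        for _ in range(3):
            flagged = np.flatnonzero(model.predict(donor_spec.values))
            wrong = {int(f): False for f in flagged if f not in truth}
            if not wrong:
                break
            model = refine_interactive(model, donor_spec, wrong)
        null_gt = sample_ler(LERParams(K=2, N=4, M=5), seed=30, n_frames=1400)
        null_session = render_session(
            null_gt, SessionConfig(seed=31, ied_amplitude=0.0,
                                   duration=1400 / 15.0))
        flagged = model.predict(frame_spectra(null_session).values)
        assert flagged.mean() <= 0.01

    def test_event_spanning_frame_boundary_merges_to_one(self):
        # a transient straddling two frames → two positive frames → 1 event
        s = tone_session(amplitude=0.0, noise=0.2, n_frames=200, seed=5)
        lfp = s.lfp.copy()
        boundary = 100 * 83
        lfp[boundary - 40: boundary + 40] += 10.0 * np.hanning(80)
        s2 = Session(dff=s.dff, lfp=lfp, frame_bounds=s.frame_bounds,
                     labels=s.labels, speed=s.speed,
                     frame_rate=s.frame_rate, lfp_rate=s.lfp_rate)
        # label both spanning frames positive, a few clean frames negative
        idx = np.asarray([10, 20, 30, 40, 99, 100])
        y = np.asarray([False, False, False, False, True, True])
        ev = detect_ieds(s2, (idx, y))
        assert np.isin(ev.frames, [99, 100]).sum() == 1


class TestIEDRate:
    def test_paper_scale_arithmetic(self):
        ev = EventSet(frames=np.arange(678), kind="IED")
        rate, count = ied_rate(ev, 600.0)
        assert round(rate, 2) == 1.13
        assert count == 678

    def test_zero_events(self):
        assert ied_rate(EventSet(frames=np.asarray([], dtype=int),
                                 kind="IED"), 100.0) == (0.0, 0)

    def test_rate_count_roundtrip_exact(self):
        ev = EventSet(frames=np.arange(137), kind="IED")
        rate, count = ied_rate(ev, 457.0)
        assert rate * 457.0 == count


class TestDetectSPWR:
    def test_bursts_detected_only_during_immobility(self):
        from lerens import inject_ripples
        gt = sample_ler(LERParams(K=2, N=4, M=5), seed=0)
        s = render_session(gt, SessionConfig(seed=1, ied_amplitude=0.0,
                                             duration=60.0))
        times = [10.0, 30.0, 50.0]
        s2 = inject_ripples(s, times, ripple_freq=150.0, amplitude=10.0)
        ev = detect_spwr(s2)
        assert len(ev) == 3
        # same bursts, animal running throughout
        s3 = inject_ripples(s, times, ripple_freq=150.0, amplitude=10.0)
        s3.speed[:] = 5.0
        assert len(detect_spwr(s3)) == 0

    def test_subthreshold_burst_not_detected(self):
        from lerens import inject_ripples
        gt = sample_ler(LERParams(K=2, N=4, M=5), seed=0)
        s = render_session(gt, SessionConfig(seed=1, ied_amplitude=0.0,
                                             duration=60.0))
        s2 = inject_ripples(s, [30.0], ripple_freq=150.0, amplitude=0.2)
        assert len(detect_spwr(s2)) == 0

    def test_missing_locomotion_trace_rejected(self):
        gt = sample_ler(LERParams(K=2, N=4, M=5), seed=0)
        s = render_session(gt, SessionConfig(seed=1, duration=30.0))
        s.speed = np.zeros(3)  # wrong length
        pytest.raises(ValueError, detect_spwr, s)

    def test_low_lfp_rate_rejected(self):
        s = make_noise_session(n_cells=2, n_frames=100, frame_rate=10.0,
                               samples_per_frame=4)  # 40 Hz LFP
        pytest.raises(ValueError, detect_spwr, s)


class TestEventSetIO:
    def test_tsv_roundtrip(self, tmp_path):
        ev = EventSet(frames=np.asarray([3, 17, 99]), kind="SPWR",
                      peak_samples=np.asarray([301, 1700, 9903]))
        save_events(ev, tmp_path / "ev.tsv")
        back = load_events(tmp_path / "ev.tsv")
        assert np.array_equal(back.frames, ev.frames)
        assert back.kind == "SPWR"
        assert np.array_equal(back.peak_samples, ev.peak_samples)

    def test_duplicate_frames_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            EventSet(frames=np.asarray([5, 5]), kind="IED")
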