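"""Preprocessing: filtering, decimation, re-referencing, blink removal,
epoching and artifact rejection."""

import numpy as np
import pytest

from gcsr.preprocess import (
    bandpass,
    downsample,
    extract_epochs,
    preprocess_recording,
    reject_artifacts,
    remove_eyeblinks,
    rereference,
)
from gcsr.synth import (BLINK_MIXING, EegRecording, GcsrEffectSpec,
                        generate_recording)
from gcsr.task import (ParticipantModel, SessionConfig, SsdClass, TrialType,
                       classify_trials, simulate_session)

FS = 512.0
CHANNELS = ["Fp1", "F7", "F8", "Fz", "Cz", "CPz", "M1", "M2"]


def make_rec(data, fs=FS, events=()):
    return EegRecording(CHANNELS[: data.shape[0]], fs, data, list(events))


def sinusoid_rec(freq, n_seconds=8, amplitude=1.0):
    t = np.arange(int(n_seconds * FS)) / FS
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return make_rec(np.tile(x, (5, 1)))


class TestBandpass:
    def test_stopband_50hz_attenuated_20db(self):
        rec = bandpass(sinusoid_rec(50.0))
        mid = rec.data[2, 1024:-1024]
        assert np.abs(mid).max() < 0.1  # >= 20 dB down

    def test_passband_10hz_within_5pct(self):
        rec = bandpass(sinusoid_rec(10.0))
        mid = rec.data[2, 1024:-1024]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_removed(self):
        rec = bandpass(make_rec(np.full((5, 4096), 100.0)))
        assert abs(rec.data.mean()) < 1.0

    def test_zero_phase_no_lag(self):
        # a pass-band tone must come out aligned with itself
        rec0 = sinusoid_rec(10.0)
        rec = bandpass(rec0)
        a = rec0.data[2, 1024:-1024]
        b = rec.data[2, 1024:-1024]
        lag = np.argmax(np.correlate(a, b, "full")) - (len(a) - 1)
        assert lag == 0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(sinusoid_rec(10.0), low_hz=36, high_hz=1)
        with pytest.raises(ValueError, match="twice"):
            bandpass(sinusoid_rec(10.0, n_seconds=1), low_hz=1, high_hz=300)


class TestDownsample:
    def test_event_index_rescaled(self):
        data = np.zeros((5, 4096))
        rec = make_rec(data, events=[(1024, "go/0"), (1027, "stop/0")])
        out = downsample(rec, 128.0)
        assert out.sample_rate_hz == 128.0
        assert out.events == [(256, "go/0"), (256, "stop/0")]
        assert out.n_samples == 1024

    def test_band_limited_content_preserved(self):
        t512 = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 8 * t512)
        out = downsample(make_rec(np.tile(x, (5, 1))), 128.0)
        t128 = np.arange(out.n_samples) / 128.0
        direct = np.sin(2 * np.pi * 8 * t128)
        core = slice(128, -128)
        r = np.corrcoef(out.data[2, core], direct[core])[0, 1]
        assert r >= 0.99

    def test_non_integer_factor_rejected(self):
        rec = make_rec(np.zeros((5, 1000)), fs=500.0)
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(rec, 128.0)


class TestRereference:
    def test_zero_mastoids_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((8, 256))
        data[6] = data[7] = 0.0
        rec = make_rec(data)
        out = rereference(rec)
        assert np.allclose(out.data, data)

    def test_constant_mastoids_shift(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 256))
        data[6] = data[7] = 5.0
        out = rereference(make_rec(data))
        assert np.allclose(out.data[0], data[0] - 5.0)

    def test_rereferenced_mastoids_sum_to_zero(self):
        rng = np.random.default_rng(2)
        out = rereference(make_rec(rng.standard_normal((8, 256))))
        assert np.allclose(out.channel("M1") + out.channel("M2"), 0.0,
                           atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rec = make_rec(rng.standard_normal((8, 256)))
        once = rereference(rec)
        twice = rereference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_missing_mastoid_named(self):
        rec = EegRecording(["Fp1", "F8", "CPz", "Cz", "M1"], FS,
                           np.zeros((5, 64)), [])
        with pytest.raises(ValueError, match="M2"):
            rereference(rec)


@pytest.fixture(scope="module")
def blinky_session():
    cfg = SessionConfig(n_sets_per_block=3, trial_period_ms=1500)
    session = simulate_session(ParticipantModel(), cfg, seed=31)
    spec = GcsrEffectSpec(amplitude_by_condition={}, blink_rate_hz=0.25,
                          background_scale_uV=5.0)
    clean_spec = GcsrEffectSpec(amplitude_by_condition={}, blink_rate_hz=0.0,
                                background_scale_uV=5.0)
    rec = generate_recording(session.trials, spec, seed=32)
    clean = generate_recording(session.trials, clean_spec, seed=32)
    return session, rec, clean


class TestBlinkRemoval:
    def _to_analysis_rate(self, rec):
        return rereference(downsample(bandpass(rec), 128.0))

    def test_blink_leakage_reduced_80pct(self, blinky_session):
        _, rec, clean = blinky_session
        x = self._to_analysis_rate(rec)
        ref = self._to_analysis_rate(clean)  # same seed, no blinks
        cleaned, found = remove_eyeblinks(x)
        assert len(found) >= 5
        # ground truth blink contribution at F8 = recording minus blink-free
        blink_f8 = x.channel("F8") - ref.channel("F8")
        resid_f8 = cleaned.channel("F8") - ref.channel("F8")
        peaks = [s // 4 for s, code in rec.events if code.startswith("blink/")]
        peaks = [p for p in peaks if 64 <= p < x.n_samples - 64]
        before = np.abs([blink_f8[p] for p in peaks]).mean()
        after = np.abs([resid_f8[p] for p in peaks]).mean()
        assert after <= 0.2 * before

    def test_blink_free_recording_passthrough(self, blinky_session):
        _, _, clean = blinky_session
        x = self._to_analysis_rate(clean)
        with pytest.warns(UserWarning, match="passed through"):
            out, found = remove_eyeblinks(x)
        assert found == []
        assert np.allclose(out.data, x.data)

    def test_unreachable_threshold_warns(self, blinky_session):
        _, rec, _ = blinky_session
        x = self._to_analysis_rate(rec)
        with pytest.warns(UserWarning, match="passed through"):
            out, _ = remove_eyeblinks(x, threshold_uV=1e5)
        assert np.allclose(out.data, x.data)


class TestEpochs:
    def _rec128(self, n_seconds=40):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((8, int(n_seconds * 128)))
        return make_rec(data, fs=128.0)

    def _pairs(self, session):
        pairs, _, _ = classify_trials(session.trials)
        return pairs

    def test_window_arithmetic(self):
        from gcsr.task import TrialRecord, Side, TrialPair
        stop = TrialRecord(1, 1, 0, 1, TrialType.STOP, SsdClass.MEDIUM, 225,
                           Side.LEFT, None, None, True, 9775, 10000)
        go = TrialRecord(0, 1, 0, 0, TrialType.GO, SsdClass.NONE, None,
                         Side.LEFT, Side.LEFT, 430, True, 20000, None)
        pair = TrialPair(stop, go)
        rec = self._rec128()
        epochs, dropped = extract_epochs(rec, [pair], subject_id="s")
        assert dropped == 0
        stop_ep = next(e for e in epochs if e.condition[0] is TrialType.STOP)
        go_ep = next(e for e in epochs if e.condition[0] is TrialType.GO)
        # stop onset 10.000 s at 128 Hz -> sample 1280; window starts 250 ms
        # earlier -> sample 1248; alignment index 32
        assert stop_ep.alignment == 32
        assert np.array_equal(stop_ep.data, rec.data[:, 1248:1248 + 128])
        # paired go: virtual stop at 20.000 + 0.225 s -> sample 2589
        virt = int(round((20000 + 225) / 1000 * 128))
        assert np.array_equal(go_ep.data, rec.data[:, virt - 32:virt + 96])
        assert go_ep.condition == (TrialType.GO, SsdClass.MEDIUM, 1)

    def test_onset_centring_option(self):
        from gcsr.task import TrialRecord, Side, TrialPair
        stop = TrialRecord(1, 1, 0, 1, TrialType.STOP, SsdClass.MEDIUM, 225,
                           Side.LEFT, None, None, True, 9775, 10000)
        go = TrialRecord(0, 1, 0, 0, TrialType.GO, SsdClass.NONE, None,
                         Side.LEFT, Side.LEFT, 430, True, 20000, None)
        rec = self._rec128()
        epochs, _ = extract_epochs(rec, [TrialPair(stop, go)], centring="onset")
        stop_ep = next(e for e in epochs if e.condition[0] is TrialType.STOP)
        assert stop_ep.alignment == 64
        assert np.array_equal(stop_ep.data, rec.data[:, 1280 - 64:1280 + 64])

    def test_edge_trials_dropped_with_count(self):
        from gcsr.task import TrialRecord, Side, TrialPair
        stop = TrialRecord(1, 1, 0, 1, TrialType.STOP, SsdClass.SHORT, 100,
                           Side.LEFT, None, None, True, 0, 100)
        go = TrialRecord(0, 1, 0, 0, TrialType.GO, SsdClass.NONE, None,
                         Side.LEFT, Side.LEFT, 400, True, 1000, None)
        rec = self._rec128(n_seconds=2)
        with pytest.warns(UserWarning, match="dropped"):
            epochs, dropped = extract_epochs(rec, [TrialPair(stop, go)])
        assert dropped == 1  # the stop epoch starts before the recording
        assert len(epochs) == 1

    def test_wrong_rate_rejected(self):
        rec = make_rec(np.zeros((5, 512)), fs=512.0)
        with pytest.raises(ValueError, match="128"):
            extract_epochs(rec, [])


class TestRejection:
    def _epochs(self):
        rng = np.random.default_rng(6)
        from gcsr.preprocess import Epoch
        eps = []
        for i in range(12):
            data = rng.standard_normal((5, 128))
            eps.append(Epoch("s", i, (TrialType.STOP, SsdClass.MEDIUM, 2), 32,
                             data, CHANNELS[:5]))
        return eps

    def test_clean_epochs_all_retained(self):
        kept, report = reject_artifacts(self._epochs())
        assert report.rejected == 0 and report.retained == 12

    def test_spiked_epoch_rejected_exactly(self):
        eps = self._epochs()
        eps[4].data[2, 60] += 500.0  # F8 spike
        kept, report = reject_artifacts(eps)
        assert report.rejected == 1
        assert all(e.trial_index != 4 for e in kept)

    def test_zero_threshold_hard_error(self):
        with pytest.raises(RuntimeError, match="all epochs rejected"):
            reject_artifacts(self._epochs(), peak_to_peak_uV=0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reject_artifacts([])


def test_epoch_count_conservation(blinky_session):
    session, rec, _ = blinky_session
    pairs, _, _ = classify_trials(session.trials)
    epochs, report = preprocess_recording(rec, pairs, subject_id="s")
    assert (report["n_retained"] + report["n_rejected"]
            + report["n_boundary_dropped"]) == 2 * len(pairs)
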