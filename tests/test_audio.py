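import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mindfuse.audio import (
    VOICE_CHANNEL_NAMES,
    AudioSegment,
    compute_mfcc,
    estimate_formants,
    estimate_pitch,
    extract_voice_features,
    frame_signal,
    mel_filterbank,
    read_wav,
    segment_audio,
    short_time_energy,
    wiener_denoise,
    write_wav,
)
from mindfuse.errors import InsufficientDataError
from mindfuse.synth import synthesize_voice

SR = 16000


def sine(freq, duration=1.0, sr=SR, amp=1.0):
    t = np.arange(int(duration * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------


class TestWienerDenoise:
    def test_zeros_unchanged(self):
        out = wiener_denoise(np.zeros(1000), SR)
        np.testing.assert_array_equal(out, 0.0)

    def test_snr_improves_on_noisy_sine(self, rng):
        clean = sine(200, 0.5, amp=0.5)
        sig_power = np.mean(clean**2)
        noise_power = sig_power / 10 ** (5.0 / 10.0)  # 5 dB SNR
        noisy = clean + rng.normal(0, np.sqrt(noise_power), len(clean))

        def snr(x):
            return 10 * np.log10(sig_power / np.mean((x - clean) ** 2))

        assert snr(wiener_denoise(noisy, SR)) > snr(noisy)

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            wiener_denoise(np.ones(100), SR, noise_window=1)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            wiener_denoise(np.array([]), SR)


class TestSegmentAudio:
    def test_exact_division(self):
        segs = segment_audio(np.zeros(10 * SR), SR)
        assert len(segs) == 10
        assert all(s.duration == pytest.approx(1.0) for s in segs)

    def test_partial_half_second_kept(self):
        segs = segment_audio(np.zeros(int(3.5 * SR)), SR)
        assert len(segs) == 4
        assert segs[-1].duration == pytest.approx(0.5)

    def test_short_trailer_dropped(self):
        assert segment_audio(np.zeros(int(0.3 * SR)), SR) == []

    def test_sample_conservation(self):
        n = int(5.7 * SR)
        segs = segment_audio(np.arange(n, dtype=float), SR)
        total = sum(len(s.samples) for s in segs)
        assert total <= n
        joined = np.concatenate([s.samples for s in segs])
        np.testing.assert_array_equal(joined, np.arange(total, dtype=float))


class TestFrameSignal:
    def test_98_frames_for_one_second(self):
        # floor((16000 - 400) / 160) + 1 = 98
        frames = frame_signal(np.zeros(SR), sample_rate=SR)
        assert frames.shape == (98, 400)

    def test_single_frame_boundary(self):
        x = np.arange(400, dtype=float)
        frames = frame_signal(x, frame_len=400 / SR, sample_rate=SR)
        assert frames.shape[0] == 1
        np.testing.assert_array_equal(frames[0], x)

    def test_hop_gt_frame_warns(self):
        with pytest.warns(UserWarning):
            frame_signal(np.zeros(SR), frame_len=0.01, hop=0.02, sample_rate=SR)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            frame_signal(np.zeros(100), sample_rate=SR)


class TestShortTimeEnergy:
    def test_ones(self):
        assert short_time_energy([1.0, 1.0, 1.0, 1.0]) == 4.0

    def test_zeros(self):
        assert short_time_energy(np.zeros(10)) == 0.0

    def test_three_four(self):
        assert short_time_energy([3.0, 4.0]) == 25.0

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            short_time_energy(np.array([]))

    @settings(max_examples=30, deadline=None)
    @given(alpha=st.floats(-8, 8, allow_nan=False))
    def test_quadratic_scaling_and_sign_invariance(self, alpha):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 64)
        e = short_time_energy(y)
        assert short_time_energy(alpha * y) == pytest.approx(alpha**2 * e, rel=1e-9)
        assert short_time_energy(-y) == pytest.approx(e, rel=1e-12)


class TestEstimatePitch:
    def test_glottal_pulse_train_120(self, rng):
        # oracle: autocorrelation peak of the clean excitation equals the
        # pulse period sr/f0, so the true pitch is 120 Hz by construction
        x = synthesize_voice(120.0, duration=1.0, sample_rate=SR, noise_sd=0.02, rng=rng)
        ests = [
            estimate_pitch(x[i : i + 400], SR) for i in range(2000, 14000, 400)
        ]
        voiced = [e for e in ests if e > 0]
        assert len(voiced) >= len(ests) * 0.9
        assert abs(np.mean(voiced) - 120.0) < 3.0

    def test_pure_sine_200(self):
        assert estimate_pitch(sine(200)[:400], SR) == pytest.approx(200.0, abs=3.0)

    def test_white_noise_unvoiced(self):
        frame = np.random.default_rng(42).normal(0, 1, 400)
        assert estimate_pitch(frame, SR) == 0.0

    def test_amplitude_and_polarity_invariance(self):
        f = sine(200)[:400]
        ref = estimate_pitch(f, SR)
        assert estimate_pitch(-f, SR) == ref
        assert estimate_pitch(5.0 * f, SR) == ref
        assert estimate_pitch(0.001 * f, SR) == ref

    def test_frame_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_pitch(np.zeros(100), SR)

    def test_silence_is_unvoiced(self):
        assert estimate_pitch(np.zeros(400), SR) == 0.0


class TestEstimateFormants:
    def test_planted_resonances_recovered(self):
        # white noise through an all-pole cascade; truth is the planted poles
        from scipy.signal import lfilter

        targets = (700.0, 1200.0, 2600.0)
        for seed in range(3):
            x = np.random.default_rng(seed).normal(0, 1, SR)
            for fc in targets:
                r = np.exp(-np.pi * 80.0 / SR)
                th = 2 * np.pi * fc / SR
                x = lfilter([1.0], [1.0, -2 * r * np.cos(th), r * r], x)
            frames = frame_signal(x, sample_rate=SR)[:50]
            ests = np.array([estimate_formants(f, SR) for f in frames])
            for k, tgt in enumerate(targets):
                nz = ests[ests[:, k] > 0, k]
                assert len(nz) > 25
                assert abs(nz.mean() - tgt) < 50.0

    def test_pure_sine_zero_fills(self):
        out = estimate_formants(sine(200)[:400], SR)
        assert len(out) == 3
        assert 0.0 in out  # fewer than 3 qualifying roots

    def test_ordering(self, rng):
        x = rng.normal(0, 1, 400)
        f1, f2, f3 = estimate_formants(x, SR)
        nz = [f for f in (f1, f2, f3) if f > 0]
        assert nz == sorted(nz)

    def test_all_zero_frame_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_formants(np.zeros(400), SR)


def oracle_mfcc(frame, sr, n_fft=512, n_mel=26, n_coeff=12):
    """Independent brute-force MFCC: explicit DFT, triangles, log, DCT."""
    frame = np.asarray(frame, dtype=float)
    padded = np.zeros(n_fft)
    padded[: len(frame)] = frame
    n = np.arange(n_fft)
    power = np.empty(n_fft // 2 + 1)
    for k in range(n_fft // 2 + 1):
        re = np.sum(padded * np.cos(-2 * np.pi * k * n / n_fft))
        im = np.sum(padded * np.sin(-2 * np.pi * k * n / n_fft))
        power[k] = (re * re + im * im) / n_fft
    mel = lambda f: 2595.0 * np.log10(1 + f / 700.0)
    imel = lambda m: 700.0 * (10 ** (m / 2595.0) - 1)
    edges = imel(np.linspace(mel(0.0), mel(sr / 2), n_mel + 2))
    energies = np.zeros(n_mel)
    for m in range(n_mel):
        for k in range(n_fft // 2 + 1):
            f = k * sr / n_fft
            if edges[m] <= f <= edges[m + 1]:
                w = (f - edges[m]) / (edges[m + 1] - edges[m])
            elif edges[m + 1] < f <= edges[m + 2]:
                w = (edges[m + 2] - f) / (edges[m + 2] - edges[m + 1])
            else:
                w = 0.0
            energies[m] += w * power[k]
    logs = np.log(np.maximum(energies, 1e-10))
    coeffs = np.zeros(n_coeff)
    for k in range(1, n_coeff + 1):
        s = np.sqrt(2.0 / n_mel)
        coeffs[k - 1] = s * np.sum(
            logs * np.cos(np.pi * k * (2 * np.arange(n_mel) + 1) / (2 * n_mel))
        )
    return coeffs


class TestComputeMfcc:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            frame = rng.normal(0, 1, 400)
            mine = compute_mfcc(frame, SR)
            ref = oracle_mfcc(frame, SR)
            np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_zero_frame_gives_zeros(self):
        np.testing.assert_allclose(compute_mfcc(np.zeros(400), SR), 0.0, atol=1e-9)

    def test_length_always_12(self, rng):
        assert compute_mfcc(rng.normal(0, 1, 320), SR).shape == (12,)

    def test_frame_longer_than_nfft_rejected(self):
        with pytest.raises(ValueError):
            compute_mfcc(np.zeros(1024), SR, n_fft=512)

    def test_filterbank_covers_spectrum(self):
        fb = mel_filterbank(SR, 512, 26)
        assert fb.shape == (26, 257)
        assert (fb >= 0).all()
        # interior bins are covered by at least one filter
        assert (fb.sum(axis=0)[3:-3] > 0).all()


class TestExtractVoiceFeatures:
    def test_17_channels_of_equal_length(self, rng):
        x = synthesize_voice(120.0, duration=1.0, sample_rate=SR, noise_sd=0.02, rng=rng)
        frames, channels = extract_voice_features(x, sample_rate=SR)
        assert len(channels) == 17
        assert len(frames) == 98
        assert all(len(c.values) == 98 for c in channels)

    def test_channel_order(self, rng):
        x = synthesize_voice(120.0, duration=1.0, sample_rate=SR, noise_sd=0.02, rng=rng)
        _, channels = extract_voice_features(x, sample_rate=SR)
        assert [c.channel_id for c in channels] == [("voice", j) for j in range(17)]
        assert VOICE_CHANNEL_NAMES[:5] == ("E", "PF", "For1", "For2", "For3")

    def test_unvoiced_segment_masks_pitch(self):
        x = np.zeros(SR)  # silence: every frame unvoiced
        with pytest.warns(UserWarning, match="unvoiced"):
            _, channels = extract_voice_features(x, sample_rate=SR)
        pitch_channel = channels[1]
        assert not pitch_channel.valid_mask.any()

    def test_noise_mostly_unvoiced(self, rng):
        x = rng.normal(0, 0.1, SR)
        _, channels = extract_voice_features(x, sample_rate=SR)
        voiced_frac = channels[1].valid_mask.mean()
        assert voiced_frac < 0.3

    def test_pitch_channel_mean_near_f0(self, rng):
        x = synthesize_voice(120.0, duration=1.0, sample_rate=SR, noise_sd=0.02, rng=rng)
        _, channels = extract_voice_features(x, sample_rate=SR)
        pf = channels[1].values[channels[1].valid_mask]
        assert abs(pf.mean() - 120.0) < 3.0


class TestWavIO:
    def test_roundtrip(self, tmp_path, rng):
        x = rng.uniform(-0.5, 0.5, 1000)
        path = tmp_path / "a.wav"
        write_wav(path, x, SR)
        samples, sr = read_wav(path)
        assert sr == SR
        np.testing.assert_allclose(samples, x, atol=1e-6)

    def test_multichannel_rejected(self, tmp_path, rng):
        from scipy.io import wavfile

        path = tmp_path / "stereo.wav"
        wavfile.write(path, SR, rng.uniform(-0.5, 0.5, (100, 2)).astype(np.float32))
        with pytest.raises(ValueError, match="mono"):
            read_wav(path)


class TestAudioSegment:
    def test_duration_invariant(self):
        seg = AudioSegment(np.zeros(SR), SR)
        assert seg.duration == pytest.approx(1.0)

    def test_too_long_rejected(self):
        with pytest.raises(ValueError):
            AudioSegment(np.zeros(2 * SR), SR)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            AudioSegment(np.array([0.0, np.nan]), SR)
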