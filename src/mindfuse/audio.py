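"""Speech preprocessing and per-frame voice descriptors.

Seventeen channels per frame: short-time energy, pitch, the first three
formants, and 12 mel-frequency cepstral coefficients.

Conventions (fixed here, configurable upstream):

* framing: 25 ms frames, 10 ms hop; energy and pitch work on the raw
  frame, formants and MFCC on a pre-emphasized (0.97), Hamming-windowed
  frame;
* pitch: search band 50-500 Hz; candidate periods come from peaks of the
  real cepstrum, refined and scored on the taper-corrected normalized
  autocorrelation; a frame whose best score, after subtracting the
  white-noise ceiling 2.5/sqrt(n), falls below 0.08 is declared unvoiced
  and encoded as pitch 0;
* formants: LPC by the autocorrelation (Levinson-Durbin) method, order
  2 + sr/1000; complex roots with bandwidth < 400 Hz and frequency in
  [90, sr/2 - 50] Hz, sorted ascending, zero-filled to three;
* MFCC: 512-point FFT power spectrum |X|^2/N, 26 triangular mel filters
  spanning 0..sr/2, natural log floored at 1e-10, orthonormal DCT-II,
  coefficients 1..12 (the DC coefficient is dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.fft import irfft, rfft
from scipy.fft import dct
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

from mindfuse.errors import InsufficientDataError
from mindfuse.keypoints import ChannelSeries

PITCH_BAND = (50.0, 500.0)
VOICED_THRESHOLD = 0.08
PREEMPHASIS = 0.97
FRAME_LEN = 0.025
FRAME_HOP = 0.010
LOG_FLOOR = 1e-10

#: per-frame channel layout consumed by the statistics module
VOICE_CHANNEL_NAMES = ("E", "PF", "For1", "For2", "For3") + tuple(
    f"mfcc{i}" for i in range(1, 13)
)


@dataclass
class AudioSegment:
    """A mono waveform chunk of at most one second."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment requires a mono 1-D waveform")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.duration > 1.0 + 0.5 / self.sample_rate:
            raise ValueError("AudioSegment duration must not exceed 1 s")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class VoiceFrameFeatures:
    """The 17-descriptor vector of one analysis frame."""

    energy: float
    pitch_hz: float
    formants_hz: tuple
    mfcc: np.ndarray

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise ValueError("energy must be non-negative")
        if self.pitch_hz != 0 and not (
            PITCH_BAND[0] <= self.pitch_hz <= PITCH_BAND[1]
        ):
            raise ValueError("pitch must be 0 (unvoiced) or inside the search band")
        f = [v for v in self.formants_hz if v > 0]
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("non-zero formants must be strictly ascending")
        self.mfcc = np.asarray(self.mfcc, dtype=float)
        if self.mfcc.shape != (12,):
            raise ValueError("exactly 12 MFCC values required")

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            ([self.energy, self.pitch_hz], self.formants_hz, self.mfcc)
        )


# ---------------------------------------------------------------------------
# I/O


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV file, returning float samples in [-1, 1] and the rate."""
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"cannot parse WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(
            f"{path}: multichannel WAV not supported; downmix to mono first"
        )
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return samples, int(rate)


def write_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    wavfile.write(path, int(sample_rate), np.asarray(samples, dtype=np.float32))


# ---------------------------------------------------------------------------
# Preprocessing


def wiener_denoise(
    samples: np.ndarray, sample_rate: float, noise_window: int = 11
) -> np.ndarray:
    """Adaptive local-statistics Wiener filter.

    The local mean and variance are estimated in a sliding window; the
    noise power is the mean of the local variances.  Where the local
    variance falls below the noise estimate the output collapses to the
    local mean.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InsufficientDataError("empty waveform")
    if noise_window < 3:
        raise ValueError("noise_window must be at least 3")
    mean = uniform_filter1d(samples, noise_window, mode="nearest")
    mean_sq = uniform_filter1d(samples * samples, noise_window, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    noise = var.mean()
    if noise == 0:
        return mean
    gain = np.where(var > noise, (var - noise) / np.maximum(var, noise), 0.0)
    return mean + gain * (samples - mean)


def segment_audio(samples: np.ndarray, sample_rate: float) -> list[AudioSegment]:
    """Cut into consecutive 1 s segments; a trailing partial of at least
    0.5 s is kept, shorter trailers are dropped."""
    if not sample_rate > 0:
        raise ValueError("sample_rate must be positive")
    samples = np.asarray(samples, dtype=float)
    seg = int(round(sample_rate))
    half = seg / 2.0
    out = []
    for start in range(0, len(samples), seg):
        chunk = samples[start : start + seg]
        if len(chunk) == seg or len(chunk) >= half:
            out.append(AudioSegment(samples=chunk, sample_rate=sample_rate))
    return out


def frame_signal(
    segment,
    frame_len: float = FRAME_LEN,
    hop: float = FRAME_HOP,
    window: str = "none",
    sample_rate: float | None = None,
) -> np.ndarray:
    """Slice a waveform into overlapping frames, shape (n_frames, L).

    n_frames = floor((n - L) / H) + 1.  ``window`` is "none" or "hamming";
    spectral consumers apply their own windows, so the default leaves the
    frames untouched.
    """
    if isinstance(segment, AudioSegment):
        samples, sr = segment.samples, segment.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required when passing a raw array")
        samples, sr = np.asarray(segment, dtype=float), sample_rate
    flen = int(round(frame_len * sr))
    fhop = int(round(hop * sr))
    if flen < 1 or fhop < 1:
        raise ValueError("frame_len and hop must be at least one sample")
    if len(samples) < flen:
        raise InsufficientDataError(
            f"segment of {len(samples)} samples shorter than one frame ({flen})"
        )
    if fhop > flen:
        warnings.warn("hop exceeds frame length; frames will not cover the signal",
                      stacklevel=2)
    n_frames = (len(samples) - flen) // fhop + 1
    idx = np.arange(flen)[None, :] + fhop * np.arange(n_frames)[:, None]
    frames = samples[idx]
    if window == "hamming":
        frames = frames * np.hamming(flen)[None, :]
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    return frames


# ---------------------------------------------------------------------------
# Per-frame descriptors


def short_time_energy(frame: np.ndarray) -> float:
    """Sum of squared samples of the (unwindowed) frame."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise InsufficientDataError("empty frame")
    return float(np.dot(frame, frame))


def _pitch_from_spectra(spec, ac, wac_ratio, n, sr, qlo, qhi, threshold):
    """Shared candidate search for one frame's spectrum/autocorrelation."""
    ac0 = float(ac[0])
    if ac0 <= 0:
        return 0.0
    m = spec.max()
    ceps = irfft(np.log(spec / m + LOG_FLOOR))
    runb = np.minimum((ac[qlo : qhi + 1] / ac0) / wac_ratio, 1.0)
    band = ceps[qlo : qhi + 1]
    pk = band.max()
    interior = (band[1:-1] >= band[:-2]) & (band[1:-1] >= band[2:])
    locmax = np.r_[False, interior, False]
    cand = list(qlo + np.flatnonzero(locmax & (band >= 0.8 * pk)))
    cand.append(qlo + int(np.argmax(runb)))
    peaks = {}
    for q in cand:
        a = max(qlo, int(q) - 4)
        b = min(qhi, int(q) + 4)
        qr = a + int(np.argmax(ac[a : b + 1]))  # biased ac has true peaks
        peaks[qr] = float(runb[qr - qlo])
    best = max(peaks.values())
    qc = min(q for q, r in peaks.items() if r >= 0.9 * best)
    prominence = peaks[qc] - 2.5 / np.sqrt(max(n - qc, 1))
    if prominence < threshold:
        return 0.0
    return sr / qc


def estimate_pitch(
    frame: np.ndarray,
    sample_rate: float,
    band: tuple = PITCH_BAND,
    voiced_threshold: float = VOICED_THRESHOLD,
) -> float:
    """Fundamental frequency of one frame, or 0 if judged unvoiced.

    Period candidates are taken from peaks of the real cepstrum of the
    Hamming-windowed frame (plus the in-band autocorrelation maximum as a
    backstop), refined on the raw autocorrelation and scored on the
    taper-corrected normalized autocorrelation; the smallest period within
    90% of the best score wins, which suppresses octave errors.
    """
    frame = np.asarray(frame, dtype=float)
    n = len(frame)
    qlo = max(2, int(np.ceil(sample_rate / band[1])))
    qhi = int(np.floor(sample_rate / band[0]))
    if n <= qhi:
        raise InsufficientDataError(
            f"frame of {n} samples too short for a {band[0]} Hz search floor "
            f"(needs > {qhi} samples)"
        )
    x = frame - frame.mean()
    w = np.hamming(n)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.abs(rfft(x * w, nfft))
    if spec.max() == 0:
        return 0.0
    ac = irfft(spec**2)
    wac = irfft(np.abs(rfft(w, nfft)) ** 2)
    wac_ratio = np.maximum(wac[qlo : qhi + 1] / wac[0], 1e-3)
    return _pitch_from_spectra(
        spec, ac, wac_ratio, n, sample_rate, qlo, qhi, voiced_threshold
    )


def _levinson_batch(r: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin recursion for a batch of autocorrelation rows.

    ``r`` has shape (F, order + 1); returns LPC coefficient rows
    (F, order + 1) with a[:, 0] == 1.
    """
    n_frames = r.shape[0]
    a = np.zeros((n_frames, order + 1))
    a[:, 0] = 1.0
    err = r[:, 0].copy()
    for i in range(1, order + 1):
        acc = r[:, i].copy()
        if i > 1:
            acc += np.einsum("fj,fj->f", a[:, 1:i], r[:, i - 1 : 0 : -1])
        k = np.where(err > 0, -acc / np.where(err > 0, err, 1.0), 0.0)
        a_new = a.copy()
        a_new[:, i] = k
        a_new[:, 1:i] = a[:, 1:i] + k[:, None] * a[:, i - 1 : 0 : -1]
        a = a_new
        err = err * (1.0 - k * k)
    return a


def _lpc_roots_to_formants(a: np.ndarray, sample_rate: float) -> tuple:
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * sample_rate / (2 * np.pi)
    bands = -np.log(np.maximum(np.abs(roots), 1e-12)) * sample_rate / np.pi
    keep = (bands < 400.0) & (freqs >= 90.0) & (freqs <= sample_rate / 2 - 50.0)
    cands = np.sort(freqs[keep])[:3]
    out = [0.0, 0.0, 0.0]
    out[: len(cands)] = [float(f) for f in cands]
    return tuple(out)


def estimate_formants(
    frame: np.ndarray, sample_rate: float, lpc_order: int | None = None
) -> tuple:
    """First three formants of one frame via the LPC root method.

    Returns (For1, For2, For3) in Hz, ascending, with 0 filling slots for
    which no qualifying root exists.
    """
    frame = np.asarray(frame, dtype=float)
    if lpc_order is None:
        lpc_order = 2 + int(sample_rate / 1000)
    if frame.size <= lpc_order:
        raise InsufficientDataError("frame shorter than the LPC order")
    x = frame * np.hamming(len(frame))
    nfft = 1 << int(np.ceil(np.log2(2 * len(x))))
    r = irfft(np.abs(rfft(x, nfft)) ** 2)[: lpc_order + 1]
    if r[0] <= 0:
        raise InsufficientDataError("degenerate (all-zero) frame")
    a = _levinson_batch(r[None, :], lpc_order)[0]
    return _lpc_roots_to_formants(a, sample_rate)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: float, n_fft: int, n_mel: int) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mel, n_fft//2 + 1).

    Filter m rises from vertex m-1 to m and falls to m+1, the vertices
    being equally spaced on the mel scale between 0 and sr/2.  Weights are
    evaluated at the exact bin frequencies (no integer bin snapping).
    """
    edges = mel_to_hz(np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2), n_mel + 2))
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_mel, len(bin_freqs)))
    for m in range(n_mel):
        lo, cen, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (bin_freqs - lo) / (cen - lo)
        down = (hi - bin_freqs) / (hi - cen)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def compute_mfcc(
    frame: np.ndarray,
    sample_rate: float,
    n_fft: int = 512,
    n_mel: int = 26,
    n_coeff: int = 12,
) -> np.ndarray:
    """Mel-frequency cepstral coefficients 1..n_coeff of one frame.

    The frame is zero-padded to ``n_fft``; frames longer than ``n_fft``
    are rejected rather than silently truncated.
    """
    frame = np.asarray(frame, dtype=float)
    if len(frame) > n_fft:
        raise ValueError(
            f"frame of {len(frame)} samples exceeds n_fft={n_fft}; resample "
            "or shorten explicitly"
        )
    power = np.abs(rfft(frame, n_fft)) ** 2 / n_fft
    fb = mel_filterbank(sample_rate, n_fft, n_mel)
    energies = fb @ power
    logs = np.log(np.maximum(energies, LOG_FLOOR))
    coeffs = dct(logs, type=2, norm="ortho")
    return coeffs[1 : n_coeff + 1]


# ---------------------------------------------------------------------------
# Segment-level assembly


def _preemphasize(samples: np.ndarray, coeff: float) -> np.ndarray:
    out = samples.copy()
    out[1:] -= coeff * samples[:-1]
    return out


def extract_voice_features(
    segment,
    sample_rate: float | None = None,
    frame_len: float = FRAME_LEN,
    hop: float = FRAME_HOP,
    preemphasis: float = PREEMPHASIS,
    n_fft: int = 512,
    n_mel: int = 26,
    n_coeff: int = 12,
    pitch_band: tuple = PITCH_BAND,
    voiced_threshold: float = VOICED_THRESHOLD,
    lpc_order: int | None = None,
) -> tuple[list[VoiceFrameFeatures], list[ChannelSeries]]:
    """Per-frame 17-vectors for one audio segment, plus 17 channel series.

    Energy and pitch are computed on the raw frames; formants and MFCC on
    pre-emphasized, Hamming-windowed frames.  Unvoiced frames are masked
    invalid on the pitch channel only.
    """
    if isinstance(segment, AudioSegment):
        samples, sr = segment.samples, segment.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required when passing a raw array")
        samples, sr = np.asarray(segment, dtype=float), sample_rate

    raw = frame_signal(samples, frame_len, hop, "none", sample_rate=sr)
    emph = frame_signal(
        _preemphasize(samples, preemphasis), frame_len, hop, "none", sample_rate=sr
    )
    n_frames, flen = raw.shape
    win = np.hamming(flen)
    windowed = emph * win[None, :]

    energies = np.einsum("ij,ij->i", raw, raw)

    # pitch (batched FFTs, per-frame candidate logic)
    qlo = max(2, int(np.ceil(sr / pitch_band[1])))
    qhi = int(np.floor(sr / pitch_band[0]))
    if flen <= qhi:
        raise InsufficientDataError(
            f"frames of {flen} samples too short for a {pitch_band[0]} Hz pitch floor"
        )
    nfft_p = 1 << int(np.ceil(np.log2(2 * flen)))
    centered = raw - raw.mean(axis=1, keepdims=True)
    specs = np.abs(rfft(centered * win[None, :], nfft_p, axis=1))
    acs = irfft(specs**2, axis=1)
    wac = irfft(np.abs(rfft(win, nfft_p)) ** 2)
    wac_ratio = np.maximum(wac[qlo : qhi + 1] / wac[0], 1e-3)
    pitches = np.zeros(n_frames)
    for i in range(n_frames):
        if specs[i].max() > 0:
            pitches[i] = _pitch_from_spectra(
                specs[i], acs[i], wac_ratio, flen, sr, qlo, qhi, voiced_threshold
            )

    # formants (batched Levinson, per-frame root finding)
    order = lpc_order if lpc_order is not None else 2 + int(sr / 1000)
    nfft_a = 1 << int(np.ceil(np.log2(2 * flen)))
    r = irfft(np.abs(rfft(windowed, nfft_a, axis=1)) ** 2, axis=1)[:, : order + 1]
    a = _levinson_batch(r, order)
    formants = np.zeros((n_frames, 3))
    for i in range(n_frames):
        if r[i, 0] > 0:
            formants[i] = _lpc_roots_to_formants(a[i], sr)

    # MFCC (fully batched)
    if flen > n_fft:
        raise ValueError(f"frame of {flen} samples exceeds n_fft={n_fft}")
    power = np.abs(rfft(windowed, n_fft, axis=1)) ** 2 / n_fft
    fb = mel_filterbank(sr, n_fft, n_mel)
    logs = np.log(np.maximum(power @ fb.T, LOG_FLOOR))
    mfccs = dct(logs, type=2, norm="ortho", axis=1)[:, 1 : n_coeff + 1]

    frames_out = [
        VoiceFrameFeatures(
            energy=float(energies[i]),
            pitch_hz=float(pitches[i]),
            formants_hz=tuple(formants[i]),
            mfcc=mfccs[i],
        )
        for i in range(n_frames)
    ]

    matrix = np.column_stack([energies, pitches, formants, mfccs])
    voiced_mask = pitches > 0
    if not voiced_mask.any():
        warnings.warn(
            "segment fully unvoiced; pitch channel carries no valid frames",
            stacklevel=2,
        )
    channels = []
    for j, name in enumerate(VOICE_CHANNEL_NAMES):
        mask = voiced_mask.copy() if name == "PF" else np.ones(n_frames, dtype=bool)
        channels.append(
            ChannelSeries(channel_id=("voice", j), values=matrix[:, j], valid_mask=mask)
        )
    return frames_out, channels
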