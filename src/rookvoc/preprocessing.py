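"""Normalized mel-spectrogram representation of vocal units.

Each annotated unit is converted to the representation every downstream
stage consumes: the best-SNR channel is selected, the waveform is
denoised by spectral gating, pre-emphasized and high-pass filtered, then
turned into a power spectrogram with a 10 ms Hamming window and 80%
overlap (480-sample window, 96-sample hop at 48 kHz), mel-scaled to 80
bands above 100 Hz, trimmed of silent edges, log-scaled, thresholded to
a 20 dB dynamic range below the maximum, and mapped linearly onto
[0, 1]. The final normalization makes the representation invariant to
the absolute amplitude of the recording.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

SAMPLE_RATE = 48_000
WIN_SAMPLES = 480  # 10 ms at 48 kHz
HOP_SAMPLES = 96  # 80% overlap
N_MELS = 80
FMIN_HZ = 100.0

_EPS = np.finfo(np.float64).eps


@dataclass
class PreprocessConfig:
    """Tunable parameters of the unit-spectrogram pipeline.

    ``dynamic_range_db`` is the retained range below the spectrogram
    maximum after log scaling; ``trim_threshold_db`` the per-frame energy
    threshold (below the peak frame) for edge trimming;
    ``denoise_strength`` the fraction of sub-threshold STFT magnitude
    removed by the spectral gate; ``snr_flank_s`` how much flanking
    context is used for channel selection and noise profiling.
    """

    preemph_alpha: float = 0.97
    dynamic_range_db: float = 20.0
    trim_threshold_db: float = 60.0
    denoise_strength: float = 1.0
    snr_flank_s: float = 0.5
    highpass: bool = True
    highpass_hz: float = 100.0
    denoise: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.preemph_alpha < 1.0:
            raise ValueError("preemph_alpha must be in [0, 1)")
        if self.dynamic_range_db <= 0:
            raise ValueError("dynamic_range_db must be > 0")


@dataclass
class UnitSpectrogram:
    """Normalized mel spectrogram of one unit: values in [0, 1], 80 bands."""

    values: np.ndarray  # (n_mels, n_frames)
    unit_id: str = ""
    hop_s: float = HOP_SAMPLES / SAMPLE_RATE
    win_s: float = WIN_SAMPLES / SAMPLE_RATE
    fmin_hz: float = FMIN_HZ
    fmax_hz: float = SAMPLE_RATE / 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("spectrogram must be 2-D with at least one frame")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("spectrogram values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def select_channel(
    segment: np.ndarray, flanks: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Pick the channel with the highest in-unit vs flanking-noise SNR.

    ``segment`` is (channels, samples) covering the unit; ``flanks`` the
    concatenated flanking context (same channel count). SNR per channel
    is ``10 log10(RMS_unit^2 / RMS_flank^2)``; without flanking context
    the in-unit RMS alone ranks channels. Ties break to the lowest
    channel index.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    if segment.shape[1] == 0:
        raise ValueError("zero-length segment")
    if segment.shape[0] == 1:
        return segment[0], 0
    unit_power = np.mean(segment**2, axis=1)
    if flanks is not None and np.asarray(flanks).size:
        flanks = np.atleast_2d(np.asarray(flanks, dtype=np.float64))
        flank_power = np.mean(flanks**2, axis=1)
        score = 10.0 * np.log10((unit_power + _EPS) / (flank_power + _EPS))
    else:
        score = unit_power
    idx = int(np.argmax(score))  # argmax returns the first maximum → lowest index
    return segment[idx], idx


def denoise(
    wave: np.ndarray,
    sample_rate: int = SAMPLE_RATE,
    config: PreprocessConfig | None = None,
    noise_clip: np.ndarray | None = None,
) -> np.ndarray:
    """Stationary spectral-gating noise reduction.

    A per-frequency gate threshold (mean + 1.5 SD of STFT magnitude) is
    estimated from ``noise_clip`` when given, otherwise from the quietest
    10% of the unit's own frames. Magnitudes below the gate are scaled by
    ``1 − denoise_strength`` after smoothing the gate mask; output length
    equals input length. The gate threshold scales with the signal, so
    the operation commutes with amplitude scaling.
    """
    config = config or PreprocessConfig()
    wave = np.asarray(wave, dtype=np.float64)
    n = wave.shape[-1]
    nper = min(WIN_SAMPLES, n)
    f, t, stft = signal.stft(wave, fs=sample_rate, nperseg=nper, noverlap=nper * 3 // 4)
    mag = np.abs(stft)

    if noise_clip is not None and np.asarray(noise_clip).size >= nper:
        _, _, noise_stft = signal.stft(
            np.asarray(noise_clip, dtype=np.float64),
            fs=sample_rate,
            nperseg=nper,
            noverlap=nper * 3 // 4,
        )
        noise_mag = np.abs(noise_stft)
    else:
        frame_energy = mag.sum(axis=0)
        k = max(1, int(np.ceil(0.1 * mag.shape[1])))
        quiet = np.argsort(frame_energy)[:k]
        noise_mag = mag[:, quiet]

    gate = noise_mag.mean(axis=1) + 1.5 * noise_mag.std(axis=1)
    mask = (mag > gate[:, None]).astype(np.float64)
    mask = ndimage.uniform_filter(mask, size=(3, 3))
    gain = 1.0 - config.denoise_strength * (1.0 - mask)
    _, out = signal.istft(stft * gain, fs=sample_rate, nperseg=nper, noverlap=nper * 3 // 4)
    if out.shape[-1] < n:
        out = np.pad(out, (0, n - out.shape[-1]))
    return out[:n]


def preemphasize(wave: np.ndarray, alpha: float = 0.97) -> np.ndarray:
    """First-difference pre-emphasis: ``y[t] = x[t] − alpha·x[t−1]``, ``y[0] = x[0]``."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    wave = np.asarray(wave, dtype=np.float64)
    if wave.size == 0:
        return wave.copy()
    out = np.empty_like(wave)
    out[0] = wave[0]
    out[1:] = wave[1:] - alpha * wave[:-1]
    return out


def highpass(wave: np.ndarray, cutoff_hz: float = 100.0, sample_rate: int = SAMPLE_RATE) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-cut filter."""
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(wave, dtype=np.float64))


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """HTK mel scale: ``2595 log10(1 + f/700)``."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int = N_MELS,
    n_fft: int = WIN_SAMPLES,
    sample_rate: int = SAMPLE_RATE,
    fmin_hz: float = FMIN_HZ,
    fmax_hz: float | None = None,
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1).

    Band edges are equally spaced on the mel scale between ``fmin_hz``
    and ``fmax_hz`` (default Nyquist); the low-frequency cut doubles as a
    noise-removing step.
    """
    fmax_hz = sample_rate / 2 if fmax_hz is None else fmax_hz
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_mels + 2))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, center, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        rising = (fft_freqs - lo) / max(center - lo, _EPS)
        falling = (hi - fft_freqs) / max(hi - center, _EPS)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def mel_center_frequencies(
    n_mels: int = N_MELS,
    sample_rate: int = SAMPLE_RATE,
    fmin_hz: float = FMIN_HZ,
    fmax_hz: float | None = None,
) -> np.ndarray:
    fmax_hz = sample_rate / 2 if fmax_hz is None else fmax_hz
    edges = mel_to_hz(np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_mels + 2))
    return np.asarray(edges[1:-1])


def compute_mel_spectrogram(wave: np.ndarray, sample_rate: int = SAMPLE_RATE) -> np.ndarray:
    """Mel power spectrogram: 10 ms Hamming window, 80% overlap, 80 bands.

    Frame count is ``1 + floor((N − 480) / 96)``; input shorter than one
    window raises (callers pad, see :func:`preprocess_unit`).
    """
    wave = np.asarray(wave, dtype=np.float64)
    if wave.ndim != 1:
        raise ValueError("expected a single-channel waveform")
    n = wave.size
    if n < WIN_SAMPLES:
        raise ValueError(f"waveform of {n} samples is shorter than one {WIN_SAMPLES}-sample window")
    n_frames = 1 + (n - WIN_SAMPLES) // HOP_SAMPLES
    idx = np.arange(WIN_SAMPLES)[None, :] + HOP_SAMPLES * np.arange(n_frames)[:, None]
    frames = wave[idx] * np.hamming(WIN_SAMPLES)[None, :]
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # (n_frames, n_fft//2+1)
    fb = mel_filterbank(sample_rate=sample_rate)
    return fb @ power.T  # (n_mels, n_frames)


def normalize_spectrogram(
    mel: np.ndarray,
    config: PreprocessConfig | None = None,
    unit_id: str = "",
) -> UnitSpectrogram:
    """Trim, log-scale, threshold and normalize a mel power spectrogram.

    Leading/trailing frames whose total energy falls more than
    ``trim_threshold_db`` below the peak frame are dropped; the matrix is
    converted to dB, floored at ``dynamic_range_db`` below its maximum,
    and mapped linearly so the floor is 0 and the maximum 1. A constant
    (zero-dynamic-range) matrix maps to all ones by convention.
    """
    config = config or PreprocessConfig()
    mel = np.asarray(mel, dtype=np.float64)
    if mel.ndim != 2 or mel.size == 0:
        raise ValueError("mel matrix must be 2-D and nonempty")

    energy = mel.sum(axis=0)
    frame_db = 10.0 * np.log10(energy + _EPS)
    keep = (frame_db >= frame_db.max() - config.trim_threshold_db) & (energy > 0)
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError(f"unit {unit_id!r}: empty after trim")
    trimmed = mel[:, kept[0] : kept[-1] + 1]  # interior frames are never removed

    db = 10.0 * np.log10(trimmed + _EPS)
    top = db.max()
    if top - db.min() < 1e-12:
        values = np.ones_like(db)
    else:
        floor = top - config.dynamic_range_db
        values = (np.maximum(db, floor) - floor) / config.dynamic_range_db
    return UnitSpectrogram(values=values, unit_id=unit_id)


def preprocess_unit(
    segment: np.ndarray,
    unit_id: str = "",
    config: PreprocessConfig | None = None,
    flanks: np.ndarray | None = None,
    sample_rate: int = SAMPLE_RATE,
) -> UnitSpectrogram:
    """Full per-unit chain: channel selection → denoise → pre-emphasis →
    high-pass → mel spectrogram → trim/log/threshold/normalize.

    ``segment`` may be (channels, samples) or a single channel; units
    shorter than one analysis window are zero-padded with a warning.
    """
    config = config or PreprocessConfig()
    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    flank_arr = None if flanks is None else np.atleast_2d(np.asarray(flanks, dtype=np.float64))
    wave, ch = select_channel(segment, flank_arr)
    noise_clip = flank_arr[ch] if flank_arr is not None else None
    if config.denoise:
        wave = denoise(wave, sample_rate, config, noise_clip=noise_clip)
    wave = preemphasize(wave, config.preemph_alpha)
    if config.highpass and wave.size > 30:
        wave = highpass(wave, config.highpass_hz, sample_rate)
    if wave.size < WIN_SAMPLES:
        warnings.warn(
            f"unit {unit_id!r}: {wave.size} samples < one window; zero-padding", stacklevel=2
        )
        wave = np.pad(wave, (0, WIN_SAMPLES - wave.size))
    mel = compute_mel_spectrogram(wave, sample_rate)
    return normalize_spectrogram(mel, config, unit_id=unit_id)
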