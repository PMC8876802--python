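"""Framing and 60-dimensional linear-frequency cepstral features.

Clips are cut into 50 ms frames shifted every 10 ms (40 ms overlap);
digitally silent frames are dropped. Each frame is peak-normalized to
[-1, 1], Hamming-windowed, transformed with a 1024-point FFT, squared
into a power spectrum, passed through 60 triangular filters spaced
uniformly over 0–8 kHz, log-compressed and decorrelated with an
orthonormal type-II DCT, yielding a 60-coefficient LFCC vector. Unlike
mel-warped cepstra, the linear filter bank keeps full resolution in the
4–6 kHz region where high-frequency individuality lives.

The same filter bank, applied to the power spectrum *without* log/DCT,
supplies the per-band energies consumed by the F-ratio analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.fft

from .synth_voice import SAMPLE_RATE, VoiceClip

FRAME_MS = 50
OVERLAP_MS = 40
N_BANDS = 60
NFFT = 1024
NYQUIST = SAMPLE_RATE / 2
ENERGY_FLOOR = 1e-10
SILENCE_RMS_FRACTION = 1e-3  # frames quieter than this x clip peak are cut


class DegenerateInputError(ValueError):
    """Raised when an all-zero frame reaches the cepstral pipeline."""


@dataclass(frozen=True)
class VoiceSample:
    """One analysis frame (800 samples = 50 ms at 16 kHz) with its labels."""

    frame: np.ndarray
    speaker_id: str
    period: str
    kind: str
    vowel_label: str


@lru_cache(maxsize=8)
def linear_filterbank(n_bands: int = N_BANDS, nfft: int = NFFT,
                      rate: int = SAMPLE_RATE):
    """Uniform triangular filter bank over 0–Nyquist.

    Returns ``(weights, band_edges)`` where ``weights`` is
    ``(n_bands, nfft//2 + 1)``. Band k nominally covers
    ``[k*w, (k+1)*w)`` Hz (w = Nyquist / n_bands); its triangular filter
    peaks at the band center and spans the two half-neighbours, so
    adjacent filters overlap by 50% and their responses sum to ~1 over
    the interior of the axis.
    """
    nyquist = rate / 2
    width = nyquist / n_bands
    bin_hz = rate / nfft
    freqs = np.arange(nfft // 2 + 1) * bin_hz
    weights = np.zeros((n_bands, freqs.size))
    for k in range(n_bands):
        center = (k + 0.5) * width
        weights[k] = np.maximum(0.0, 1.0 - np.abs(freqs - center) / width)
    edges = tuple((k * width, (k + 1) * width) for k in range(n_bands))
    return weights, edges


def band_edges(n_bands: int = N_BANDS) -> tuple[tuple[float, float], ...]:
    """(low, high) Hz intervals, half-open, tiling 0–8 kHz uniformly."""
    return linear_filterbank(n_bands)[1]


def extract_samples(clip: VoiceClip, frame_ms: int = FRAME_MS,
                    overlap_ms: int = OVERLAP_MS) -> list[VoiceSample]:
    """Cut a clip into fixed frames and drop silent ones.

    Frames start every ``frame_ms - overlap_ms`` milliseconds from sample
    0; a trailing partial frame is discarded. A frame is silent when its
    RMS falls below ``SILENCE_RMS_FRACTION`` of the clip's peak amplitude
    (scale-free, so quiet but voiced frames survive). A clip shorter than
    one frame yields an empty list.
    """
    if overlap_ms >= frame_ms:
        raise ValueError("overlap must be shorter than the frame width")
    frame_len = int(frame_ms * SAMPLE_RATE / 1000)
    step = int((frame_ms - overlap_ms) * SAMPLE_RATE / 1000)
    w = np.asarray(clip.waveform, dtype=np.float64)
    if w.size < frame_len:
        return []
    n_frames = (w.size - frame_len) // step + 1
    idx = np.arange(frame_len)[None, :] + step * np.arange(n_frames)[:, None]
    frames = w[idx]
    peak = np.max(np.abs(w))
    rms = np.sqrt(np.mean(frames**2, axis=1))
    keep = rms >= SILENCE_RMS_FRACTION * peak if peak > 0 else np.zeros(
        n_frames, dtype=bool)
    return [VoiceSample(frame=frames[i], speaker_id=clip.speaker_id,
                        period=clip.period, kind=clip.kind,
                        vowel_label=clip.vowel_label)
            for i in np.flatnonzero(keep)]


def _frame_matrix(samples) -> np.ndarray:
    if isinstance(samples, VoiceSample):
        samples = [samples]
    if isinstance(samples, np.ndarray) and samples.ndim == 1:
        frames = samples[None, :]
    elif isinstance(samples, np.ndarray):
        frames = samples
    else:
        frames = np.stack([s.frame for s in samples])
    return np.asarray(frames, dtype=np.float64)


def power_spectra(samples) -> np.ndarray:
    """Peak-normalize, Hamming-window and FFT frames into power spectra.

    Accepts a VoiceSample, a list of them, a frame vector or a frame
    matrix; returns an ``(n, NFFT//2 + 1)`` array of non-negative values.
    """
    frames = _frame_matrix(samples)
    peaks = np.max(np.abs(frames), axis=1, keepdims=True)
    if np.any(peaks == 0):
        raise DegenerateInputError("all-zero frame in cepstral pipeline")
    frames = frames / peaks
    window = np.hamming(frames.shape[1])
    spec = np.fft.rfft(frames * window, n=NFFT, axis=1)
    return np.abs(spec) ** 2


def band_power_matrix(samples) -> np.ndarray:
    """60 filter-bank energies per frame (linear power domain, no log/DCT).

    This is the representation the F-ratio analysis consumes.
    """
    frames = _frame_matrix(samples)
    if frames.shape[0] == 0:
        raise ValueError("band_power_matrix requires at least one sample")
    weights, _ = linear_filterbank()
    return power_spectra(frames) @ weights.T


def lfcc(sample) -> np.ndarray:
    """60-dimensional LFCC of one frame."""
    return lfcc_matrix(sample)[0]


def lfcc_matrix(samples) -> np.ndarray:
    """LFCCs for many frames at once: ``(n, 60)``.

    Pipeline: peak normalization, Hamming window, 1024-point FFT, power
    spectrum, 60 uniform triangular filters, log with floor 1e-10,
    orthonormal type-II DCT.
    """
    energies = band_power_matrix(samples)
    log_e = np.log(np.maximum(energies, ENERGY_FLOOR))
    return scipy.fft.dct(log_e, type=2, norm="ortho", axis=1)


def featurize_clips(clips: list[VoiceClip], frame_ms: int = FRAME_MS,
                    overlap_ms: int = OVERLAP_MS) -> tuple[pd.DataFrame,
                                                           np.ndarray,
                                                           np.ndarray]:
    """Frame a corpus and compute LFCCs and band powers in one pass.

    Returns ``(meta, lfccs, band_powers)``: a metadata row plus one
    60-vector of each kind per surviving (non-silent) frame.
    """
    all_samples: list[VoiceSample] = []
    for clip in clips:
        all_samples.extend(extract_samples(clip, frame_ms, overlap_ms))
    if not all_samples:
        raise ValueError("no non-silent samples in corpus")
    meta = pd.DataFrame({
        "speaker_id": [s.speaker_id for s in all_samples],
        "period": [s.period for s in all_samples],
        "kind": [s.kind for s in all_samples],
        "vowel_label": [s.vowel_label for s in all_samples],
    })
    frames = np.stack([s.frame for s in all_samples])
    powers = band_power_matrix(frames)
    log_e = np.log(np.maximum(powers, ENERGY_FLOOR))
    lfccs = scipy.fft.dct(log_e, type=2, norm="ortho", axis=1)
    return meta, lfccs, powers
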