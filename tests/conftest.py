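"""Shared fixtures: one default two-period cohort per test session."""

import numpy as np
import pytest

from voxage import features, robustness, synth_voice

COHORT_SEED = 101
CORPUS_SEED = 102


@pytest.fixture(scope="session")
def cohort():
    return synth_voice.make_cohort(3, 3, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def corpus(cohort):
    return synth_voice.generate_corpus(cohort, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def featurized(corpus):
    """(meta, lfccs, band_powers) for every non-silent frame of the corpus."""
    return features.featurize_clips(corpus)


@pytest.fixture(scope="session")
def vowel_band_medians(corpus):
    """person -> period -> (n_clips, 60) spectrogram band medians."""
    return robustness.corpus_band_medians(corpus, kind="vowel")


@pytest.fixture(scope="session")
def target_ids(cohort):
    return [p.speaker_id for p in cohort if p.role == "target"]


def estimate_f0(waveform, rate=16000, lo_hz=80, hi_hz=400):
    """Autocorrelation pitch oracle used by several synthesis tests.

    The waveform is low-passed below the first formant region first so
    that formant ringing cannot masquerade as a sub-period peak.
    """
    from scipy.signal import butter, filtfilt

    w = np.asarray(waveform, dtype=float)
    b, a = butter(4, 450.0, btype="low", fs=rate)
    w = filtfilt(b, a, w - w.mean())
    ac = np.correlate(w, w, "full")[w.size - 1:]
    lo, hi = int(rate / hi_hz), int(rate / lo_hz)
    window = ac[lo:hi]
    # subharmonic lags (2T, 3T...) rival the true period under jitter:
    # take the smallest lag within 90% of the window maximum
    lag = lo + int(np.flatnonzero(window >= 0.9 * window.max())[0])
    return rate / lag
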