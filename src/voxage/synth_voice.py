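"""Seeded two-period synthetic voice corpora with designed individuality.

Emulates a longitudinal voice corpus in which each speaker is recorded in
two developmental periods: an *unstable* period (immature vocal organs,
higher and more variable fundamental frequency) and a *stable* period
(mature vocal organs). Speaker identity is planted as a set of
*invariant resonance peaks* — narrow spectral amplifications whose center
frequencies are unique to each speaker and identical in both periods,
concentrated in the 1–2 kHz and 4–6 kHz regions. Everything else that
shapes the spectrum (fundamental frequency, vowel formants, an extra pair
of speaker-specific resonances) drifts between periods, so only the
invariant peaks carry cross-period individuality.

Synthesis follows a simple source-filter scheme: a jittered glottal
impulse train is passed through parallel second-order peak resonators for
the vowel formants, the invariant peaks and the period-specific
resonances, then Gaussian noise is added at a fixed floor. All randomness
flows from explicit integer seeds; every output is a pure function of its
arguments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import iirpeak, lfilter

SAMPLE_RATE = 16_000
UNSTABLE = "unstable"
STABLE = "stable"
PERIODS = (UNSTABLE, STABLE)
VOWELS = ("a", "i", "u", "e", "o")

#: Canonical Japanese vowel formants (center Hz, bandwidth Hz) F1/F2/F3.
VOWEL_FORMANTS: dict[str, tuple[tuple[float, float], ...]] = {
    "a": ((800.0, 90.0), (1200.0, 110.0), (2700.0, 160.0)),
    "i": ((300.0, 70.0), (2300.0, 120.0), (3000.0, 170.0)),
    "u": ((350.0, 70.0), (1200.0, 110.0), (2800.0, 160.0)),
    "e": ((500.0, 80.0), (1900.0, 120.0), (2800.0, 160.0)),
    "o": ((500.0, 80.0), (800.0, 100.0), (2700.0, 160.0)),
}

# Mean F0 defaults (Hz): adolescent males drop sharply across the voice
# change; females drift mildly.
F0_DEFAULTS = {
    "male": {UNSTABLE: 180.0, STABLE: 120.0},
    "female": {UNSTABLE: 250.0, STABLE: 220.0},
}

INVARIANT_PEAK_GAIN_DB = 12.0
INVARIANT_PEAK_BW_HZ = 150.0
PERIOD_FORMANT_GAIN_DB = 13.0
VOWEL_FORMANT_GAIN_DB = 12.0
BREATH_NOISE_STD = 0.05  # aspiration noise added to the glottal source
TARGET_RMS = 0.1  # clips are level-normalized to this RMS

#: Regions (Hz) in which the designed invariant peaks live.
LOW_INVARIANT_REGION = (1000.0, 2000.0)
HIGH_INVARIANT_REGION = (4000.0, 6000.0)


@dataclass(frozen=True)
class Resonance:
    """A second-order spectral peak: center (Hz), bandwidth (Hz), gain (dB)."""

    center_hz: float
    bandwidth_hz: float
    gain_db: float


@dataclass(frozen=True)
class SpeakerProfile:
    """Ground-truth acoustic identity of one synthetic speaker.

    ``invariant_peaks`` are identical in both periods by construction and
    are the only spectral cue that survives the period change;
    ``f0_by_period`` and ``formants_by_period`` drift between periods.
    """

    speaker_id: str
    role: str  # "target" | "non_target"
    sex: str  # "male" | "female"
    invariant_peaks: tuple[Resonance, ...]
    f0_by_period: dict[str, float]
    formants_by_period: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for p in self.invariant_peaks:
            if p.center_hz >= SAMPLE_RATE / 2:
                raise ValueError(f"peak at {p.center_hz} Hz is above Nyquist")


@dataclass(frozen=True)
class PeriodSpec:
    """Recording conditions for one developmental period."""

    name: str
    n_clips_per_speaker: int = 8  # phrase clips
    n_vowel_clips_per_speaker: int = 4  # per vowel
    f0_jitter: float = 0.02  # relative std of pulse-interval jitter
    clip_f0_scatter: float = 0.08  # relative sd of per-clip mean F0
    noise_floor_db: float = -40.0


#: Default period conditions. The stable period has half the unstable
#: period's clips, mirroring the sample imbalance of longitudinal corpora
#: in which adult material is scarcer; the unstable period's pitch
#: wanders more from clip to clip (immature pitch control).
DEFAULT_PERIODS: dict[str, PeriodSpec] = {
    UNSTABLE: PeriodSpec(UNSTABLE, n_clips_per_speaker=8,
                         n_vowel_clips_per_speaker=4,
                         clip_f0_scatter=0.08),
    STABLE: PeriodSpec(STABLE, n_clips_per_speaker=4,
                       n_vowel_clips_per_speaker=2,
                       clip_f0_scatter=0.05),
}


@dataclass(frozen=True)
class VoiceClip:
    """A labeled mono waveform at 16 kHz."""

    waveform: np.ndarray  # float64 in [-1, 1]
    speaker_id: str
    period: str
    kind: str  # "phrase" | "vowel"
    vowel_label: str  # "a".."o" | "none"
    seed_used: int

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / SAMPLE_RATE


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def make_cohort(n_male: int, n_female: int, seed: int) -> list[SpeakerProfile]:
    """Build a seeded cohort of speaker profiles with distinct invariant peaks.

    Every speaker receives one invariant peak inside 1–2 kHz and one inside
    4–6 kHz; centers are spread on jittered grids so any two speakers
    differ by at least 50 Hz in at least one peak. The first male and the
    first female are flagged ``role="target"`` (the two verification
    targets); everyone else is a non-target.
    """
    if n_male < 0 or n_female < 0 or n_male + n_female < 2:
        raise ValueError("need non-negative counts with at least 2 speakers")
    n = n_male + n_female
    rng = np.random.default_rng(seed)

    def slots(low: float, high: float, jitter: float) -> np.ndarray:
        centers = np.linspace(low, high, n)
        spacing = (high - low) / max(n - 1, 1)
        j = min(jitter, max(0.0, (spacing - 60.0) / 2))
        centers = centers + rng.uniform(-j, j, size=n)
        return rng.permutation(centers)

    low_centers = slots(1080.0, 1920.0, 30.0)
    high_centers = slots(4150.0, 5850.0, 50.0)

    profiles: list[SpeakerProfile] = []
    sexes = ["male"] * n_male + ["female"] * n_female
    for idx, sex in enumerate(sexes):
        peaks = (
            Resonance(float(low_centers[idx]), INVARIANT_PEAK_BW_HZ,
                      INVARIANT_PEAK_GAIN_DB),
            Resonance(float(high_centers[idx]), INVARIANT_PEAK_BW_HZ,
                      INVARIANT_PEAK_GAIN_DB),
        )
        f0_offset = float(rng.uniform(-10.0, 10.0))
        f0 = {p: F0_DEFAULTS[sex][p] + f0_offset for p in PERIODS}
        # Period-specific resonances: speaker-specific individuality that
        # does NOT survive the period change — vocal-tract growth moves
        # them to a different region entirely. Kept outside 1-2 and
        # 4-6 kHz so they never shadow the invariant peaks.
        formants = {
            UNSTABLE: ((float(rng.uniform(2500.0, 3500.0)), 250.0),),
            STABLE: ((float(rng.uniform(7300.0, 7900.0)), 250.0),),
        }
        # exactly one target per sex when counts permit: the first male
        # and the first female
        role = "target" if idx in (0, n_male) and idx < n else "non_target"
        profiles.append(SpeakerProfile(
            speaker_id=f"{'M' if sex == 'male' else 'F'}{idx:02d}",
            role=role, sex=sex, invariant_peaks=peaks,
            f0_by_period=f0, formants_by_period=formants))
    return profiles


def _apply_resonances(x: np.ndarray,
                      resonances: list[Resonance]) -> np.ndarray:
    """Add parallel unity-peak bandpass branches: y = x + sum (g-1) P_i(x)."""
    y = x.astype(float).copy()
    for r in resonances:
        q = r.center_hz / r.bandwidth_hz
        b, a = iirpeak(r.center_hz, q, fs=SAMPLE_RATE)
        gain = 10.0 ** (r.gain_db / 20.0)
        y += (gain - 1.0) * lfilter(b, a, x)
    return y


def _impulse_train(n: int, f0: float, jitter: float,
                   rng: np.random.Generator) -> np.ndarray:
    x = np.zeros(n)
    t = 0.0
    while t < n:
        x[int(t)] = 1.0
        period = SAMPLE_RATE / (f0 * (1.0 + rng.normal(0.0, jitter)))
        t += max(period, 2.0)
    return x


def synthesize_vowel(profile: SpeakerProfile, period: PeriodSpec,
                     vowel: str, duration: float, seed: int) -> VoiceClip:
    """Source-filter synthesis of a sustained vowel for one speaker/period.

    A jittered impulse train at the period's fundamental frequency, plus
    a weak aspiration-noise component, is shaped by the canonical
    formants of ``vowel``, the speaker's invariant peaks and the
    period-specific resonances; the clip is level-normalized to a fixed
    RMS and measurement noise is added at the period's noise floor.
    Peak amplitude is kept <= 1.
    """
    if vowel not in VOWELS:
        raise ValueError(f"unknown vowel label: {vowel!r}")
    if duration < 0.05:
        raise ValueError("duration must be at least one 50 ms frame")
    rng = np.random.default_rng(seed)
    n = int(round(duration * SAMPLE_RATE))
    # speakers do not hold one exact pitch across recordings: each clip
    # draws its own mean F0 around the period mean
    f0 = profile.f0_by_period[period.name] * (
        1.0 + rng.normal(0.0, period.clip_f0_scatter))
    src = _impulse_train(n, f0, period.f0_jitter, rng)
    src += rng.normal(0.0, BREATH_NOISE_STD, size=n)

    resonances = [Resonance(c, bw, VOWEL_FORMANT_GAIN_DB)
                  for c, bw in VOWEL_FORMANTS[vowel]]
    resonances += list(profile.invariant_peaks)
    resonances += [Resonance(c, bw, PERIOD_FORMANT_GAIN_DB)
                   for c, bw in profile.formants_by_period[period.name]]
    y = _apply_resonances(src, resonances)

    y *= TARGET_RMS / np.sqrt(np.mean(y**2))
    y += rng.normal(0.0, 10.0 ** (period.noise_floor_db / 20.0), size=n)
    peak = np.max(np.abs(y))
    if peak > 1.0:
        y /= peak
    return VoiceClip(waveform=y, speaker_id=profile.speaker_id,
                     period=period.name, kind="vowel", vowel_label=vowel,
                     seed_used=seed)


def synthesize_phrase(profile: SpeakerProfile, period: PeriodSpec,
                      n_segments: int, seed: int,
                      segment_duration: float = 0.2) -> VoiceClip:
    """Phrase stand-in: cross-faded vowel-like segments with noise bursts.

    Segments are random vowels of ``segment_duration`` seconds, joined by
    10 ms linear cross-fades; between segments an unvoiced 30 ms noise
    burst (a consonant stand-in) is inserted with probability 0.3.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = np.random.default_rng(seed)
    fade = int(0.010 * SAMPLE_RATE)
    pieces: list[np.ndarray] = []
    for i in range(n_segments):
        vowel = str(rng.choice(VOWELS))
        clip = synthesize_vowel(profile, period, vowel, segment_duration,
                                seed=_child_seed(rng))
        pieces.append(clip.waveform)
        if i < n_segments - 1 and rng.random() < 0.3:
            burst = rng.normal(0.0, 0.05, size=int(0.030 * SAMPLE_RATE))
            pieces.append(burst)

    out = pieces[0]
    ramp_up = np.linspace(0.0, 1.0, fade)
    for piece in pieces[1:]:
        head, tail = out[:-fade], out[-fade:]
        mixed = tail * ramp_up[::-1] + piece[:fade] * ramp_up
        out = np.concatenate([head, mixed, piece[fade:]])
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out = out / peak
    return VoiceClip(waveform=out, speaker_id=profile.speaker_id,
                     period=period.name, kind="phrase", vowel_label="none",
                     seed_used=seed)


def generate_corpus(cohort: list[SpeakerProfile],
                    periods: dict[str, PeriodSpec] | None = None,
                    seed: int = 0,
                    phrase_segments: int = 5,
                    vowel_duration: float = 0.4) -> list[VoiceClip]:
    """Generate the full two-period corpus for a cohort.

    Per speaker and period: ``n_clips_per_speaker`` phrase clips and
    ``n_vowel_clips_per_speaker`` clips of each of the five vowels.
    Deterministic given ``seed``.
    """
    periods = DEFAULT_PERIODS if periods is None else periods
    rng = np.random.default_rng(seed)
    clips: list[VoiceClip] = []
    for profile in cohort:
        for period in periods.values():
            for _ in range(period.n_clips_per_speaker):
                clips.append(synthesize_phrase(
                    profile, period, phrase_segments, seed=_child_seed(rng)))
            for vowel in VOWELS:
                for _ in range(period.n_vowel_clips_per_speaker):
                    clips.append(synthesize_vowel(
                        profile, period, vowel, vowel_duration,
                        seed=_child_seed(rng)))
    return clips


def write_corpus(clips: list[VoiceClip], directory: str) -> pd.DataFrame:
    """Write 16-bit mono WAVs plus a manifest CSV; return the manifest."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, clip in enumerate(clips):
        name = (f"{clip.speaker_id}_{clip.period}_{clip.kind}_"
                f"{clip.vowel_label}_{i:04d}.wav")
        path = os.path.join(directory, name)
        pcm = np.round(np.clip(clip.waveform, -1.0, 1.0) * 32767.0)
        try:
            wavfile.write(path, SAMPLE_RATE, pcm.astype(np.int16))
        except OSError as exc:
            raise OSError(f"failed to write {path}: {exc}") from exc
        rows.append({"speaker_id": clip.speaker_id, "period": clip.period,
                     "kind": clip.kind, "vowel_label": clip.vowel_label,
                     "path": name, "seed": clip.seed_used})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(directory, "manifest.csv"), index=False)
    return manifest


def read_corpus(directory: str) -> list[VoiceClip]:
    """Read back a corpus written by :func:`write_corpus`."""
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    clips = []
    for row in manifest.itertuples():
        rate, data = wavfile.read(os.path.join(directory, row.path))
        if rate != SAMPLE_RATE:
            raise ValueError(f"{row.path}: expected {SAMPLE_RATE} Hz, "
                             f"got {rate}")
        clips.append(VoiceClip(
            waveform=data.astype(np.float64) / 32767.0,
            speaker_id=row.speaker_id, period=row.period, kind=row.kind,
            vowel_label=str(row.vowel_label), seed_used=int(row.seed)))
    return clips
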