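"""Band-median centroid analysis of cross-period robustness.

Do the 1–2 kHz and 4–6 kHz regions carry individuality that survives the
period change better than the rest of the spectrum? For each clip a
magnitude spectrogram (50 ms Hamming frames every 10 ms, 1024-point FFT)
is reduced to 60 per-band medians. A *replicate* then draws, per period,
``pairs_per_centroid`` random (u, v) pairs — u a median from one
frequency region, v a median from a second, disjoint region — and
averages them into a 2-D centroid; the Euclidean distance between a
person's two period centroids measures how far their spectral signature
moved with age. Under the *invariant* condition the two regions are
1–2 kHz and 4–6 kHz; under the *other* condition each replicate uses
size-matched random disjoint band subsets drawn entirely outside those
regions. Small invariant-condition distances relative to the other
condition (per-person one-sided rank-sum) indicate age-robust
individuality in the designated regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .features import NFFT, N_BANDS, band_edges
from .synth_voice import SAMPLE_RATE, VoiceClip

CONDITION_INVARIANT = "invariant"
CONDITION_OTHER = "other"
INVARIANT_REGIONS = ((1000.0, 2000.0), (4000.0, 6000.0))
DEFAULT_N_REPLICATES = 3000
DEFAULT_PAIRS_PER_CENTROID = 50


def _region_bands(low: float, high: float) -> list[int]:
    edges = band_edges()
    return [k for k, (lo, hi) in enumerate(edges)
            if lo >= low - 1e-9 and hi <= high + 1e-9]


def spectrogram_band_medians(clip: VoiceClip,
                             frame_ms: int = 50,
                             overlap_ms: int = 40) -> np.ndarray:
    """60 medians of magnitude-spectrogram cells, one per frequency band.

    Frames follow the feature pipeline's framing and Hamming window but
    the amplitudes are NOT peak-normalized (the medians compare absolute
    levels); a band's median pools every (frame, bin) cell whose bin
    frequency falls inside the band's half-open interval.
    """
    if overlap_ms >= frame_ms:
        raise ValueError("overlap must be shorter than the frame width")
    frame_len = int(frame_ms * SAMPLE_RATE / 1000)
    step = int((frame_ms - overlap_ms) * SAMPLE_RATE / 1000)
    w = np.asarray(clip.waveform, dtype=np.float64)
    if w.size < frame_len:
        raise ValueError("clip shorter than one analysis frame")
    n_frames = (w.size - frame_len) // step + 1
    idx = np.arange(frame_len)[None, :] + step * np.arange(n_frames)[:, None]
    frames = w[idx] * np.hamming(frame_len)
    mag = np.abs(np.fft.rfft(frames, n=NFFT, axis=1))  # (frames, bins)

    bin_hz = SAMPLE_RATE / NFFT
    freqs = np.arange(mag.shape[1]) * bin_hz
    medians = np.zeros(N_BANDS)
    for k, (lo, hi) in enumerate(band_edges()):
        cols = (freqs >= lo) & (freqs < hi)
        medians[k] = np.median(mag[:, cols])
    return medians


def sample_median_pairs(vectors, region_a_bands, region_b_bands,
                        n_pairs: int, seed: int) -> np.ndarray:
    """Random (u, v) pairs of band medians from two disjoint regions.

    Each coordinate independently picks a uniformly random vector and a
    uniformly random band within its region. Returns ``(n_pairs, 2)``.
    """
    a = np.asarray(sorted(region_a_bands), dtype=int)
    b = np.asarray(sorted(region_b_bands), dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both regions must contain at least one band")
    if np.intersect1d(a, b).size:
        raise ValueError("regions must be disjoint")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    M = np.stack([np.asarray(v, dtype=np.float64) for v in vectors])
    rng = np.random.default_rng(seed)
    u = M[rng.integers(0, M.shape[0], n_pairs),
          a[rng.integers(0, a.size, n_pairs)]]
    v = M[rng.integers(0, M.shape[0], n_pairs),
          b[rng.integers(0, b.size, n_pairs)]]
    return np.column_stack([u, v])


def centroid(pairs) -> tuple[float, float]:
    """Component-wise mean of a non-empty set of 2-D points."""
    pts = np.asarray(pairs, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("cannot take the centroid of zero pairs")
    c = pts.reshape(-1, 2).mean(axis=0)
    return float(c[0]), float(c[1])


def _draw_other_regions(rng: np.random.Generator,
                        pool: np.ndarray,
                        size_a: int, size_b: int):
    chosen = rng.choice(pool, size=size_a + size_b, replace=False)
    return chosen[:size_a], chosen[size_a:]


def cross_period_distances(medians_by_person: dict,
                           condition: str,
                           n_replicates: int = DEFAULT_N_REPLICATES,
                           pairs_per_centroid: int =
                           DEFAULT_PAIRS_PER_CENTROID,
                           seed: int = 0,
                           periods: tuple[str, str] = ("unstable", "stable"),
                           ) -> pd.DataFrame:
    """Replicated centroid distances per person under one region condition.

    ``medians_by_person`` maps person -> period -> (n_clips, 60) matrix of
    band-median vectors. Each replicate forms one centroid per period
    (two centroids) and one distance, so ``n_replicates`` distances rest
    on ``2 * n_replicates`` centroids per person. Returns a long table
    (person, condition, replicate, distance). Deterministic given seed.

    Draws are *paired* across the two periods: each pair uses the same
    band and the same uniform deviate for the clip choice in both
    periods, so the distance isolates the between-period change (a
    person whose two periods are identical gets distance exactly 0)
    while remaining valid under unequal per-period clip counts.
    """
    if condition not in (CONDITION_INVARIANT, CONDITION_OTHER):
        raise ValueError(f"unknown condition {condition!r}")
    missing = [p for p, by_period in medians_by_person.items()
               if any(s not in by_period or len(by_period[s]) == 0
                      for s in periods)]
    if missing:
        raise ValueError("persons missing a period: " + ", ".join(
            str(m) for m in sorted(missing)))

    bands_a = np.asarray(_region_bands(*INVARIANT_REGIONS[0]), dtype=int)
    bands_b = np.asarray(_region_bands(*INVARIANT_REGIONS[1]), dtype=int)
    pool = np.asarray([k for k in range(N_BANDS)
                       if k not in set(bands_a) | set(bands_b)], dtype=int)

    master = np.random.SeedSequence(seed)
    rows = []
    for person, person_ss in zip(sorted(medians_by_person),
                                 master.spawn(len(medians_by_person))):
        rng = np.random.default_rng(person_ss)
        mats = {s: np.asarray(medians_by_person[person][s], dtype=np.float64)
                for s in periods}
        for rep in range(n_replicates):
            if condition == CONDITION_OTHER:
                reg_a, reg_b = _draw_other_regions(rng, pool, bands_a.size,
                                                   bands_b.size)
            else:
                reg_a, reg_b = bands_a, bands_b
            band_u = reg_a[rng.integers(0, reg_a.size, pairs_per_centroid)]
            band_v = reg_b[rng.integers(0, reg_b.size, pairs_per_centroid)]
            clip_u = rng.random(pairs_per_centroid)
            clip_v = rng.random(pairs_per_centroid)
            cents = []
            for s in periods:
                M = mats[s]
                u = M[(clip_u * M.shape[0]).astype(int), band_u]
                v = M[(clip_v * M.shape[0]).astype(int), band_v]
                cents.append((u.mean(), v.mean()))
            d = float(np.hypot(cents[0][0] - cents[1][0],
                               cents[0][1] - cents[1][1]))
            rows.append((person, condition, rep, d))
    return pd.DataFrame(rows, columns=["person_id", "condition",
                                       "replicate", "distance"])


def distance_summary(samples: pd.DataFrame) -> dict:
    """Boxplot statistics per (person, condition) plus rank-sum contrasts.

    When both conditions are present for a person, reports the one-sided
    Mann-Whitney test that invariant-condition distances are
    stochastically smaller than other-condition distances.
    """
    if samples.empty:
        raise ValueError("no distance samples")
    stats = []
    for (person, condition), grp in samples.groupby(
            ["person_id", "condition"]):
        d = grp["distance"].to_numpy()
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        stats.append({"person_id": person, "condition": condition,
                      "n": int(d.size), "min": float(d.min()),
                      "q1": float(q1), "median": float(med),
                      "q3": float(q3), "max": float(d.max()),
                      "mean": float(d.mean())})
    comparisons = []
    for person, grp in samples.groupby("person_id"):
        inv = grp.loc[grp["condition"] == CONDITION_INVARIANT, "distance"]
        oth = grp.loc[grp["condition"] == CONDITION_OTHER, "distance"]
        if len(inv) and len(oth):
            res = mannwhitneyu(inv, oth, alternative="less")
            comparisons.append({"person_id": person,
                                "statistic": float(res.statistic),
                                "p_value": float(res.pvalue),
                                "invariant_median": float(inv.median()),
                                "other_median": float(oth.median())})
    return {"per_person_condition": stats, "comparisons": comparisons}


def corpus_band_medians(clips: list[VoiceClip],
                        kind: str = "vowel") -> dict:
    """Build the person -> period -> median-matrix mapping from clips.

    By default pools all vowel clips of a person/period; pass a filtered
    clip list (e.g. a single vowel) for a stratified analysis.
    """
    out: dict = {}
    for clip in clips:
        if kind is not None and clip.kind != kind:
            continue
        vec = spectrogram_band_medians(clip)
        out.setdefault(clip.speaker_id, {}).setdefault(clip.period,
                                                       []).append(vec)
    return {p: {s: np.stack(v) for s, v in by_period.items()}
            for p, by_period in out.items()}
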