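"""Per-band Fisher F-ratio profiles of speaker individuality.

For band k, speaker i and period s, with x_{i,s,j,k} the filter-bank
power of sample j:

    mu_{i,s,k} = (1/N_{i,s}) sum_j x_{i,s,j,k}          (speaker mean)
    mu_{s,k}   = (1/I) sum_i mu_{i,s,k}                 (cohort mean)

    F-ratio_{i,s,k} = [ (1/I) sum_i (mu_{i,s,k} - mu_{s,k})^2 ]
                      / [ (1/N_{i,s}) sum_j (x_{i,s,j,k} - mu_{i,s,k})^2 ]

The numerator (inter-speaker variance of the band) is shared by all
speakers in a period; the denominator is speaker i's intra-speaker
variance, so a high profile value marks a band where the cohort spreads
out but speaker i is self-consistent. Each 60-band profile is min-max
normalized to [0, 1] so profiles are comparable across periods and
speakers. Cohort means weight speakers equally regardless of how many
samples each contributes (important under period imbalance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import N_BANDS, band_edges


@dataclass(frozen=True)
class BandPowerDataset:
    """Band powers (n_samples, 60) with per-sample speaker/period labels."""

    values: np.ndarray
    speaker_ids: np.ndarray
    periods: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.speaker_ids) != len(self.values) or \
                len(self.periods) != len(self.values):
            raise ValueError("label lengths must match the sample count")

    @classmethod
    def from_meta(cls, meta: pd.DataFrame,
                  powers: np.ndarray) -> "BandPowerDataset":
        return cls(values=np.asarray(powers, dtype=np.float64),
                   speaker_ids=meta["speaker_id"].to_numpy(),
                   periods=meta["period"].to_numpy())

    def subset(self, mask) -> "BandPowerDataset":
        return BandPowerDataset(self.values[mask], self.speaker_ids[mask],
                                self.periods[mask])

    def speakers(self) -> list:
        return sorted(set(self.speaker_ids.tolist()))


@dataclass(frozen=True)
class FRatioProfile:
    speaker_id: str
    period: str
    raw_values: np.ndarray  # 60 non-negative values, +inf where degenerate
    normalized_values: np.ndarray  # min-max within this profile
    band_edges: tuple
    degenerate_bands: tuple  # indices whose intra-speaker variance was 0


def speaker_band_mean(ds: BandPowerDataset, speaker, period) -> np.ndarray:
    """Per-band mean power of one speaker in one period."""
    mask = (ds.speaker_ids == speaker) & (ds.periods == period)
    if not mask.any():
        raise ValueError(f"no samples for speaker {speaker!r} in {period!r}")
    return ds.values[mask].mean(axis=0)


def global_band_mean(ds: BandPowerDataset, period) -> np.ndarray:
    """Unweighted mean of the per-speaker means (speakers count equally)."""
    speakers = [s for s in ds.speakers()
                if ((ds.speaker_ids == s) & (ds.periods == period)).any()]
    if len(speakers) < 2:
        raise ValueError("need at least two speakers in the period")
    return np.mean([speaker_band_mean(ds, s, period) for s in speakers],
                   axis=0)


def f_ratio(ds: BandPowerDataset, speaker, period) -> np.ndarray:
    """Raw 60-band F-ratio of one speaker in one period.

    Bands with zero intra-speaker variance yield +inf (sentinel, flagged
    downstream) rather than raising, so degenerate synthetic bands do not
    abort a run.
    """
    mask = (ds.speaker_ids == speaker) & (ds.periods == period)
    if mask.sum() < 2:
        raise ValueError("need >= 2 samples for the intra-speaker variance")
    speakers = [s for s in ds.speakers()
                if ((ds.speaker_ids == s) & (ds.periods == period)).any()]
    if len(speakers) < 2:
        raise ValueError("need at least two speakers in the period")
    means = np.stack([speaker_band_mean(ds, s, period) for s in speakers])
    grand = means.mean(axis=0)
    numerator = np.mean((means - grand) ** 2, axis=0)
    x = ds.values[mask]
    denominator = np.mean((x - x.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denominator > 0, numerator / denominator, np.inf)


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Rescale a finite value set linearly onto [0, 1]."""
    raw = np.asarray(raw, dtype=np.float64)
    finite = raw[np.isfinite(raw)]
    if finite.size < 2 or finite.min() == finite.max():
        raise ValueError("min-max normalization needs two distinct "
                         "finite values")
    lo, hi = finite.min(), finite.max()
    clipped = np.clip(raw, lo, hi)  # +inf sentinels map to 1
    return (clipped - lo) / (hi - lo)


def fratio_profile(ds: BandPowerDataset, speaker, period) -> FRatioProfile:
    raw = f_ratio(ds, speaker, period)
    return FRatioProfile(
        speaker_id=str(speaker), period=str(period), raw_values=raw,
        normalized_values=minmax_normalize(raw),
        band_edges=band_edges(),
        degenerate_bands=tuple(np.flatnonzero(~np.isfinite(raw)).tolist()))


def all_profiles(ds: BandPowerDataset) -> list[FRatioProfile]:
    """One profile per (speaker, period) present in the dataset."""
    out = []
    for period in sorted(set(ds.periods.tolist())):
        for speaker in ds.speakers():
            mask = (ds.speaker_ids == speaker) & (ds.periods == period)
            if mask.sum() >= 2:
                out.append(fratio_profile(ds, speaker, period))
    return out


def vowel_averaged_profiles(meta: pd.DataFrame,
                            powers: np.ndarray) -> list[FRatioProfile]:
    """Per-vowel profiles averaged into one curve per (speaker, period).

    The F-ratio is computed separately within each vowel (so vowel
    formant differences do not inflate the intra-speaker variance) and
    the five normalized curves are averaged. This is the vowel-sample
    view in which low-frequency (1–2 kHz) individuality becomes visible.
    """
    vowels = sorted(v for v in set(meta["vowel_label"]) if v != "none")
    if not vowels:
        raise ValueError("no vowel samples in the dataset")
    curves: dict[tuple[str, str], list[np.ndarray]] = {}
    for vowel in vowels:
        mask = (meta["vowel_label"] == vowel).to_numpy()
        ds = BandPowerDataset.from_meta(meta[mask], powers[mask])
        for prof in all_profiles(ds):
            curves.setdefault((prof.speaker_id, prof.period),
                              []).append(prof.normalized_values)
    out = []
    for (speaker, period), vals in sorted(curves.items()):
        mean_curve = np.mean(vals, axis=0)
        out.append(FRatioProfile(
            speaker_id=speaker, period=period,
            raw_values=mean_curve, normalized_values=mean_curve,
            band_edges=band_edges(), degenerate_bands=()))
    return out


def bands_in_region(low_hz: float, high_hz: float,
                    edges=None) -> list[int]:
    """Indices of bands wholly inside [low_hz, high_hz]."""
    edges = band_edges() if edges is None else edges
    return [k for k, (lo, hi) in enumerate(edges)
            if lo >= low_hz - 1e-9 and hi <= high_hz + 1e-9]


def band_region_report(profiles: list[FRatioProfile],
                       regions: list[tuple[float, float]]) -> dict:
    """Contrast normalized F-ratio inside vs outside frequency regions.

    A region is *period-robust* for a speaker when its inside mean
    exceeds the outside mean in both periods. The report lists the
    per-profile contrasts and, per region, the speakers for whom it is
    period-robust.
    """
    if not regions:
        raise ValueError("at least one region required")
    for low, high in regions:
        if not bands_in_region(low, high):
            raise ValueError(f"region {low}-{high} Hz contains no band")

    per_profile = []
    for prof in profiles:
        for low, high in regions:
            inside = bands_in_region(low, high, prof.band_edges)
            outside = [k for k in range(len(prof.band_edges))
                       if k not in inside]
            per_profile.append({
                "speaker_id": prof.speaker_id, "period": prof.period,
                "region": (low, high),
                "inside_mean": float(prof.normalized_values[inside].mean()),
                "outside_mean": float(
                    prof.normalized_values[outside].mean())
                if outside else float("nan"),
            })

    speakers = sorted({p.speaker_id for p in profiles})
    periods = sorted({p.period for p in profiles})
    region_summary = []
    for low, high in regions:
        robust = []
        for speaker in speakers:
            rows = [r for r in per_profile
                    if r["speaker_id"] == speaker and r["region"] == (low,
                                                                      high)]
            if len(rows) == len(periods) and all(
                    r["inside_mean"] > r["outside_mean"] for r in rows):
                robust.append(speaker)
        region_summary.append({"region": (low, high),
                               "robust_speakers": robust,
                               "n_robust": len(robust),
                               "n_speakers": len(speakers)})
    return {"per_profile": per_profile, "regions": region_summary}


def profiles_to_frame(profiles: list[FRatioProfile]) -> pd.DataFrame:
    """Long-format table: one row per (speaker, period, band)."""
    rows = []
    for prof in profiles:
        for k, (lo, hi) in enumerate(prof.band_edges):
            rows.append({"speaker_id": prof.speaker_id,
                         "period": prof.period,
                         "band": k, "band_low_hz": lo, "band_high_hz": hi,
                         "raw": prof.raw_values[k],
                         "normalized": prof.normalized_values[k]})
    return pd.DataFrame(rows)
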