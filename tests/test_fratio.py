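"""Fisher F-ratio profiles: hand-checked values, a naive triple-loop
oracle, normalization contracts and the permutation null."""

import numpy as np
import pandas as pd
import pytest

from voxage import fratio
from voxage.fratio import BandPowerDataset


def make_ds(per_speaker: dict, period="unstable"):
    """Build a dataset from {speaker: (n_samples, n_bands) array}."""
    values, speakers = [], []
    for s, x in per_speaker.items():
        x = np.atleast_2d(np.asarray(x, float))
        values.append(x)
        speakers += [s] * len(x)
    values = np.vstack(values)
    return BandPowerDataset(values, np.array(speakers),
                            np.array([period] * len(values)))


def naive_f_ratio(per_speaker: dict, target):
    """Triple-loop transliteration of the defining sums."""
    speakers = sorted(per_speaker)
    n_bands = np.atleast_2d(per_speaker[target]).shape[1]
    out = np.zeros(n_bands)
    for k in range(n_bands):
        mus = {}
        for s in speakers:
            x = np.atleast_2d(per_speaker[s])
            total = 0.0
            for j in range(len(x)):
                total += x[j, k]
            mus[s] = total / len(x)
        grand = sum(mus.values()) / len(speakers)
        num = sum((mus[s] - grand) ** 2 for s in speakers) / len(speakers)
        x = np.atleast_2d(per_speaker[target])
        den = sum((x[j, k] - mus[target]) ** 2
                  for j in range(len(x))) / len(x)
        out[k] = num / den
    return out


class TestSpeakerBandMean:
    def test_simple_mean(self):
        ds = make_ds({"a": [[1.0], [3.0]], "b": [[5.0], [7.0]]})
        assert fratio.speaker_band_mean(ds, "a", "unstable") == \
            pytest.approx([2.0])

    def test_constant_samples(self):
        ds = make_ds({"a": [[4.0, 2.0]] * 3, "b": [[1.0, 1.0]]})
        np.testing.assert_allclose(
            fratio.speaker_band_mean(ds, "a", "unstable"), [4.0, 2.0])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(89)
        x = rng.random((10, 60))
        ds = make_ds({"a": x, "b": rng.random((4, 60))})
        loop = np.array([sum(x[j, k] for j in range(10)) / 10
                         for k in range(60)])
        np.testing.assert_allclose(
            fratio.speaker_band_mean(ds, "a", "unstable"), loop,
            rtol=1e-12)

    def test_missing_speaker_rejected(self):
        ds = make_ds({"a": [[1.0]], "b": [[2.0]]})
        with pytest.raises(ValueError):
            fratio.speaker_band_mean(ds, "c", "unstable")


class TestGlobalBandMean:
    def test_mean_of_speaker_means(self):
        ds = make_ds({"a": [[2.0]], "b": [[6.0]]})
        assert fratio.global_band_mean(ds, "unstable") == pytest.approx([4.0])

    def test_equal_speaker_weighting_under_imbalance(self):
        # speaker a contributes 9 samples, b only 1: the cohort mean must
        # ignore the imbalance, unlike a pooled mean over samples
        ds = make_ds({"a": [[0.0]] * 9, "b": [[10.0]]})
        cohort = fratio.global_band_mean(ds, "unstable")[0]
        pooled = ds.values.mean()
        assert cohort == pytest.approx(5.0)
        assert pooled == pytest.approx(1.0)
        assert cohort != pooled

    def test_single_speaker_rejected(self):
        ds = make_ds({"a": [[1.0]]})
        with pytest.raises(ValueError):
            fratio.global_band_mean(ds, "unstable")


class TestFRatio:
    def test_hand_computed_example(self):
        # A: [1, 3] -> mu 2, B: [5, 7] -> mu 6, grand mean 4
        # numerator (1/2)(4 + 4) = 4 ; intra-A variance 1 -> ratio 4
        ds = make_ds({"A": [[1.0], [3.0]], "B": [[5.0], [7.0]]})
        assert fratio.f_ratio(ds, "A", "unstable") == pytest.approx([4.0])

    def test_identical_speakers_score_zero(self):
        x = [[1.0, 5.0], [3.0, 6.0]]
        ds = make_ds({"A": x, "B": [row[:] for row in x]})
        np.testing.assert_allclose(fratio.f_ratio(ds, "A", "unstable"),
                                   [0.0, 0.0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(97)
        spk = {"A": rng.random((5, 8)), "B": rng.random((5, 8)),
               "C": rng.random((5, 8))}
        base = fratio.f_ratio(make_ds(spk), "B", "unstable")
        scaled = fratio.f_ratio(
            make_ds({s: 7.3 * x for s, x in spk.items()}), "B", "unstable")
        np.testing.assert_allclose(scaled, base, rtol=1e-10)

    def test_zero_intra_variance_yields_inf_sentinel(self):
        ds = make_ds({"A": [[2.0], [2.0]], "B": [[5.0], [7.0]]})
        assert np.isinf(fratio.f_ratio(ds, "A", "unstable")[0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spk = {s: rng.random((5, 8)) + 0.1 for s in ("A", "B", "C")}
        ds = make_ds(spk)
        for target in spk:
            np.testing.assert_allclose(
                fratio.f_ratio(ds, target, "unstable"),
                naive_f_ratio(spk, target), rtol=1e-10)


class TestMinMaxNormalize:
    def test_direct(self):
        np.testing.assert_allclose(
            fratio.minmax_normalize(np.array([2.0, 4.0, 6.0])),
            [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        v = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(fratio.minmax_normalize(v), v)

    def test_output_range_contract(self):
        rng = np.random.default_rng(103)
        out = fratio.minmax_normalize(rng.normal(size=60))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fratio.minmax_normalize(np.full(60, 3.3))


class TestBandRegionReport:
    def _flat_profile(self, speaker, period, hot_bands, hot=1.0, cold=0.5):
        values = np.full(60, cold)
        values[hot_bands] = hot
        return fratio.FRatioProfile(
            speaker_id=speaker, period=period, raw_values=values,
            normalized_values=values, band_edges=fratio.band_edges(),
            degenerate_bands=())

    def test_constructed_contrast_flagged(self):
        hot = fratio.bands_in_region(4000, 6000)
        profiles = [self._flat_profile("S", p, hot)
                    for p in ("unstable", "stable")]
        report = fratio.band_region_report(profiles, [(4000.0, 6000.0)])
        assert report["regions"][0]["robust_speakers"] == ["S"]

    def test_full_coverage_region_equals_profile_mean(self):
        profiles = [self._flat_profile("S", "unstable", [3, 9])]
        report = fratio.band_region_report(profiles, [(0.0, 8000.0)])
        row = report["per_profile"][0]
        assert row["inside_mean"] == pytest.approx(
            profiles[0].normalized_values.mean())

    def test_empty_region_rejected(self):
        profiles = [self._flat_profile("S", "unstable", [3])]
        with pytest.raises(ValueError):
            fratio.band_region_report(profiles, [(100.0, 110.0)])

    def test_designed_regions_recovered_on_corpus(self, featurized, cohort):
        """Both designed regions are period-robust for >= 5/6 speakers."""
        meta, _, powers = featurized
        vm = (meta["kind"] == "vowel").to_numpy()
        profiles = fratio.vowel_averaged_profiles(
            meta[vm].reset_index(drop=True), powers[vm])
        report = fratio.band_region_report(
            profiles, [(1000.0, 2000.0), (4000.0, 6000.0)])
        for region in report["regions"]:
            assert region["n_robust"] >= 5

    def test_permutation_null_destroys_regions(self, featurized):
        """Shuffling speaker labels erases the flagged regions in >= 90%
        of 50 shuffles."""
        meta, _, powers = featurized
        vm = (meta["kind"] == "vowel").to_numpy()
        sub_meta = meta[vm].reset_index(drop=True)
        sub_powers = powers[vm]
        rng = np.random.default_rng(107)
        destroyed = 0
        for _ in range(50):
            shuffled = sub_meta.copy()
            shuffled["speaker_id"] = rng.permutation(
                shuffled["speaker_id"].to_numpy())
            profiles = fratio.vowel_averaged_profiles(shuffled, sub_powers)
            report = fratio.band_region_report(
                profiles, [(1000.0, 2000.0), (4000.0, 6000.0)])
            if any(r["n_robust"] < 5 for r in report["regions"]):
                destroyed += 1
        assert destroyed >= 45


class TestProfilesFrame:
    def test_long_format_shape(self, featurized):
        meta, _, powers = featurized
        vm = (meta["kind"] == "vowel").to_numpy()
        ds = BandPowerDataset.from_meta(meta[vm], powers[vm])
        profiles = fratio.all_profiles(ds)
        frame = fratio.profiles_to_frame(profiles)
        assert len(frame) == len(profiles) * 60
        assert set(frame["period"]) == {"unstable", "stable"}
        assert ((frame["normalized"] >= 0) & (frame["normalized"] <= 1)).all()
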