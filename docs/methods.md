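# Methods

`voxage` studies a longitudinal question from voice biometrics: does a
speaker's acoustic individuality survive the vocal change of
adolescence? The package models two developmental *periods* — an
**unstable** period (immature vocal organs, higher and more variable
fundamental frequency) and a **stable** period (mature vocal organs) —
and asks whether a verifier trained on one period recognizes the same
speaker in the other, and which frequency bands carry the identity that
transfers.

Because no public longitudinal corpus spans both periods for the same
speakers, the package is built around a synthetic-data generator whose
ground truth is known by construction. Every downstream stage (features,
verification, F-ratio, robustness) consumes ordinary 16 kHz mono WAV
audio and works equally on real recordings with the same labels.

## Synthetic two-period corpora (`synth_voice`)

Each speaker is a source-filter model. The glottal source is an impulse
train at the period's fundamental frequency with 2% pulse-interval
jitter, plus Gaussian aspiration noise (sd 0.05 relative to unit
impulses, about −6 dB against the source RMS). The vocal tract is a set
of parallel second-order unity-peak resonators (`scipy.signal.iirpeak`),
applied as `y = x + Σ (g_i − 1) · P_i(x)` so each resonance raises its
band by its gain without attenuating the rest of the spectrum:

- **vowel formants** — canonical Japanese F1/F2/F3 per vowel
  (/a/ 800/1200/2700 Hz, /i/ 300/2300/3000, /u/ 350/1200/2800,
  /e/ 500/1900/2800, /o/ 500/800/2700), +12 dB, shared by all speakers;
- **invariant peaks** — the designed individuality: per speaker one
  peak inside 1–2 kHz and one inside 4–6 kHz (+12 dB, 150 Hz
  bandwidth), identical in both periods, centers spread ≥ 50 Hz apart
  across speakers;
- **period resonances** — individuality that does *not* survive
  growth: one +13 dB resonance per speaker whose region moves entirely
  between periods (unstable 2.5–3.5 kHz → stable 7.3–7.9 kHz),
  emulating vocal-tract growth relocating a cavity resonance.

Mean F0 drops 180→120 Hz for male speakers and 250→220 Hz for female
speakers (plus a ±10 Hz speaker offset common to both periods), so the
male drift is larger — the adolescent voice change. Each clip draws its
own mean F0 around the period mean (sd 8% unstable, 5% stable): real
speakers do not hold one exact pitch across recordings, and an
artificially constant per-period F0 would make every spectral statistic
track harmonic-comb positions rather than the vocal-tract envelope.
Clips are level-normalized to RMS 0.1 and measurement noise is added at
−40 dB full scale. Phrase clips concatenate random vowel-like 0.2 s
segments with 10 ms cross-fades and occasional 30 ms unvoiced bursts.

The default cohort is 6 speakers (3 male, 3 female; the first of each
sex is a verification target) with 8 phrase + 4-per-vowel clips per
speaker in the unstable period and half of each in the stable period —
a deliberate 2:1 imbalance that reproduces the scarcity of
adult-period material in longitudinal corpora (and its consequence:
training on the stable period is the harder direction).

Every function takes an explicit integer seed and is bit-reproducible;
the corpus generator derives per-clip seeds from one master seed.

What the generator does **not** emulate: intelligible speech content,
glottal-flow pulse shapes (the source is an impulse train), coupled
formant-F0 interaction, channel/recording variation, and any
within-speaker correlation structure beyond pitch scatter. Passing
tests therefore show that the pipeline recovers *designed* invariants
under realistic levels of noise and drift — not that real adolescent
voices behave this way.

## Features (`features`)

Clips are framed at 50 ms with 40 ms overlap (10 ms hop) from sample 0;
a trailing partial frame is dropped. Frames whose RMS falls below
10⁻³ × the clip's peak amplitude are discarded as silent (scale-free,
so quiet voiced frames survive). Each frame is peak-normalized to
[−1, 1], Hamming-windowed, zero-padded to a 1024-point FFT and squared
into a power spectrum. Sixty triangular filters with 50% overlap are
spaced *linearly* over 0–8 kHz (band width 133⅓ Hz) — unlike mel
filters, this keeps full resolution in the 4–6 kHz region where
high-frequency individuality lives. LFCCs are the orthonormal type-II
DCT of the log (floor 10⁻¹⁰) filter energies; all 60 coefficients are
kept. The same filter bank without log/DCT produces the linear-domain
band powers used by the F-ratio.

Numerical choices: log-before-DCT is applied (a cepstrum requires it)
with both it and the per-frame normalization scope configurable in
principle through the module constants; FFT length 1024 is the next
power of two above the 800-sample frame.

## Verifier (`verifier`)

A small feedforward network written in NumPy: 60-d LFCC input, three
hidden blocks (affine → batch normalization → ReLU) of widths 128, 64,
32, then an affine layer and softmax over {target, non-target}.
Training: cross-entropy, mini-batches of 32, 300 epochs, Adam with its
standard constants (α=10⁻³, β₁=0.9, β₂=0.999, ε=10⁻⁸). Batch norm uses
batch statistics during fitting (running statistics updated with
momentum 0.1) and the frozen running statistics at inference, so
prediction is a pure function. One integer seed controls weight
initialization (He-scaled Gaussians) and batch shuffling; an ensemble
derives n distinct member seeds from a master seed via
`numpy.random.SeedSequence`. The forward/backward pass is written out
explicitly so the analytic gradients can be (and are) verified against
central finite differences. No early stopping, validation split or
regularization beyond batch norm.

The network is trained per target speaker as target-vs-rest on one
period's samples of one utterance kind, and scored frame-by-frame on
the other period.

## Evaluation (`evaluation`)

For thresholds t ∈ {0.00, 0.01, …, 1.00} a frame is accepted iff its
target probability strictly exceeds t. FAR = FP/(FP+TN),
FRR = FN/(FN+TP); the equal error rate is (FAR+FRR)/2 at the threshold
minimizing |FAR−FRR| (ties resolved toward the smaller threshold, a
deterministic choice), and verification accuracy = 1 − EER. Ensembles
report the mean of per-model accuracies, not a pooled-score EER. A note
on the grid: with n target frames the smallest realizable FRR step is
1/n, so the grid EER can differ from an exhaustive all-scores sweep by
up to 0.01 + 1/(2n); the test suite checks exactly this bound.

## Fisher F-ratio (`fratio`)

For band k, speaker i, period s, with per-sample filter-bank powers
x_{i,s,j,k}:

    μ_{i,s,k} = mean_j x_{i,s,j,k}
    μ_{s,k}   = mean_i μ_{i,s,k}          (speakers weighted equally)

    F_{i,s,k} = [ (1/I) Σ_i (μ_{i,s,k} − μ_{s,k})² ]
                / [ (1/N_{i,s}) Σ_j (x_{i,s,j,k} − μ_{i,s,k})² ]

The numerator (inter-speaker variance) is common to all speakers of a
period; the denominator is speaker i's intra-speaker variance. Both are
population (1/N) variances, and band powers enter in the linear power
domain. Equal speaker weighting in μ_{s,k} matters under the 2:1 period
imbalance. A band with zero intra-speaker variance yields a +inf
sentinel, flagged on the profile rather than raised, so degenerate
synthetic bands cannot abort a run. Each 60-band profile is min-max
normalized to [0, 1] within itself, making curves comparable across
speakers and periods.

One structural property of this definition is worth stating: because
the numerator is shared and the denominator favors bands where the
*profiled* speaker is quiet and stable, a speaker's highest-ranked
bands are typically the bands where the *cohort* carries structure —
the designed regions as a whole — rather than that speaker's own peak
bands. Recovery is therefore asserted at the region level (designed
regions dominate each profile's top ranks and are flagged
period-robust), which is also how band-level individuality is read off
such profiles in practice.

Profiles for the region analysis are computed **per vowel** and the
five normalized curves averaged: pooling vowels would inject the
between-vowel F2 differences into the intra-speaker variance and mask
the 1–2 kHz individuality that is only visible within a vowel.

## Robustness of the 1–2 / 4–6 kHz regions (`robustness`)

Each vowel clip is reduced to 60 band medians of its magnitude
spectrogram (same framing and window as the features; no per-frame
normalization, since absolute levels are the point). For one person and
one *replicate*, 50 (u, v) pairs are drawn — u a median from region A,
v from region B, each from a random clip and band — and averaged into a
2-D centroid per period; the Euclidean distance between the two period
centroids measures how far that person's spectral signature moved with
age. Under the **invariant** condition, A and B are the 1–2 kHz and
4–6 kHz band sets; under the **other** condition, each replicate draws
fresh random disjoint band subsets of the same sizes from the 38 bands
outside both regions. The default run performs 3000 replicates (6000
centroids, 3000 distances) per person and condition.

Draws are paired across periods (same band and the same uniform deviate
for the clip index in both periods), so a person whose two periods are
identical gets distance exactly 0 and the statistic isolates
between-period change even though the two periods hold different
numbers of clips. All vowels of a person/period are pooled by default;
passing a filtered clip list gives a per-vowel analysis. The
condition-level comparison is a per-person one-sided Mann–Whitney
rank-sum test (invariant < other); on the default cohort it succeeds at
the 0.01 level for every person, the synthetic analogue of the finding
that 1–2 and 4–6 kHz carry age-robust individuality.

## Orchestration (`cli`)

`voxage all --config config.yaml` (or `run_experiment(RunConfig(...))`)
executes the full grid — 2 targets × 2 train/test directions × 6
utterance kinds (phrase + five vowels), each averaged over a 5-model
ensemble — then the F-ratio region report and the robustness analysis,
writing features.csv, results.csv, fratio.csv, distances.csv,
report.json and run.log under one output directory. All stage seeds
derive from the single master seed; the report embeds a hash of the
config. `validate_config` returns the complete list of violations at
once. Subcommands `generate` and `featurize` expose the corpus and
feature stages separately for use with external audio.

## Problem sizes and limitations

The shipped defaults (6 speakers, ~250 clips, ~13k frames, 5-model
ensembles at 300 epochs) were chosen so a full verification direction
trains in a few minutes on one CPU core while leaving enough samples
per speaker-period for stable variance estimates; the acceptance script
runs the headline unstable→stable experiment at exactly these sizes.
Known limitations: the impulse-train source lacks a realistic glottal
spectrum (mitigated by the aspiration component); invariant peaks are
the only cross-period identity, so verification accuracy on the
synthetic corpus is near ceiling rather than in the 54–75% range
expected of real cross-age audio; and the F-ratio's printed form (per
speaker, shared numerator) is kept exactly as defined rather than
replaced by a pooled ANOVA-style statistic.
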