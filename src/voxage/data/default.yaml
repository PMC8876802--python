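# Default experiment configuration: a 6-speaker cohort (3 male, 3 female,
# one verification target per sex) recorded in two developmental periods,
# with the stable period holding half the unstable period's clips.
seed: 20220301
out_dir: voxage_run
n_male: 3
n_female: 3
n_phrase_unstable: 8
n_phrase_stable: 4
n_vowel_unstable: 4
n_vowel_stable: 2
phrase_segments: 5
vowel_duration: 0.4
frame_ms: 50
overlap_ms: 40
hidden_layout: [128, 64, 32]
iterations: 300
batch_size: 32
n_models: 5
n_replicates: 3000
pairs_per_centroid: 50
regions:
  - [1000.0, 2000.0]
  - [4000.0, 6000.0]
write_audio: false
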