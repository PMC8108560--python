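# Example study configuration for `sleeptes simulate` / `sleeptes run-all`.
# Any omitted field keeps its default (see sleeptes.pipeline.StudyConfig).

n_subjects: 5
n_epochs: 960          # 8 h of 30-s epochs
rate: 64.0
stager: rule           # rule | cnn | truth
n3_boost: 1.11         # stimulation-condition N3 transition multiplier
include_spectral: false
seed: 0
montage: [C3, C4, M1, M2, EOGL, EOGR, EMG]
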