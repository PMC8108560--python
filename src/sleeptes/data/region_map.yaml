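# Default scalp-region channel map (10-20 system).
# The study montage averages power spectral density over clusters of
# channels per region; this shipped default assigns one representative
# 10-20 electrode to each of the ten regions so that the regional analysis
# is exercisable with a compact montage. Left/right region pairs must have
# equal cluster sizes.
regions:
  Left Frontal: [F7]
  Right Frontal: [F8]
  Medial Prefrontal: [Fpz]
  Medial Frontal: [Fz]
  Left Temporoparietal: [T5]
  Right Temporoparietal: [T6]
  Posterior Parietal: [Pz]
  Left Occipital: [O1]
  Right Occipital: [O2]
  Medial Occipital: [Oz]
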