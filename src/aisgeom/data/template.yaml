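ais_split_frac: 0.5
apical1:
  length: 100.0
apical2:
  diam: 1.6
  length: 150.0
apical3:
  diam: 1.2
  length: 150.0
axon_distal:
  diam: 0.5
  length: 200.0
basal:
  diam: 0.9
  length: 150.0
soma_nseg: 3
tuft:
  diam: 0.8
  length: 100.0
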