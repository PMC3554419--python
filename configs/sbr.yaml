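# Sequential glucose-excess batches at 12/18/24/30 C, sampled three times in
# the exponential phase (glucose between 80% and 30% of the initial 25 g/L).
model: packaged:reduced_glycolysis
thermo:
  ratkowsky: {t_min: -0.42, t_ref: 30.0}
reactor: {mode: batch}
scenarios:
  - {regime: SBR, batch_temperatures: [12.0, 18.0, 24.0, 30.0]}
analysis: {theta: 0.15, permutations: 1000, seed: 0}
output_dir: ../results/sbr
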