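# 3-h linear temperature shift starting from a 12 C steady-state chemostat.
model: packaged:reduced_glycolysis
thermo:
  ratkowsky: {t_min: -0.42, t_ref: 30.0}
reactor: {mode: chemostat, dilution_rate: 0.03, feed_concentrations: {GLCo: 138.8}}
scenarios:
  - {regime: LTS12}
analysis: {theta: 0.15, permutations: 1000, seed: 0}
output_dir: ../results/lts12
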