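# Full perturbed round: TDH lump two-fold less temperature-sensitive,
# all three regimes, with synthetic measurement noise available via `synth`.
model: packaged:reduced_glycolysis
thermo:
  ratkowsky: {t_min: -0.42, t_ref: 30.0}
  sensitivity: {reaction_id: TDHL, factor: 2.0}
  keq_temperature_dependence: false
reactor: {mode: chemostat, dilution_rate: 0.03, feed_concentrations: {GLCo: 138.8}}
scenarios:
  - {regime: SBR, batch_temperatures: [12.0, 18.0, 24.0, 30.0]}
  - {regime: LTS30}
  - {regime: CTC}
noise: {cv: 0.10, replicates: 2, glucose_loq: 0.01, seed: 0}
analysis: {theta: 0.15, permutations: 1000, seed: 0}
output_dir: ../results/run_tdhl
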