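# Reduced anaerobic yeast glycolysis: linear backbone with transport entry,
# a glycerol branch and pooled triose phosphates (TRIO).  Cofactors (ATP/ADP,
# NAD/NADH) are treated as buffered and do not appear.  Concentrations mM,
# rates mM·min⁻¹ of cytosolic volume at the 30 °C reference temperature.
#
# Vmax magnitudes are of the order of the classical in-vitro-parameterized
# yeast glycolysis models (glucose transport capacity ~1e2 mM/min), sized so
# that a glucose-limited chemostat at D = 0.03 h⁻¹ remains feasible down to
# 12 °C when all capacities are six-fold lower than at 30 °C.
# Product saturation terms (km_products) are deliberately strong so that a
# perturbation of one enzyme's temperature sensitivity propagates upstream
# through the chain, as it does in the full cofactor-coupled model.
name: reduced_glycolysis
species:
  - {id: GLCo, compartment: extracellular}   # broth glucose
  - {id: GLCi, compartment: intracellular}
  - {id: G6P,  compartment: intracellular}
  - {id: F6P,  compartment: intracellular}
  - {id: FBP,  compartment: intracellular}
  - {id: TRIO, compartment: intracellular}   # pooled DHAP + GAP
  - {id: PEP,  compartment: intracellular}   # pooled lower glycolysis head
  - {id: PYR,  compartment: intracellular}
  - {id: ETOH, compartment: extracellular}
  - {id: GLYC, compartment: extracellular}
  - {id: CO2,  compartment: extracellular}   # vented; tracked as flux only
clamped: [GLCo, ETOH, GLYC, CO2]
reactions:
  - id: GLT          # hexose carrier, symmetric facilitated diffusion
    pathway_index: 1
    stoichiometry: {GLCo: -1, GLCi: 1}
    rate_law:
      kind: facilitated_diffusion
      vmax_ref: 130.0
      km_substrates: {GLCo: 1.0}
  - id: HXK
    pathway_index: 2
    stoichiometry: {GLCi: -1, G6P: 1}
    rate_law:
      kind: reversible_mm
      vmax_ref: 260.0
      km_substrates: {GLCi: 0.08}
      km_products: {G6P: 1.0}
      keq_ref: 3500.0        # 30 °C table value (effective, cofactors buffered)
  - id: PGI
    pathway_index: 3
    stoichiometry: {G6P: -1, F6P: 1}
    rate_law:
      kind: reversible_mm
      vmax_ref: 700.0
      km_substrates: {G6P: 1.4}
      km_products: {F6P: 0.30}
      keq_ref: 0.29          # 30 °C table value
  - id: PFK
    pathway_index: 4
    stoichiometry: {F6P: -1, FBP: 1}
    rate_law:
      kind: reversible_mm
      vmax_ref: 300.0
      km_substrates: {F6P: 0.10}
      km_products: {FBP: 0.30}
      keq_ref: 2400.0        # 30 °C table value (effective)
  - id: FBA          # aldolase + triose-phosphate isomerase, lumped
    pathway_index: 5
    stoichiometry: {FBP: -1, TRIO: 2}
    rate_law:
      kind: reversible_mm
      vmax_ref: 300.0
      km_substrates: {FBP: 0.30}
      km_products: {TRIO: 1.0}
      keq_ref: 1.4           # mM convention: [TRIO]^2/[FBP] at 30 °C
  - id: TDHL         # TDH·PGK·PGM·ENO, lumped TRIO -> PEP
    pathway_index: 6
    stoichiometry: {TRIO: -1, PEP: 1}
    rate_law:
      kind: reversible_mm
      vmax_ref: 500.0
      km_substrates: {TRIO: 0.40}
      km_products: {PEP: 0.30}
      keq_ref: 4.3           # product of the four lumped 30 °C Keq values
  - id: PYK
    pathway_index: 7
    stoichiometry: {PEP: -1, PYR: 1}
    rate_law:
      kind: reversible_mm
      vmax_ref: 650.0
      km_substrates: {PEP: 0.20}
      km_products: {PYR: 0.50}
      keq_ref: 14000.0       # 30 °C table value
  - id: PDC          # decarboxylase + alcohol dehydrogenase, lumped
    pathway_index: 8
    stoichiometry: {PYR: -1, ETOH: 1, CO2: 1}
    rate_law:
      kind: irreversible_mm
      vmax_ref: 450.0
      km_substrates: {PYR: 2.0}
  - id: GLYCb        # glycerol branch off the triose pool (NADH sink)
    pathway_index: 0         # branch: not part of the linear backbone order
    stoichiometry: {TRIO: -1, GLYC: 1}
    rate_law:
      kind: irreversible_mm
      vmax_ref: 12.0
      km_substrates: {TRIO: 0.02}   # near-saturated branch, flux ≈ R·Vmax
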