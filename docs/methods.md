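# Methods

## The model

### Rate laws and network

Intracellular kinetics follow the generic enzyme-rate decomposition

    v = scale · Vmax_ref · f(K, S, P) · (1 − Γ/Keq),

with `scale` a dimensionless temperature factor (1 at the 30 °C reference),
`f` a saturation function, Γ the mass-action ratio from the reaction's
stoichiometry and Keq the equilibrium constant in the concentration
convention implied by that stoichiometry. Four mechanisms are supported:
irreversible Michaelis–Menten, reversible Michaelis–Menten
(`f = (ΠS/K_S)/(1 + ΠS/K_S + ΠP/K_P)` with stoichiometric exponents),
a symmetric facilitated-diffusion carrier
(`v = Vmax(S − P)/(K(1 + S/K + P/K))`), and mass action. Concentrations are
mM, rates mM·min⁻¹ of cytosolic volume, time in the simulation API is hours.

The packaged reduced glycolysis model (`models/reduced_glycolysis.yaml`) has
eleven species and nine reactions: carrier entry (GLT), hexokinase (HXK),
phosphoglucose isomerase (PGI), phosphofructokinase (PFK), a lumped
aldolase+triose-phosphate-isomerase step (FBA, FBP ↔ 2·TRIO, Keq in mM), a
lumped lower-glycolysis step (TDHL = TDH·PGK·PGM·ENO, TRIO → PEP), pyruvate
kinase (PYK), a lumped decarboxylase+alcohol-dehydrogenase sink
(PDC, PYR → ethanol + CO₂) and a glycerol branch off the triose pool.
Cofactors (ATP/ADP, NAD/NADH) are treated as buffered and do not appear;
trehalose/glycogen turnover and allosteric regulation are out of scope. A
full base model can be imported read-only from SBML where available.

Design choices that matter and why:

- **Product-sensitive (reversible) forms for HXK, PFK, PYK and TDHL.** The
  physiologically one-way steps carry their literature equilibrium constants
  (HXK 3.5·10³, PFK 2.4·10³, PYK 1.4·10⁴ at 30 °C; TDHL uses 4.3, the
  product of its four lumped components), so they remain thermodynamically
  irreversible, but the product-occupancy term in `f` is retained. In the
  full cofactor-coupled pathway a downstream perturbation propagates upstream
  through shared cofactors and product inhibition; a chain of strictly
  irreversible laws would pin each substrate by flux alone and block that
  propagation entirely, making single-enzyme perturbations invisible above
  the immediately preceding metabolite. Product sensitivity restores the
  coupling with one mechanism.
- **Capacity magnitudes.** Vmax values (GLT 130, HXK 260, PGI 700, PFK 300,
  FBA 300, TDHL 500, PYK 650, PDC 450, GLYCb 12 mM·min⁻¹ at 30 °C) are of
  the order of the classical in-vitro-parameterized yeast glycolysis models.
  They are sized against three constraints fixed before any analysis: a
  unique stable glucose-excess steady state at 30 °C, chemostat feasibility
  at D = 0.03 h⁻¹ over the whole 12–30 °C range (at 12 °C every capacity is
  six-fold lower, and sustaining D requires an uptake flux of
  ≈ 15.4 mM·min⁻¹ per cell volume — this alone forces carrier capacity
  ≳ 100 mM·min⁻¹), and strictly positive concentrations everywhere. Steps
  after the FBP split carry twice the hexose flux, hence the larger lower-
  pathway capacities.
- **Glycerol branch nearly saturated** (K_M = 0.02 mM against triose pools
  of 0.02–1 mM). The branch then draws an essentially capacity-set flux, so
  re-partitioning at the triose node does not leak a perturbation into the
  downstream backbone; the branch share of glucose carbon is ≈ 5–10%,
  in the range expected for anaerobic glycerol formation.
- **HXK product constant 1.0 mM.** Strong hexose-phosphate back-pressure on
  the first committed step would couple upstream pool shifts to the carrier
  and hence to total flux; 1.0 mM keeps the coupling weak (<0.1% flux
  feedback) while PGI's reversibility still transmits deviations to G6P.

### Temperature

Catalytic capacities follow the sub-optimal branch of the Ratkowsky
square-root law, normalized at the reference temperature:

    R(T) = ((T − T_min)/(T_ref − T_min))²,  T_ref = 30 °C.

`T_min = −0.42 °C` is calibrated so that R(30)/R(12) = 6.0, the flux ratio
observed between 30 °C and 12 °C glucose-excess batches; it is a notional
zero-rate temperature, not a growth limit, and is config-overridable. The
per-reaction Ratkowsky coefficients are flux-proportional,
`b_j = b_Glc · v_j(30 °C)/v_uptake(30 °C)`, which is equivalent to one shared
normalized R(T) — yields are treated as temperature-independent in this
range.

"Two-fold less temperature-sensitive" is implemented as halving the
Ratkowsky exponent (2 → 2/factor), which halves d ln R/dT at every
temperature and keeps R(T_ref) = 1. Alternatives (rescaling T_min, halving
ΔR over the range) exist; the exponent form was chosen because it perturbs
the sensitivity uniformly without moving the reference point. At 12 °C the
perturbed enzyme retains R_alt = 0.41 of its reference capacity versus 0.17
for its neighbours — a 2.45-fold relative excess.

Equilibrium constants can optionally follow the Van't Hoff relation,
`ln(Keq,2/Keq,1) = ΔH°r/R_gas·(1/T1 − 1/T2)`, with enthalpies fitted
through the tabulated 12/30 °C anchor pairs (lumped reactions sum the
component enthalpies). The switch is off by default: every fold change
across 12–30 °C is below two, an order of magnitude smaller than the
six-fold capacity effect, and leaving Keq fixed keeps the homeostasis
statement exact. The printed fold-change column mixes ratio directions;
the table stored in `thermo.KEQ_TABLE` records the direction per reaction
explicitly.

### Reactor

Extracellular amounts follow
`dN_i/dt = q_i·N_X + F_in·C_i,in − F_out·C_i,out`, with specific rates
`q_i` obtained from cytosolic fluxes via 2.0 mL cytosol per gDW. Biomass
grows as `μ = Y_XS·q_S` with Y_XS = 0.09 g·g⁻¹ (anaerobic). Because the
catabolic network alone would then create biomass out of nothing, a
growth-coupled anabolic drain removes hexose phosphate in exact carbon
equivalence to the biomass formed (biomass CH₁.₈O₀.₅N₀.₂ at 24.6 g per
C-mol ⇒ drain = 0.11 × uptake flux); the closed-batch carbon balance
(glucose → ethanol + glycerol + CO₂ + biomass + pool changes) then closes
by construction, and the audit verifies it numerically to <0.5%. The drain
is proportional to uptake, so it scales with R(T) like every other rate and
preserves the homeostasis theorem. Ethanol evaporates with a first-order
constant of 0.008 h⁻¹ (off in carbon-balance tests); CO₂ is vented and
integrated as a cumulative off-gas amount, the model's analogue of the
on-line off-gas signal used as a flux proxy. Defaults mirror the
experimental setup: glucose feed 25 g·L⁻¹ = 138.8 mM, chemostat dilution
rate 0.03 h⁻¹, working volume 1 L.

Chemostat runs start at the constant-temperature steady state (the
experiments equilibrated five residence times), found by a continuation
strategy: the per-cell steady state is walked down in residual glucose until
μ brackets D, the 1-D crossing is bisected, and the full multivariate system
is then polished by Newton iteration. Washout (μ persistently below D) is
flagged on trajectories, not raised.

### Regimes and sampling

- **SBR** — glucose-excess batches at 12/18/24/30 °C, each starting from the
  excess steady state with a 0.2 gDW·L⁻¹ inoculum, sampled at three
  exponential-phase points (glucose at 80%, 49% and 30% of the feed — the
  geometric ladder of the sampling window). The adaptation cycles of the
  real campaign have no model counterpart (there is no adaptation state), so
  one batch per temperature stands in for the third cycle; each temperature
  is labelled as its own regime (SBR12…SBR30), as each batch is a separate
  culture.
- **LTS30 / LTS12** — a steady chemostat ramped at 0.2 °C·min⁻¹ to the
  opposite extreme and back (3 h total), sampled at every 30/24/18/12 °C
  crossing on both legs and 1, 2, 3 h after return.
- **CTC** — the circadian sinusoid `21 + 9·sin(π/12·t + 1.57)` °C (24-h
  period; the phase constant is the programmed literal, not π/2), run for
  six cycles and sampled every 3 h during cycles 5–6.

Normalization follows the figure convention: levels are divided by the
30 °C glucose-excess reference — the first 30 °C batch sample when batches
are part of the round (that row is exactly 1), otherwise the clamped
glucose-excess steady state.

## Collapse statistic and localization

For each metabolite, a pooled monotone reference curve ĝ(S) is fitted to
level against log₁₀ residual glucose by isotonic regression (direction from
the rank-correlation sign; values interpolated between fitted points).
Relative residuals r = (level − ĝ)/ĝ give the collapse score C_m = median|r|,
pooled and per regime; a regime deviates when C_m,q > θ. The default
θ = max(0.15, 2·CV) encodes that deviations must clear measurement noise —
with the default 10% CV, duplicate samples put the noise floor of median|r|
near 0.05, a factor ≈ 4 below θ. Residual temperature dependence is tested
by permuting temperature labels (1000 permutations, seeded) against the
Spearman correlation of r with sampling temperature, two-sided, with the
add-one p-value correction.

A perturbed enzyme leaves every metabolite upstream of itself off the curve
and every downstream one on it, so localization accepts only flag patterns
forming a non-empty contiguous head of the pathway ordering (metabolites
ordered by the pathway index of their consuming backbone reaction) and
returns that head's boundary — the consumer of the most downstream deviating
metabolite. All-clear patterns return no candidate; anything else is
reported as inconsistent. This rule cannot return an enzyme downstream of
the true perturbation: a missed upstream flag or a spurious downstream flag
breaks contiguity and yields "none" rather than a wrong boundary.

Replicate studies use the glucose-excess stratum: under glucose limitation
the imposed flux makes perturbed and unperturbed models walk nearly the same
metabolite–glucose manifold (deviations < 1%), so chemostat rows carry
almost no discrimination power — consistent with the observation that the
two hypotheses separate under glucose excess.

## Synthetic data

The generator emulates the measurement structure of the campaign: duplicate
samples per scheduled time point, two independent cultures per condition
(re-simulated with inoculum/biomass jittered ±5%), multiplicative lognormal
noise with mean exactly one (σ² = ln(1 + CV²), default CV 10% — replicate
CVs are not published; 10% is typical of isotope-dilution LC-MS
metabolomics), reported level = replicate mean with its standard error, and
glucose censored at LOQ/2 below 0.01 mM. Everything is reproducible from a
single integer seed. In the 50-seed replicate studies the culture pair is
simulated once per condition and only measurement noise is redrawn per
seed; culture-to-culture variation contributes far less than measurement
noise at these settings. What the generator does **not** emulate: systematic
instrument drift, quenching/extraction losses, correlated errors between
metabolites sharing an internal standard, and biological adaptation between
sequential batches — so passing recovery tests demonstrate statistical
power under the stated noise model, not robustness to structured
experimental bias.

## Numerics

- Steady states: Newton/hybrid root solving in log-concentration space
  (positivity by construction), `xtol` 1e-13, accepted only when
  max|N·v| ≤ 1e-9 mM·min⁻¹; on failure, stiff ODE relaxation to a plateau
  followed by a second polish, with the successful path recorded.
- Time courses: LSODA with rtol 1e-8, atol 1e-10 mM. Rates are evaluated
  without domain checks inside the integrator (trial steps may graze zero);
  the Michaelis–Menten forms are smooth there and excursions are bounded by
  atol. Public rate evaluation validates and raises on negative input.
- The all-zero-capacity model returns the trivial zero-flux state with a
  warning rather than an error.
- Degenerate Γ (zero substrate) raises a distinct domain error; reversible
  rates return the forward limit when a product is absent.
- Batch sampling times are found by linear interpolation of the glucose
  trajectory on a 0.15 h output grid; chemostat horizons are six residence
  times for settling checks.
- Problem sizes for the replicate studies — 50 noise seeds per condition on
  a two-culture batch design, 500 null tables of 40 points for the
  permutation-size check — keep each study deterministic and small while
  leaving binomial confidence intervals well inside the asserted bounds.

## Known limitations

- No cofactor dynamics: perturbations touching ATP/NADH stoichiometry
  (e.g. the glycerol/redox balance under temperature shifts) are outside the
  model's reach.
- The reduced model's absolute concentrations are of realistic magnitude
  but not fitted to any dataset; only structural/relative statements
  (collapse, upstream localization, flux ratios) are meaningful.
- Localization assumes a single perturbed enzyme on a linear backbone;
  several simultaneously different enzymes are not searched for (attempts to
  simulate them in the original study were reported unstable).
- SBML import maps only simple kinetic laws and is intended to bootstrap a
  base model for manual curation, not to reproduce a foreign model verbatim.
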