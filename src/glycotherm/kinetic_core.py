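"""Kinetic network representation, rate laws, steady states and time courses.

Concentrations are mM, reaction rates mM·min⁻¹ (per cytosolic volume), time in
the public simulation API is hours.  A reaction rate follows the generic form

    v = scale · Vmax_ref · f(K, S, P) · (1 − Γ/Keq)

where ``scale`` is a dimensionless temperature factor (1 at the reference
temperature), ``f`` a saturation function determined by the mechanism, Γ the
mass-action ratio and Keq the equilibrium constant.  Irreversible mechanisms
drop the thermodynamic bracket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import ConfigurationError, DomainError, SimulationError, SteadyStateError

RATE_LAW_KINDS = ("irreversible_mm", "reversible_mm", "facilitated_diffusion", "mass_action")

#: default solver tolerances
STEADY_STATE_ATOL = 1e-9      # mM·min⁻¹, absolute, on each component of N·v
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10              # mM


@dataclass(frozen=True)
class Species:
    """A chemical species; ``compartment`` is 'intracellular' or 'extracellular'."""

    id: str
    compartment: str
    unit: str = "mM"

    def __post_init__(self):
        if self.compartment not in ("intracellular", "extracellular"):
            raise ConfigurationError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}")


@dataclass
class RateLaw:
    """Parameters of one enzyme mechanism.

    ``km_substrates``/``km_products`` are saturation constants (mM) keyed by
    species id; ``keq_ref`` is the equilibrium constant at the reference
    temperature in the concentration convention implied by the reaction's
    stoichiometry (dimensionless for uni-uni, mM for e.g. FBP↔2·triose-P).
    """

    kind: str
    vmax_ref: float
    km_substrates: dict[str, float] = field(default_factory=dict)
    km_products: dict[str, float] = field(default_factory=dict)
    keq_ref: float | None = None
    effector_constants: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in RATE_LAW_KINDS:
            raise ConfigurationError(f"unknown rate-law kind {self.kind!r}")
        if self.vmax_ref < 0:
            raise ConfigurationError("vmax_ref must be >= 0")
        for name, kmmap in (("km_substrates", self.km_substrates),
                            ("km_products", self.km_products)):
            for sid, k in kmmap.items():
                if k <= 0:
                    raise ConfigurationError(f"{name}[{sid}] must be > 0")
        if self.kind == "reversible_mm" and (self.keq_ref is None or self.keq_ref <= 0):
            raise ConfigurationError("reversible_mm requires keq_ref > 0")


@dataclass
class Reaction:
    """A reaction: signed integer stoichiometry (a column of N) plus kinetics.

    ``pathway_index`` orders reactions along the linear glycolytic backbone and
    is used by the localization analysis; branches may share the index of the
    backbone step they leave from.
    """

    id: str
    stoichiometry: dict[str, int]
    rate_law: RateLaw
    pathway_index: int = 0

    def __post_init__(self):
        if not any(c < 0 for c in self.stoichiometry.values()):
            raise ConfigurationError(
                f"reaction {self.id!r} has no substrate (negative coefficient)")

    @property
    def substrates(self) -> list[str]:
        return [s for s, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [s for s, c in self.stoichiometry.items() if c > 0]


def mass_action_ratio(reaction: Reaction, concentrations: Mapping[str, float]) -> float:
    """Γ = Π products^|coef| / Π substrates^|coef| from the reaction stoichiometry."""
    num = 1.0
    den = 1.0
    for sid, coef in reaction.stoichiometry.items():
        if sid not in concentrations:
            raise ConfigurationError(f"species {sid!r} missing from concentration map")
        c = concentrations[sid]
        if c < 0:
            raise DomainError(f"negative concentration for {sid!r}")
        if coef < 0:
            if c == 0:
                raise DomainError(
                    f"mass-action ratio undefined: substrate {sid!r} concentration is zero")
            den *= c ** (-coef)
        elif coef > 0:
            num *= c ** coef
    return num / den


def _saturation(conc, km, exponents):
    """Π (C_i/K_i)^n_i over the Km map; missing Km → species treated as saturating."""
    out = 1.0
    for sid, k in km.items():
        out *= (conc[sid] / k) ** exponents.get(sid, 1)
    return out


def evaluate_rate(rate_law: RateLaw, concentrations: Mapping[str, float],
                  scale: float = 1.0, stoichiometry: Mapping[str, int] | None = None,
                  _validate: bool = True) -> float:
    """Evaluate one rate law (mM·min⁻¹) at the given concentrations and scale.

    ``stoichiometry`` supplies the |coefficient| exponents for the mass-action
    ratio and saturation terms; it is required for reversible kinds.  With
    ``_validate=False`` the domain checks are skipped (used internally by the
    integrator whose trial steps may graze zero).
    """
    if _validate:
        if scale < 0:
            raise DomainError("scale must be >= 0")
        referenced = set(rate_law.km_substrates) | set(rate_law.km_products)
        if stoichiometry:
            referenced |= set(stoichiometry)
        for sid in referenced:
            if sid not in concentrations:
                raise ConfigurationError(f"species {sid!r} missing from concentration map")
            if concentrations[sid] < 0:
                raise DomainError(f"negative concentration for {sid!r}")
    if scale == 0.0 or rate_law.vmax_ref == 0.0:
        return 0.0

    stoich = stoichiometry or {}
    expo = {sid: abs(c) for sid, c in stoich.items()}
    kind = rate_law.kind

    if kind == "irreversible_mm":
        f = 1.0
        for sid, k in rate_law.km_substrates.items():
            s = concentrations[sid]
            f *= (s / k) ** expo.get(sid, 1) / (1.0 + s / k) ** expo.get(sid, 1) \
                if expo.get(sid, 1) != 1 else s / (k + s)
        # optional product occupancy (dead-end inhibition) via km_products
        if rate_law.km_products:
            den = 1.0
            for sid, k in rate_law.km_products.items():
                den += concentrations[sid] / k
            f /= den
        return scale * rate_law.vmax_ref * f

    if kind == "reversible_mm":
        s_term = _saturation(concentrations, rate_law.km_substrates, expo)
        p_term = _saturation(concentrations, rate_law.km_products, expo)
        f = s_term / (1.0 + s_term + p_term)
        # Γ from stoichiometry; substrates may sit at zero during transients
        num = 1.0
        den = 1.0
        for sid, coef in stoich.items():
            c = concentrations[sid]
            if coef > 0:
                num *= c ** coef
            else:
                den *= c ** (-coef)
        if den == 0.0:
            return 0.0 if num > 0 else scale * rate_law.vmax_ref * f
        gamma = num / den
        return scale * rate_law.vmax_ref * f * (1.0 - gamma / rate_law.keq_ref)

    if kind == "facilitated_diffusion":
        # symmetric carrier: v = Vmax (S−P) / (K (1 + S/K + P/K))
        (s_id, k), = rate_law.km_substrates.items()
        p_ids = [sid for sid, c in stoich.items() if c > 0]
        p = concentrations[p_ids[0]] if p_ids else 0.0
        s = concentrations[s_id]
        return scale * rate_law.vmax_ref * (s - p) / (k * (1.0 + s / k + p / k))

    # mass_action
    fwd = 1.0
    for sid, coef in stoich.items():
        if coef < 0:
            fwd *= concentrations[sid] ** (-coef)
    rev = 0.0
    if rate_law.keq_ref:
        rev = 1.0
        for sid, coef in stoich.items():
            if coef > 0:
                rev *= concentrations[sid] ** coef
        rev /= rate_law.keq_ref
    return scale * rate_law.vmax_ref * (fwd - rev)


@dataclass
class NetworkModel:
    """Stoichiometric network with rate laws; ``clamped`` species are held fixed."""

    species: Sequence[Species]
    reactions: Sequence[Reaction]
    clamped: set[str] = field(default_factory=set)
    name: str = "model"
    conserved_moieties: list[list[str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate species ids")
        known = set(ids)
        for rxn in self.reactions:
            for sid in rxn.stoichiometry:
                if sid not in known:
                    raise ConfigurationError(
                        f"reaction {rxn.id!r} references undeclared species {sid!r}")
        for sid in self.clamped:
            if sid not in known:
                raise ConfigurationError(f"clamped species {sid!r} not declared")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise ConfigurationError("duplicate reaction ids")

    # -- convenience views ---------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def dynamic_species(self) -> list[str]:
        """Intracellular, non-clamped species: the rows of N that must balance."""
        return [s.id for s in self.species
                if s.compartment == "intracellular" and s.id not in self.clamped]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ConfigurationError(f"unknown reaction id {rid!r}")

    def stoichiometric_matrix(self, species_ids: Sequence[str] | None = None) -> np.ndarray:
        sids = list(species_ids) if species_ids is not None else self.dynamic_species
        n = np.zeros((len(sids), len(self.reactions)))
        index = {s: i for i, s in enumerate(sids)}
        for j, rxn in enumerate(self.reactions):
            for sid, coef in rxn.stoichiometry.items():
                if sid in index:
                    n[index[sid], j] = coef
        return n

    def rates(self, concentrations: Mapping[str, float],
              scales: Mapping[str, float] | None = None,
              _validate: bool = True) -> dict[str, float]:
        scales = scales or {}
        return {
            rxn.id: evaluate_rate(rxn.rate_law, concentrations,
                                  scale=scales.get(rxn.id, 1.0),
                                  stoichiometry=rxn.stoichiometry,
                                  _validate=_validate)
            for rxn in self.reactions
        }


@dataclass
class SteadyState:
    """Solved steady state; ``method`` records whether root solving or ODE
    relaxation produced it."""

    concentrations: dict[str, float]
    fluxes: dict[str, float]
    residual_norm: float
    method: str = "root"


def _residual_vector(model, conc, scales, n_matrix):
    v = model.rates(conc, scales, _validate=False)
    vvec = np.array([v[rid] for rid in model.reaction_ids])
    return n_matrix @ vvec, v


def solve_steady_state(model: NetworkModel,
                       clamped_values: Mapping[str, float],
                       scales: Mapping[str, float] | None = None,
                       initial_guess: Mapping[str, float] | None = None,
                       tol: float = STEADY_STATE_ATOL,
                       imposed_flux: tuple[str, float] | None = None,
                       free_clamped: str | None = None) -> SteadyState:
    """Solve N·v = 0 for the intracellular concentrations.

    All extracellular (and otherwise clamped) species must appear in
    ``clamped_values``.  Unknowns are solved in log space, which enforces
    positivity; if root finding from the guess fails, the system is relaxed by
    stiff ODE integration and polished by a second root solve.

    With ``imposed_flux=(reaction_id, value)`` one clamped species named by
    ``free_clamped`` becomes an additional unknown and the named reaction's
    rate is constrained to ``value`` — the steady-state manifold parameterized
    by flux instead of by external substrate.
    """
    scales = dict(scales or {})
    unknown = list(model.dynamic_species)
    for s in model.species:
        if s.compartment == "extracellular" and s.id not in clamped_values \
                and s.id not in model.clamped:
            raise ConfigurationError(f"extracellular species {s.id!r} not clamped")
    fixed = {sid: float(val) for sid, val in clamped_values.items()}
    if imposed_flux is not None:
        if free_clamped is None:
            raise ConfigurationError("imposed_flux requires free_clamped")
        unknown = unknown + [free_clamped]
        fixed.pop(free_clamped, None)

    if all(r.rate_law.vmax_ref == 0 for r in model.reactions):
        warnings.warn("all Vmax are zero: returning trivial zero-flux state")
        conc = dict(fixed)
        guess = initial_guess or {}
        for sid in unknown:
            conc[sid] = float(guess.get(sid, 1.0))
        return SteadyState(conc, {r: 0.0 for r in model.reaction_ids}, 0.0, "trivial")

    guess = dict(initial_guess or {})
    x0 = np.array([max(float(guess.get(sid, 1.0)), 1e-9) for sid in unknown])
    n_matrix = model.stoichiometric_matrix()

    def assemble(z):
        conc = dict(fixed)
        c = np.exp(z)
        for sid, ci in zip(unknown, c):
            conc[sid] = ci
        return conc

    def fun(z):
        conc = assemble(z)
        res, v = _residual_vector(model, conc, scales, n_matrix)
        if imposed_flux is not None:
            rid, target = imposed_flux
            res = np.append(res, v[rid] - target)
        return res

    sol = root(fun, np.log(x0), method="hybr", options={"xtol": 1e-13})
    res = fun(sol.x)
    best = (np.max(np.abs(res)), sol.x)

    if best[0] > tol and imposed_flux is None:
        # ODE relaxation fallback: integrate to a plateau, then polish
        def rhs(t, z):
            conc = assemble(z)
            r, _ = _residual_vector(model, conc, scales, n_matrix)
            return r / np.exp(z)  # d ln c / dt

        relax = solve_ivp(rhs, (0.0, 1e7), np.log(x0), method="LSODA",
                          rtol=1e-10, atol=1e-12)
        if relax.success:
            sol2 = root(fun, relax.y[:, -1], method="hybr", options={"xtol": 1e-13})
            res2 = fun(sol2.x)
            if np.max(np.abs(res2)) < best[0]:
                best = (np.max(np.abs(res2)), sol2.x)
                if best[0] <= tol:
                    conc = assemble(best[1])
                    v = model.rates(conc, scales)
                    return SteadyState(conc, v, best[0], "relaxation")

    if best[0] > tol:
        raise SteadyStateError(
            f"no steady state found (last residual {best[0]:.3e} mM/min)",
            residual=best[0])
    conc = assemble(best[1])
    if any(c < 0 for c in conc.values()):
        raise SteadyStateError("negative steady-state concentration", residual=best[0])
    v = model.rates(conc, scales)
    return SteadyState(conc, v, best[0], "root")


@dataclass
class KineticTrajectory:
    """Time course of a clamped-boundary kinetic simulation (time in h)."""

    time: np.ndarray
    concentrations: dict[str, np.ndarray]   # dynamic + clamped, mM
    fluxes: dict[str, np.ndarray]           # mM·min⁻¹

    def final_concentrations(self) -> dict[str, float]:
        return {sid: arr[-1] for sid, arr in self.concentrations.items()}


def _as_time_function(x) -> Callable[[float], float]:
    return x if callable(x) else (lambda t, _v=float(x): _v)


def simulate(model: NetworkModel,
             clamped_profiles: Mapping[str, float | Callable[[float], float]],
             scale_profiles: Mapping[str, float | Callable[[float], float]] | None,
             t_span: tuple[float, float],
             t_eval: Iterable[float],
             initial: Mapping[str, float],
             rtol: float = ODE_RTOL, atol: float = ODE_ATOL) -> KineticTrajectory:
    """Integrate dC/dt = N·v with time-dependent clamps and temperature scales.

    ``t_span``/``t_eval`` are hours; rates are mM·min⁻¹ so the RHS carries a
    factor 60.  A stiff-capable integrator (LSODA) is used throughout.
    """
    t_eval = np.asarray(list(t_eval), dtype=float)
    if t_eval.size and (np.any(np.diff(t_eval) < 0) or t_eval[0] < t_span[0]
                        or t_eval[-1] > t_span[1]):
        raise ConfigurationError("t_eval must be increasing and inside t_span")

    dyn = model.dynamic_species
    clamp_funs = {sid: _as_time_function(v) for sid, v in clamped_profiles.items()}
    scale_funs = {rid: _as_time_function(v) for rid, v in (scale_profiles or {}).items()}
    n_matrix = model.stoichiometric_matrix()

    def conc_at(t, y):
        conc = {sid: f(t) for sid, f in clamp_funs.items()}
        for sid, ci in zip(dyn, y):
            conc[sid] = ci
        return conc

    def rhs(t, y):
        conc = conc_at(t, y)
        scales = {rid: f(t) for rid, f in scale_funs.items()}
        v = model.rates(conc, scales, _validate=False)
        vvec = np.array([v[rid] for rid in model.reaction_ids])
        return 60.0 * (n_matrix @ vvec)

    y0 = np.array([float(initial[sid]) for sid in dyn])
    sol = solve_ivp(rhs, t_span, y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}",
                              last_time=sol.t[-1] if sol.t.size else t_span[0])

    concs = {sid: sol.y[i] for i, sid in enumerate(dyn)}
    if sol.t.size and sol.t[0] == t_span[0]:
        for i, sid in enumerate(dyn):        # initial point is exact, not interpolated
            concs[sid][0] = y0[i]
    for sid, f in clamp_funs.items():
        concs[sid] = np.array([f(t) for t in sol.t])
    fluxes = {rid: np.empty(sol.t.size) for rid in model.reaction_ids}
    for k, t in enumerate(sol.t):
        conc = conc_at(t, sol.y[:, k])
        scales = {rid: f(t) for rid, f in scale_funs.items()}
        v = model.rates(conc, scales, _validate=False)
        for rid in model.reaction_ids:
            fluxes[rid][k] = v[rid]
    return KineticTrajectory(sol.t, concs, fluxes)


def toy_pathway(vmax=(10.0, 20.0, 20.0), km=(1.0, 2.0, 2.0)) -> NetworkModel:
    """Three-step irreversible Michaelis–Menten chain S → A → B → P.

    S and P are extracellular (clamped); the default parameters give the
    closed-form steady state A = B = flux·K/(Vmax−flux) used as an analytic
    oracle throughout the test-suite.
    """
    species = [Species("S", "extracellular"), Species("A", "intracellular"),
               Species("B", "intracellular"), Species("P", "extracellular")]
    reactions = [
        Reaction("v1", {"S": -1, "A": 1},
                 RateLaw("irreversible_mm", vmax[0], {"S": km[0]}), 1),
        Reaction("v2", {"A": -1, "B": 1},
                 RateLaw("irreversible_mm", vmax[1], {"A": km[1]}), 2),
        Reaction("v3", {"B": -1, "P": 1},
                 RateLaw("irreversible_mm", vmax[2], {"B": km[2]}), 3),
    ]
    return NetworkModel(species, reactions, clamped={"S", "P"}, name="toy_pathway")
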