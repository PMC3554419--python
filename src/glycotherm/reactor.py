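"""Bioreactor embedding of the kinetic network.

Extracellular amounts follow  dN_i/dt = q_i·N_X + F_in·C_i,in − F_out·C_i,out,
with the biomass-specific rates q_i (mmol·gDW⁻¹·h⁻¹) obtained from the
intracellular fluxes (mM·min⁻¹ of cytosol) via the cytosolic volume per gram
dry weight.  Biomass grows as μ = Y_XS·q_S with q_S the specific glucose
uptake in g·gDW⁻¹·h⁻¹; a growth-coupled anabolic drain removes hexose
phosphate equivalent to the biomass carbon formed, so that carbon closes
exactly over glucose → ethanol + glycerol + CO₂ + biomass.  Ethanol
additionally evaporates with a first-order rate constant; CO₂ is vented and
tracked as a cumulative off-gas amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import ConfigurationError, SimulationError, SteadyStateError
from .kinetic_core import NetworkModel
from .thermo import TemperatureProfile

MW_GLUCOSE = 180.16            # g·mol⁻¹
BIOMASS_G_PER_CMOL = 24.6      # CH1.8O0.5N0.2
CARBON_PER_GLUCOSE = 6

#: carbon atoms per mole, for the closed-batch audit
CARBON_CONTENT = {"GLCo": 6, "ETOH": 2, "GLYC": 3, "CO2": 1,
                  "GLCi": 6, "G6P": 6, "F6P": 6, "FBP": 6,
                  "TRIO": 3, "PEP": 3, "PYR": 3}


@dataclass
class ReactorConfig:
    """Reactor mode and physical parameters.

    Defaults mirror the study's setup: glucose feed 25 g·L⁻¹ (138.8 mM),
    dilution rate 0.03 h⁻¹ for chemostats, anaerobic biomass yield
    0.09 g·g⁻¹, 2 mL cytosol per gDW, ethanol evaporation 0.008 h⁻¹.
    """

    mode: str = "chemostat"                       # 'batch' or 'chemostat'
    volume: float = 1.0                           # L
    dilution_rate: float = 0.03                   # h⁻¹ (chemostat)
    feed_concentrations: dict[str, float] = field(
        default_factory=lambda: {"GLCo": 138.8})  # mM
    yield_x_s: float = 0.09                       # gDW per g glucose
    cytosol_volume_factor: float = 2.0            # mL cytosol per gDW
    evaporation_k: float = 0.008                  # h⁻¹, ethanol
    initial_biomass: float = 0.2                  # gDW·L⁻¹ (batch start)

    def __post_init__(self):
        if self.mode not in ("batch", "chemostat"):
            raise ConfigurationError(f"unknown reactor mode {self.mode!r}")
        if self.mode == "batch":
            self.dilution_rate = 0.0

    @property
    def f_in(self) -> float:
        return self.dilution_rate * self.volume

    @property
    def f_out(self) -> float:
        return self.f_in

    @property
    def flux_to_specific(self) -> float:
        """mM·min⁻¹ (cytosol) → mmol·gDW⁻¹·h⁻¹."""
        return 60.0 * self.cytosol_volume_factor / 1000.0

    @property
    def anabolic_fraction(self) -> float:
        """Hexose-phosphate drain per unit glucose-uptake flux that exactly
        supplies the biomass carbon implied by the yield."""
        return self.yield_x_s * MW_GLUCOSE / (BIOMASS_G_PER_CMOL * CARBON_PER_GLUCOSE)

    def growth_rate(self, v_uptake: float) -> float:
        """μ (h⁻¹) from the glucose-uptake flux (mM·min⁻¹ cytosol)."""
        q_s_gram = v_uptake * self.flux_to_specific * MW_GLUCOSE / 1000.0
        return self.yield_x_s * q_s_gram


@dataclass
class ReactorState:
    """Amount-based reactor state: extracellular mmol, biomass gDW,
    intracellular mM."""

    n_i: dict[str, float]
    n_x: float
    intracellular: dict[str, float]
    t: float = 0.0
    temperature: float = 30.0


def _extracellular_ids(model: NetworkModel) -> list[str]:
    return [s.id for s in model.species if s.compartment == "extracellular"]


def _specific_rates(model: NetworkModel, fluxes: Mapping[str, float],
                    config: ReactorConfig) -> dict[str, float]:
    """q_i (mmol·gDW⁻¹·h⁻¹) for every extracellular species."""
    conv = config.flux_to_specific
    return {sid: conv * sum(r.stoichiometry.get(sid, 0) * fluxes[r.id]
                            for r in model.reactions)
            for sid in _extracellular_ids(model)}


def reactor_derivative(state: ReactorState, t: float, model: NetworkModel,
                       scales: Mapping[str, float], config: ReactorConfig
                       ) -> tuple[dict[str, float], float, dict[str, float]]:
    """Time derivative of (extracellular amounts, biomass, intracellular mM).

    ``scales`` must already be evaluated at the current temperature.  Returns
    (dN_i/dt mmol·h⁻¹, dN_X/dt gDW·h⁻¹, dC/dt mM·h⁻¹).
    """
    conc = dict(state.intracellular)
    for sid in _extracellular_ids(model):
        conc[sid] = state.n_i.get(sid, 0.0) / config.volume
    v = model.rates(conc, scales, _validate=False)
    uptake = v.get("GLT", 0.0)
    mu = config.growth_rate(uptake)

    dyn = model.dynamic_species
    n_matrix = model.stoichiometric_matrix(dyn)
    vvec = np.array([v[rid] for rid in model.reaction_ids])
    dc = 60.0 * (n_matrix @ vvec)
    dcd = dict(zip(dyn, dc))
    if "G6P" in dcd:
        dcd["G6P"] -= 60.0 * config.anabolic_fraction * uptake

    q = _specific_rates(model, v, config)
    dn: dict[str, float] = {}
    for sid in _extracellular_ids(model):
        if sid == "CO2":                      # vented: pure accumulation
            dn[sid] = q[sid] * state.n_x
            continue
        val = q[sid] * state.n_x
        val += config.f_in * config.feed_concentrations.get(sid, 0.0)
        val -= config.f_out * (state.n_i.get(sid, 0.0) / config.volume)
        if sid == "ETOH":
            val -= config.evaporation_k * state.n_i.get(sid, 0.0)
        dn[sid] = val
    dnx = (mu - config.dilution_rate) * state.n_x
    return dn, dnx, dcd


def clamped_steady_state(model: NetworkModel, config: ReactorConfig,
                         clamps: Mapping[str, float],
                         scales: Mapping[str, float],
                         guess: Mapping[str, float] | None = None,
                         tol: float = 1e-8) -> dict[str, float]:
    """Intracellular steady state at fixed broth concentrations, including the
    growth-coupled hexose-phosphate drain (the per-cell system the reactor
    integrates).  Returns the intracellular concentration map."""
    dyn = model.dynamic_species
    n_matrix = model.stoichiometric_matrix(dyn)
    g6p = dyn.index("G6P") if "G6P" in dyn else None
    x0 = np.log([max(float((guess or {}).get(s, 1.0)), 1e-8) for s in dyn])

    def fun(z):
        conc = dict(clamps)
        for s, ci in zip(dyn, np.exp(z)):
            conc[s] = ci
        v = model.rates(conc, scales, _validate=False)
        vvec = np.array([v[rid] for rid in model.reaction_ids])
        res = n_matrix @ vvec
        if g6p is not None:
            res[g6p] -= config.anabolic_fraction * v.get("GLT", 0.0)
        return res

    sol = root(fun, x0, method="hybr", options={"xtol": 1e-13})
    resid = float(np.max(np.abs(fun(sol.x))))
    if resid > tol:
        raise SteadyStateError(
            f"clamped steady state not found (residual {resid:.2e} mM/min)",
            residual=resid)
    return dict(zip(dyn, np.exp(sol.x)))


def _chemostat_guess(model: NetworkModel, config: ReactorConfig,
                     scales: Mapping[str, float]) -> dict[str, float]:
    """Continuation in residual glucose: walk the clamped (per-cell) steady
    state down from glucose excess until μ brackets D, then bisect.  Gives the
    multi-dimensional solver a starting point close to the true chemostat
    state, which matters at warm temperatures where residual glucose is tiny.
    """
    from scipy.optimize import brentq

    d = config.dilution_rate
    feed = config.feed_concentrations.get("GLCo", 138.8)
    base_clamps = {sid: 0.0 for sid in _extracellular_ids(model)}
    cache: dict[str, float] = {}

    def mu_at(glco: float) -> float:
        clamps = dict(base_clamps)
        clamps["GLCo"] = glco
        conc = clamped_steady_state(model, config, clamps, scales,
                                    guess=cache or None, tol=1e-6)
        cache.clear()
        cache.update(conc)
        full = dict(conc)
        full.update(clamps)
        return config.growth_rate(model.rates(full, scales)["GLT"])

    grid = np.geomspace(feed, 1e-4 * feed, 25)
    mu_hi = mu_at(grid[0])
    if mu_hi <= d:        # washout: best guess is glucose at feed level
        return {**cache, "GLCo": feed, "X": 1e-3}
    lo = None
    for g_prev, g in zip(grid, grid[1:]):
        if mu_at(g) < d:
            lo = (g, g_prev)
            break
    if lo is None:
        lo = (grid[-1], grid[0])
    g_star = brentq(lambda g: mu_at(g) - d, lo[0], lo[1], xtol=1e-10)
    mu_at(g_star)
    qs = d / (config.yield_x_s * MW_GLUCOSE / 1000.0)    # mmol·gDW⁻¹·h⁻¹
    x_guess = max(d * (feed - g_star) / qs, 1e-3)
    return {**cache, "GLCo": g_star, "X": x_guess}


def chemostat_steady_state(model: NetworkModel, config: ReactorConfig,
                           scales: Mapping[str, float],
                           guess: Mapping[str, float] | None = None) -> ReactorState:
    """Full chemostat steady state: intracellular pools, residual glucose and
    biomass such that all balances close and μ = D."""
    if config.mode != "chemostat":
        raise ConfigurationError("chemostat steady state needs chemostat mode")
    d = config.dilution_rate
    feed = config.feed_concentrations.get("GLCo", 0.0)
    dyn = model.dynamic_species
    unknown = dyn + ["GLCo", "X"]
    if guess is None:
        guess = _chemostat_guess(model, config, scales)
    guess = dict(guess)
    guess.setdefault("GLCo", 1.0)
    guess.setdefault("X", 2.0)
    x0 = np.log([max(float(guess.get(s, 1.0)), 1e-8) for s in unknown])
    n_matrix = model.stoichiometric_matrix(dyn)
    conv = config.flux_to_specific
    g6p = dyn.index("G6P") if "G6P" in dyn else None

    def fun(z):
        c = np.exp(z)
        conc = dict(zip(unknown[:-1], c[:-1]))
        x_bio = c[-1]
        for sid in _extracellular_ids(model):
            conc.setdefault(sid, 0.0)
        v = model.rates(conc, scales, _validate=False)
        vvec = np.array([v[rid] for rid in model.reaction_ids])
        res = n_matrix @ vvec
        uptake = v.get("GLT", 0.0)
        if g6p is not None:
            res[g6p] -= config.anabolic_fraction * uptake
        res_mu = (config.growth_rate(uptake) - d) * 1e3
        res_glc = -uptake * conv * x_bio + d * (feed - conc["GLCo"])
        return np.concatenate([res, [res_mu, res_glc]])

    sol = root(fun, x0, method="hybr", options={"xtol": 1e-13})
    resid = float(np.max(np.abs(fun(sol.x))))
    if resid > 1e-7:
        raise SteadyStateError(
            f"chemostat steady state not found (residual {resid:.2e}); "
            "the culture may be infeasible (washout) at this temperature",
            residual=resid)
    c = np.exp(sol.x)
    intracellular = dict(zip(dyn, c[:len(dyn)]))
    glco, x_bio = c[-2], c[-1]
    conc = dict(intracellular)
    for sid in _extracellular_ids(model):
        conc[sid] = glco if sid == "GLCo" else 0.0
    v = model.rates(conc, scales)
    q = _specific_rates(model, v, config)
    n_i = {"GLCo": glco * config.volume, "CO2": 0.0}
    if "ETOH" in q:
        n_i["ETOH"] = q["ETOH"] * x_bio / (d + config.evaporation_k) * config.volume
    if "GLYC" in q and d > 0:
        n_i["GLYC"] = q["GLYC"] * x_bio / d * config.volume
    return ReactorState(n_i=n_i, n_x=x_bio * config.volume,
                        intracellular=intracellular, t=0.0)


def initial_batch_state(model: NetworkModel, config: ReactorConfig,
                        scales: Mapping[str, float]) -> ReactorState:
    """Glucose-excess start: broth at feed glucose, intracellular pools at the
    corresponding steady state (cells adapted to excess), small inoculum."""
    feed = config.feed_concentrations.get("GLCo", 138.8)
    clamps = {sid: 0.0 for sid in _extracellular_ids(model)}
    clamps["GLCo"] = feed
    intracellular = clamped_steady_state(model, config, clamps, scales)
    n_i = {sid: clamps[sid] * config.volume for sid in _extracellular_ids(model)}
    return ReactorState(n_i=n_i, n_x=config.initial_biomass * config.volume,
                        intracellular=intracellular, t=0.0)


@dataclass
class Trajectory:
    """Tidy reactor time course.

    ``data`` columns: time_h, temperature_C, one column per species (mM;
    broth concentration for extracellular, cumulative off-gas for CO2 as
    co2_cum_mM), biomass_gdw_l, mu_h, flux_<rxn> (mM·min⁻¹) and q_<ext>
    (mmol·gDW⁻¹·h⁻¹).
    """

    data: pd.DataFrame
    washout_flagged: bool = False

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def interpolate(self, time_h: float) -> pd.Series:
        """Linear interpolation of every column at one time point."""
        t = self.data["time_h"].to_numpy()
        out = {}
        for col in self.data.columns:
            out[col] = float(np.interp(time_h, t, self.data[col].to_numpy()))
        return pd.Series(out)


def run_reactor(model: NetworkModel, config: ReactorConfig,
                profile: TemperatureProfile,
                scale_functions: Mapping[str, Callable[[float], float]],
                t_span: tuple[float, float],
                t_eval: np.ndarray | list[float] | None = None,
                initial: ReactorState | None = None,
                rtol: float = 1e-8, atol: float = 1e-10,
                stop_on_glucose: float | None = None) -> Trajectory:
    """Integrate the full reactor under a temperature profile.

    ``scale_functions`` maps reaction id → R_j(T); the temperature at each
    time comes from ``profile``.  A chemostat defaults to starting at the
    steady state of the profile's initial temperature (the study equilibrated
    five residence times before perturbing).  ``stop_on_glucose`` terminates a
    batch when broth glucose falls to the given concentration (mM).
    """
    def scales_at(t):
        temp = profile.temperature(t)
        return {rid: f(temp) for rid, f in scale_functions.items()}

    if initial is None:
        if config.mode == "chemostat":
            initial = chemostat_steady_state(model, config, scales_at(t_span[0]))
        else:
            initial = initial_batch_state(model, config, scales_at(t_span[0]))

    ext = _extracellular_ids(model)
    dyn = model.dynamic_species
    n_matrix = model.stoichiometric_matrix(dyn)
    conv = config.flux_to_specific
    vol = config.volume
    rids = model.reaction_ids
    g6p = dyn.index("G6P") if "G6P" in dyn else None
    if t_eval is None:
        t_eval = np.linspace(*t_span, 501)
    t_eval = np.asarray(t_eval, dtype=float)

    y0 = np.array([initial.intracellular[s] for s in dyn]
                  + [initial.n_i.get(s, 0.0) for s in ext] + [initial.n_x])

    def rhs(t, y):
        conc = dict(zip(dyn, y[:len(dyn)]))
        for k, s in enumerate(ext):
            conc[s] = y[len(dyn) + k] / vol
        x_bio = y[-1]
        v = model.rates(conc, scales_at(t), _validate=False)
        vvec = np.array([v[rid] for rid in rids])
        dc = 60.0 * (n_matrix @ vvec)
        uptake = v.get("GLT", 0.0)
        if g6p is not None:
            dc[g6p] -= 60.0 * config.anabolic_fraction * uptake
        dn = np.empty(len(ext))
        for k, sid in enumerate(ext):
            q_i = conv * sum(r.stoichiometry.get(sid, 0) * v[r.id]
                             for r in model.reactions)
            if sid == "CO2":
                dn[k] = q_i * x_bio
                continue
            val = q_i * x_bio + config.f_in * config.feed_concentrations.get(sid, 0.0) \
                - config.f_out * conc[sid]
            if sid == "ETOH":
                val -= config.evaporation_k * y[len(dyn) + k]
            dn[k] = val
        dnx = (config.growth_rate(uptake) - config.dilution_rate) * x_bio
        return np.concatenate([dc, dn, [dnx]])

    events = None
    if stop_on_glucose is not None and "GLCo" in ext:
        idx = len(dyn) + ext.index("GLCo")

        def glucose_low(t, y):
            return y[idx] / vol - stop_on_glucose
        glucose_low.terminal = True
        glucose_low.direction = -1
        events = [glucose_low]

    sol = solve_ivp(rhs, t_span, y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol, events=events)
    if not sol.success:
        raise SimulationError(f"reactor integration failed: {sol.message}",
                              last_time=sol.t[-1] if sol.t.size else t_span[0])

    rows = []
    washout = False
    for k, t in enumerate(sol.t):
        y = sol.y[:, k]
        conc = dict(zip(dyn, y[:len(dyn)]))
        for j, s in enumerate(ext):
            conc[s] = y[len(dyn) + j] / vol
        x_bio = y[-1]
        v = model.rates(conc, scales_at(t), _validate=False)
        mu = config.growth_rate(v.get("GLT", 0.0))
        if config.mode == "chemostat" and mu < 0.5 * config.dilution_rate:
            washout = True
        row = {"time_h": t, "temperature_C": profile.temperature(t),
               "biomass_gdw_l": x_bio / vol, "mu_h": mu}
        for s in dyn:
            row[s] = conc[s]
        for s in ext:
            row["co2_cum_mM" if s == "CO2" else s] = conc[s]
        for rid in rids:
            row[f"flux_{rid}"] = v[rid]
        q = _specific_rates(model, v, config)
        for s in ext:
            row[f"q_{s}"] = q[s]
        rows.append(row)
    return Trajectory(data=pd.DataFrame(rows), washout_flagged=washout)


def co2_offgas_rate(traj_row: Mapping[str, float], config: ReactorConfig) -> float:
    """Reactor CO₂ off-gas rate (mmol·h⁻¹) at one trajectory point:
    v_PDC · cytosol conversion · N_X, never negative."""
    return max(traj_row["q_CO2"], 0.0) * traj_row["biomass_gdw_l"] * config.volume


def carbon_balance_error(traj: Trajectory, config: ReactorConfig) -> float:
    """Relative carbon-closure error between the first and last point of a
    closed-batch run (evaporation off): glucose carbon consumed versus carbon
    in ethanol + glycerol + CO₂ + biomass + intracellular pool changes."""
    d0 = traj.data.iloc[0]
    d1 = traj.data.iloc[-1]
    vol = config.volume
    consumed = (d0["GLCo"] - d1["GLCo"]) * vol * CARBON_CONTENT["GLCo"]
    produced = 0.0
    for sid in ("ETOH", "GLYC"):
        if sid in traj.data.columns:
            produced += (d1[sid] - d0[sid]) * vol * CARBON_CONTENT[sid]
    if "co2_cum_mM" in traj.data.columns:
        produced += (d1["co2_cum_mM"] - d0["co2_cum_mM"]) * vol
    produced += (d1["biomass_gdw_l"] - d0["biomass_gdw_l"]) * vol \
        / BIOMASS_G_PER_CMOL * 1000.0
    for sid, nc in CARBON_CONTENT.items():
        if sid in ("GLCo", "ETOH", "GLYC", "CO2") or sid not in traj.data.columns:
            continue
        cyt0 = d0["biomass_gdw_l"] * vol * config.cytosol_volume_factor / 1000.0
        cyt1 = d1["biomass_gdw_l"] * vol * config.cytosol_volume_factor / 1000.0
        produced += (d1[sid] * cyt1 - d0[sid] * cyt0) * nc
    return abs(produced - consumed) / abs(consumed)
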