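"""The simulation study: temperature regimes × sensitivity hypotheses.

Two rounds are simulated.  Under the *identical* hypothesis every enzyme
shares the normalized Ratkowsky capacity function R(T); at steady state the
network equations then lose their temperature dependence and every
intracellular metabolite is a function of extracellular glucose alone.  Under
the *single_enzyme_different* hypothesis one enzyme's Ratkowsky exponent is
divided by the sensitivity factor, which breaks that collapse upstream of the
perturbed reaction — most visibly under glucose excess, where the common
factor otherwise cancels exactly.

Regimes: SBR (sequential batches at 12/18/24/30 °C, sampled three times in
the exponential phase), LTS30/LTS12 (3-h linear temperature shift applied to
a steady chemostat, sampled at the 30/24/18/12 °C crossings and 1–3 h after
return) and CTC (circadian sinusoid on a chemostat, sampled every 3 h during
cycles 5–6).
"""

from __future__ import annotations

from copy import deepcopy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .kinetic_core import NetworkModel, solve_steady_state
from .reactor import ReactorConfig, Trajectory, clamped_steady_state, run_reactor
from .thermo import (RatkowskyParams, SensitivitySpec, TemperatureProfile,
                     apply_sensitivity, ctc_profile, lts_profile,
                     vant_hoff_params_from_table, keq_at_temperature,
                     CELSIUS_OFFSET)

#: metabolites reported by the measurement campaign, in pathway order
MEASURED_METABOLITES = ["G6P", "F6P", "FBP", "TRIO", "PEP", "PYR"]

REGIMES = ("SBR", "LTS12", "LTS30", "CTC")


@dataclass
class ScenarioSpec:
    """One regime under one temperature-sensitivity hypothesis."""

    regime: str
    hypothesis: str = "identical"            # or 'single_enzyme_different'
    sensitivity: SensitivitySpec | None = None
    batch_temperatures: tuple = (12.0, 18.0, 24.0, 30.0)
    ctc_cycles_before_sampling: int = 4      # sample cycles 5-6
    ctc_sampling_interval_h: float = 3.0
    lts_post_return_hours: tuple = (1.0, 2.0, 3.0)
    sbr_glucose_window: tuple = (0.8, 0.3)   # exponential-phase sampling window

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.hypothesis not in ("identical", "single_enzyme_different"):
            raise ConfigurationError(f"unknown hypothesis {self.hypothesis!r}")
        if self.hypothesis == "single_enzyme_different" and self.sensitivity is None:
            raise ConfigurationError(
                "single_enzyme_different requires a SensitivitySpec")


@dataclass
class ScenarioResult:
    """Sampled rows plus the underlying trajectories (keyed by sub-run)."""

    spec: ScenarioSpec
    samples: pd.DataFrame            # regime, time_h, temperature_C, glucose_mM,
    trajectories: dict = field(default_factory=dict)    # metabolites + norm_*
    reference: dict = field(default_factory=dict)       # normalization levels, mM

    def long_table(self) -> pd.DataFrame:
        """Tidy (one metabolite per row) view used by the collapse analysis."""
        rows = []
        for _, r in self.samples.iterrows():
            for met in MEASURED_METABOLITES:
                rows.append({"regime": r["regime"], "time_h": r["time_h"],
                             "temperature_C": r["temperature_C"],
                             "glucose_mM": r["glucose_mM"], "metabolite": met,
                             "level": r[met]})
        return pd.DataFrame(rows)


def scale_functions_for(model: NetworkModel, params: RatkowskyParams,
                        spec: ScenarioSpec):
    sens = spec.sensitivity if spec.hypothesis == "single_enzyme_different" else None
    return apply_sensitivity(params, sens, model.reaction_ids)


def reference_levels(model: NetworkModel, config: ReactorConfig,
                     params: RatkowskyParams, spec: ScenarioSpec) -> dict[str, float]:
    """Normalization reference: glucose-excess steady state at the reference
    temperature (30 °C), where every scale function equals one."""
    scale_funs = scale_functions_for(model, params, spec)
    scales = {rid: f(params.t_ref) for rid, f in scale_funs.items()}
    clamps = {s.id: 0.0 for s in model.species if s.compartment == "extracellular"}
    clamps["GLCo"] = config.feed_concentrations.get("GLCo", 138.8)
    conc = clamped_steady_state(model, config, clamps, scales)
    return {m: conc[m] for m in MEASURED_METABOLITES if m in conc}


def _sample_rows(traj: Trajectory, regime: str, times: np.ndarray) -> list[dict]:
    rows = []
    for k, t in enumerate(times):
        point = traj.interpolate(float(t))
        row = {"regime": regime, "sample_index": k, "time_h": float(t),
               "temperature_C": point["temperature_C"],
               "glucose_mM": point["GLCo"],
               "biomass_gdw_l": point["biomass_gdw_l"],
               "q_CO2": point["q_CO2"], "mu_h": point["mu_h"]}
        for met in MEASURED_METABOLITES:
            row[met] = point[met]
        rows.append(row)
    return rows


def _sbr_sampling_times(traj: Trajectory, feed: float, window: tuple) -> np.ndarray:
    """Three exponential-phase times: glucose crossings of the window edges
    and their geometric midpoint."""
    g = traj.column("GLCo")
    t = traj.column("time_h")
    hi, lo = window[0] * feed, window[1] * feed
    mid = float(np.sqrt(hi * lo))
    times = []
    for target in (hi, mid, lo):
        below = np.nonzero(g <= target)[0]
        if below.size == 0:
            raise ConfigurationError(
                "batch did not deplete glucose into the sampling window")
        k = below[0]
        if k == 0:
            times.append(t[0])
        else:
            f = (g[k - 1] - target) / (g[k - 1] - g[k])
            times.append(t[k - 1] + f * (t[k] - t[k - 1]))
    return np.asarray(times)


def _lts_sampling_times(profile: TemperatureProfile, post_hours: tuple) -> np.ndarray:
    """Crossings of 30/24/18/12 °C on both ramp legs plus post-return points."""
    leg = profile.leg_duration_h
    marks = [0.0, 2 * leg]
    for temp in (12.0, 18.0, 24.0, 30.0):
        dt = abs(temp - profile.start_t) / (profile.ramp_rate * 60.0)
        if 0.0 < dt <= leg:
            marks.append(dt)                # outbound leg crossing
            marks.append(2 * leg - dt)      # return leg crossing
    marks += [2 * leg + h for h in post_hours]
    return np.unique(np.round(marks, 6))


def run_scenario(model: NetworkModel, spec: ScenarioSpec,
                 params: RatkowskyParams, config: ReactorConfig,
                 reference: dict[str, float] | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10,
                 initial_biomass_factor: float = 1.0) -> ScenarioResult:
    """Simulate one regime and return its sampled metabolite table.

    ``reference`` (metabolite → mM) normalizes levels.  By default an SBR run
    normalizes to its own first 30 °C glucose-excess sample (so that row is
    exactly one), and chemostat regimes to the glucose-excess steady state at
    the reference temperature.  ``initial_biomass_factor`` jitters the
    starting biomass (used to emulate independent cultures).
    """
    scale_funs = scale_functions_for(model, params, spec)
    feed = config.feed_concentrations.get("GLCo", 138.8)
    rows: list[dict] = []
    trajectories: dict[str, Trajectory] = {}

    if spec.regime == "SBR":
        bcfg = deepcopy(config)
        bcfg.mode = "batch"
        bcfg.dilution_rate = 0.0
        bcfg.initial_biomass = config.initial_biomass * initial_biomass_factor
        for temp in spec.batch_temperatures:
            profile = TemperatureProfile("constant", constant_t=temp)
            # generous horizon; terminate once glucose leaves the window
            t_end = 600.0
            traj = run_reactor(model, bcfg, profile, scale_funs, (0.0, t_end),
                               t_eval=np.linspace(0.0, t_end, 4001),
                               rtol=rtol, atol=atol,
                               stop_on_glucose=0.25 * feed)
            times = _sbr_sampling_times(traj, feed, spec.sbr_glucose_window)
            # each batch temperature is a culture of its own
            rows += _sample_rows(traj, f"SBR{temp:g}", times)
            trajectories[f"SBR_{temp:g}C"] = traj
    else:
        if spec.regime == "CTC":
            profile = ctc_profile()
            n_cycles = spec.ctc_cycles_before_sampling + 2
            t_end = profile.period_h * n_cycles
            t0 = profile.period_h * spec.ctc_cycles_before_sampling
            times = np.arange(t0, t_end + 1e-9, spec.ctc_sampling_interval_h)
        else:
            start_t = 30.0 if spec.regime == "LTS30" else 12.0
            target_t = 12.0 if spec.regime == "LTS30" else 30.0
            profile = lts_profile(start_t=start_t, target_t=target_t)
            times = _lts_sampling_times(profile, spec.lts_post_return_hours)
            t_end = float(times[-1])
        ccfg = deepcopy(config)
        ccfg.mode = "chemostat"
        initial = None
        if initial_biomass_factor != 1.0:
            from .reactor import chemostat_steady_state
            scales0 = {rid: f(profile.temperature(0.0)) for rid, f in scale_funs.items()}
            initial = chemostat_steady_state(model, ccfg, scales0)
            initial.n_x *= initial_biomass_factor
        grid = np.union1d(np.linspace(0.0, t_end, max(int(t_end * 20), 200)), times)
        traj = run_reactor(model, ccfg, profile, scale_funs, (0.0, t_end),
                           t_eval=grid, initial=initial, rtol=rtol, atol=atol)
        rows += _sample_rows(traj, spec.regime, times)
        trajectories[spec.regime] = traj

    samples = pd.DataFrame(rows)
    if reference is None:
        if spec.regime == "SBR":
            ref_rows = samples[(samples["sample_index"] == 0)
                               & (np.isclose(samples["temperature_C"],
                                             max(spec.batch_temperatures)))]
            reference = {m: float(ref_rows.iloc[0][m]) for m in MEASURED_METABOLITES}
        else:
            reference = reference_levels(model, config, params, spec)
    for met in MEASURED_METABOLITES:
        samples[f"norm_{met}"] = samples[met] / reference[met]
    return ScenarioResult(spec=spec, samples=samples, trajectories=trajectories,
                          reference=dict(reference))


def run_round(model: NetworkModel, hypothesis: str, params: RatkowskyParams,
              config: ReactorConfig, sensitivity: SensitivitySpec | None = None,
              regimes: tuple = ("SBR", "LTS30", "CTC"),
              rtol: float = 1e-8, atol: float = 1e-10) -> pd.DataFrame:
    """One full simulation round over several regimes, normalized to a shared
    glucose-excess 30 °C reference (the first 30 °C batch sample when SBR is
    part of the round)."""
    ordered = sorted(regimes, key=lambda r: r != "SBR")   # SBR first
    reference = None
    frames = {}
    for regime in ordered:
        spec = ScenarioSpec(regime=regime, hypothesis=hypothesis,
                            sensitivity=sensitivity)
        res = run_scenario(model, spec, params, config, reference=reference,
                           rtol=rtol, atol=atol)
        reference = res.reference
        frames[regime] = res.samples
    out = pd.concat([frames[r] for r in regimes], ignore_index=True)
    out.insert(0, "hypothesis", hypothesis)
    return out


def flux_temperature_sensitivity(model: NetworkModel, params: RatkowskyParams,
                                 temperature_c: float, d_temperature: float = 0.1,
                                 sensitivity: SensitivitySpec | None = None,
                                 glucose_mM: float = 138.8,
                                 substrate_id: str = "GLCo",
                                 scale_functions=None) -> float:
    """Central-difference relative flux-temperature sensitivity (°C⁻¹) of the
    glucose-excess steady state: (1/J)·dJ/dT.

    With identical sensitivities this equals d ln R/dT = 2/(T − T_min)
    analytically, because concentrations are temperature-invariant and every
    flux is proportional to R(T).  ``scale_functions`` overrides the Ratkowsky
    scaling entirely (e.g. all-constant functions give zero sensitivity).
    """
    scale_funs = scale_functions if scale_functions is not None else \
        apply_sensitivity(params, sensitivity, model.reaction_ids)
    clamps = {s.id: 0.0 for s in model.species if s.compartment == "extracellular"}
    clamps[substrate_id] = glucose_mM
    guess = {s: 1.0 for s in model.dynamic_species}
    fluxes = {}
    for temp in (temperature_c - d_temperature, temperature_c, temperature_c + d_temperature):
        scales = {rid: f(temp) for rid, f in scale_funs.items()}
        ss = solve_steady_state(model, clamps, scales, initial_guess=guess)
        fluxes[temp] = ss.fluxes.get("GLT", ss.fluxes[model.reaction_ids[0]])
        guess = {s: ss.concentrations[s] for s in model.dynamic_species}
    j_lo = fluxes[temperature_c - d_temperature]
    j_hi = fluxes[temperature_c + d_temperature]
    j_mid = fluxes[temperature_c]
    return (j_hi - j_lo) / (2.0 * d_temperature * j_mid)


def model_with_keq_at(model: NetworkModel, temperature_c: float) -> NetworkModel:
    """Optional Van't Hoff propagation: a copy of the model whose reversible
    Keq values are moved from 30 °C to the given temperature using enthalpies
    fitted through the printed 12/30 °C anchor pairs (lumped reactions sum the
    enthalpies of their components).  Off by default in all scenario runs —
    the fold changes involved are below two and secondary to capacity scaling.
    """
    lump = {"HXK": ["HXK"], "PGI": ["PGI"], "PFK": ["PFK"],
            "FBA": ["FBA", "TPI"], "TDHL": ["TDH", "PGK", "PGM", "ENO"],
            "PYK": ["PYK"]}
    t_k = temperature_c + CELSIUS_OFFSET
    out = deepcopy(model)
    for rxn in out.reactions:
        if rxn.rate_law.keq_ref is None or rxn.id not in lump:
            continue
        factor = 1.0
        for enz in lump[rxn.id]:
            vh = vant_hoff_params_from_table(enz)
            factor *= keq_at_temperature(vh, t_k) / vh.keq_ref
        rxn.rate_law.keq_ref *= factor
    return out
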