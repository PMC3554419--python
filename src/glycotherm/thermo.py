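"""Temperature mathematics.

Enzyme capacity follows the sub-optimal branch of the Ratkowsky square-root
law, Vmax_j(T) = b_j (T − T_min)², normalized to the reference temperature:

    R(T) = ((T − T_min) / (T_ref − T_min))²,  R(T_ref) = 1.

Equilibrium constants follow the Van't Hoff relation
ln(Keq,2/Keq,1) = ΔH°r/R_gas · (1/T1 − 1/T2).

The default T_min of −0.42 °C calibrates R(30 °C)/R(12 °C) to 6.0, the
batch-flux ratio observed between those temperatures in anaerobic yeast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import ConfigurationError, DomainError

GAS_CONSTANT = 8.314          # J·mol⁻¹·K⁻¹
CELSIUS_OFFSET = 273.15

DEFAULT_T_MIN = -0.42         # °C
DEFAULT_T_REF = 30.0          # °C


@dataclass
class RatkowskyParams:
    """Square-root-law parameters; ``b_glc`` anchors the glucose-uptake step
    and per-reaction ``b_j`` follow the reference flux distribution."""

    b_glc: float = 0.14        # mM·min⁻¹·°C⁻²
    t_min: float = DEFAULT_T_MIN
    t_ref: float = DEFAULT_T_REF
    b_j: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.t_min < 12.0 <= self.t_ref):
            raise ConfigurationError("require t_min < 12 <= t_ref")
        if self.b_glc <= 0:
            raise ConfigurationError("b_glc must be > 0")


def ratkowsky_scale(params: RatkowskyParams, temperature_c: float,
                    exponent: float = 2.0) -> float:
    """Normalized capacity scale R(T) = ((T − T_min)/(T_ref − T_min))^exponent."""
    if temperature_c < params.t_min:
        raise DomainError(
            f"temperature {temperature_c} °C below T_min = {params.t_min} °C")
    return ((temperature_c - params.t_min) / (params.t_ref - params.t_min)) ** exponent


def compute_b(b_glc: float, v_j_ref: float, v_consumption_ref: float) -> float:
    """Ratkowsky coefficient of reaction j from its reference-flux share:
    b_j = b_glc · v_j(T_ref) / v_consumption(T_ref)."""
    if v_consumption_ref <= 0:
        raise DomainError("reference glucose consumption must be > 0")
    return b_glc * v_j_ref / v_consumption_ref


def ratkowsky_coefficients(params: RatkowskyParams,
                           reference_fluxes: Mapping[str, float],
                           uptake_reaction: str) -> dict[str, float]:
    """Per-reaction b_j for a whole flux distribution at the reference state."""
    v_cons = reference_fluxes[uptake_reaction]
    return {rid: compute_b(params.b_glc, v, v_cons)
            for rid, v in reference_fluxes.items()}


@dataclass
class VantHoffParams:
    """Keq at the reference temperature plus the standard reaction enthalpy."""

    keq_ref: float
    delta_h: float             # J·mol⁻¹
    t_ref_c: float = DEFAULT_T_REF

    def __post_init__(self):
        if self.keq_ref <= 0:
            raise DomainError("keq_ref must be > 0")


def vant_hoff_delta_h(keq_1: float, t1_k: float, keq_2: float, t2_k: float) -> float:
    """Invert the Van't Hoff relation for ΔH°r (J·mol⁻¹) from two (T, Keq) anchors."""
    if keq_1 <= 0 or keq_2 <= 0:
        raise DomainError("equilibrium constants must be > 0")
    if t1_k == t2_k:
        raise DomainError("anchor temperatures must differ")
    return GAS_CONSTANT * math.log(keq_2 / keq_1) / (1.0 / t1_k - 1.0 / t2_k)


def keq_at_temperature(params: VantHoffParams, temperature_k: float) -> float:
    """Keq(T) propagated from the reference anchor."""
    if temperature_k <= 0:
        raise DomainError("absolute temperature must be > 0")
    t_ref_k = params.t_ref_c + CELSIUS_OFFSET
    return params.keq_ref * math.exp(
        params.delta_h / GAS_CONSTANT * (1.0 / t_ref_k - 1.0 / temperature_k))


# --- printed equilibrium-constant table (12 °C, 30 °C anchors) --------------
# Fold-change direction varies by row in the printed source: 'lo_over_hi'
# rows report Keq(12)/Keq(30), 'hi_over_lo' rows Keq(30)/Keq(12).
KEQ_TABLE: dict[str, dict] = {
    "HXK": {"keq_12": 7.7e3,  "keq_30": 3.5e3,  "fold": 0.45, "direction": "hi_over_lo"},
    "PGI": {"keq_12": 0.27,   "keq_30": 0.29,   "fold": 0.93, "direction": "lo_over_hi"},
    "PFK": {"keq_12": 5.0e3,  "keq_30": 2.4e3,  "fold": 2.08, "direction": "lo_over_hi"},
    "FBA": {"keq_12": 9.3e-4, "keq_30": 1.4e-3, "fold": 1.51, "direction": "hi_over_lo"},
    "TPI": {"keq_12": 0.040,  "keq_30": 0.048,  "fold": 1.20, "direction": "hi_over_lo"},
    "TDH": {"keq_12": 0.66,   "keq_30": 0.69,   "fold": 1.05, "direction": "hi_over_lo"},
    "PGK": {"keq_12": 20.0,   "keq_30": 16.0,   "fold": 1.25, "direction": "lo_over_hi"},
    "PGM": {"keq_12": 0.074,  "keq_30": 0.087,  "fold": 1.18, "direction": "hi_over_lo"},
    "ENO": {"keq_12": 5.1,    "keq_30": 4.5,    "fold": 1.13, "direction": "lo_over_hi"},
    "PYK": {"keq_12": 3.9e4,  "keq_30": 1.4e4,  "fold": 2.79, "direction": "lo_over_hi"},
}

T12_K = 12.0 + CELSIUS_OFFSET
T30_K = 30.0 + CELSIUS_OFFSET


def keq_fold_change(enzyme: str) -> float:
    """Recompute the printed fold change from the table's own Keq pair, using
    that row's stated ratio direction."""
    row = KEQ_TABLE[enzyme]
    if row["direction"] == "lo_over_hi":
        return row["keq_12"] / row["keq_30"]
    return row["keq_30"] / row["keq_12"]


def vant_hoff_params_from_table(enzyme: str) -> VantHoffParams:
    """ΔH°r fitted through the two printed anchors, referenced at 30 °C."""
    row = KEQ_TABLE[enzyme]
    dh = vant_hoff_delta_h(row["keq_12"], T12_K, row["keq_30"], T30_K)
    return VantHoffParams(keq_ref=row["keq_30"], delta_h=dh, t_ref_c=30.0)


@dataclass
class SensitivitySpec:
    """Marks one reaction as ``factor`` times less temperature-sensitive than
    the rest of the network (factor 1 ⇒ no perturbation)."""

    reaction_id: str
    factor: float = 2.0

    def __post_init__(self):
        if self.factor < 1:
            raise ConfigurationError("sensitivity factor must be >= 1")


def apply_sensitivity(params: RatkowskyParams, spec: SensitivitySpec | None,
                      reaction_ids: list[str]) -> dict[str, Callable[[float], float]]:
    """Per-reaction normalized scale functions T(°C) → R_j(T).

    The perturbed reaction's Ratkowsky exponent is divided by ``factor``
    (2 → 1 for a two-fold lower sensitivity), which halves d ln R/dT at every
    temperature while keeping R(T_ref) = 1; all other reactions keep the
    baseline square law.
    """
    if spec is not None and spec.reaction_id not in reaction_ids:
        raise ConfigurationError(f"unknown reaction id {spec.reaction_id!r}")

    def make(exponent):
        return lambda t_c: ratkowsky_scale(params, t_c, exponent=exponent)

    funs = {rid: make(2.0) for rid in reaction_ids}
    if spec is not None and spec.factor > 1:
        funs[spec.reaction_id] = make(2.0 / spec.factor)
    return funs


@dataclass
class TemperatureProfile:
    """One of the study's three temperature regimes.

    constant      — fixed T (sequential-batch cultures at 12/18/24/30 °C)
    linear_shift  — down-and-back (or up-and-back) ramp at ``ramp_rate``
                    °C·min⁻¹ from ``start_t`` to ``target_t``, then hold
    sinoid        — circadian cycle T(t) = mean + amplitude·sin(ω·t + phase)
    """

    variant: str
    constant_t: float = 30.0
    start_t: float = 30.0
    target_t: float = 12.0
    ramp_rate: float = 0.2             # °C·min⁻¹
    hold_after_h: float = 3.0
    mean: float = 21.0
    amplitude: float = 9.0
    angular_frequency: float = math.pi / 12.0   # h⁻¹ → 24 h period
    phase: float = 1.57                # printed value, deliberately not π/2

    def __post_init__(self):
        if self.variant not in ("constant", "linear_shift", "sinoid"):
            raise ConfigurationError(f"unknown profile variant {self.variant!r}")

    @property
    def leg_duration_h(self) -> float:
        return abs(self.target_t - self.start_t) / (self.ramp_rate * 60.0)

    @property
    def shift_span_h(self) -> float:
        """Total duration of the down-and-back (or up-and-back) shift."""
        return 2.0 * self.leg_duration_h

    @property
    def period_h(self) -> float:
        if self.variant != "sinoid":
            raise ConfigurationError("period defined only for sinoid profiles")
        return 2.0 * math.pi / self.angular_frequency

    def temperature(self, t_h: float) -> float:
        if t_h < 0:
            raise DomainError("time must be >= 0")
        if self.variant == "constant":
            return self.constant_t
        if self.variant == "sinoid":
            return self.mean + self.amplitude * math.sin(
                self.angular_frequency * t_h + self.phase)
        leg = self.leg_duration_h
        rate = (self.ramp_rate * 60.0) * (1 if self.target_t > self.start_t else -1)
        if t_h <= leg:
            return self.start_t + rate * t_h
        if t_h <= 2 * leg:
            return self.target_t - rate * (t_h - leg)
        return self.start_t


def profile_temperature(profile: TemperatureProfile, t_h: float) -> float:
    """Functional alias for :meth:`TemperatureProfile.temperature`."""
    return profile.temperature(t_h)


def ctc_profile() -> TemperatureProfile:
    """The circadian cycle as programmed: T(°C) = 21 + 9·sin(π/12·t + 1.57)."""
    return TemperatureProfile("sinoid")


def lts_profile(start_t: float = 30.0, target_t: float = 12.0) -> TemperatureProfile:
    """Linear temperature shift at 0.2 °C·min⁻¹ with return to the start value."""
    return TemperatureProfile("linear_shift", start_t=start_t, target_t=target_t)
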