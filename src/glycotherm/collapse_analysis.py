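"""Quantifying the metabolite–glucose collapse and localizing a deviant enzyme.

The study's central readout is whether, across temperature regimes, each
intracellular metabolite is a single-valued function of extracellular glucose.
Here that is made quantitative: a pooled monotone (isotonic) reference curve
ĝ(S) is fitted per metabolite on log10 glucose, relative residuals
r = (level − ĝ)/ĝ are computed, and the collapse score is the median |r| —
pooled (C_m) and per regime (C_m,q).  A regime deviates when C_m,q exceeds a
threshold θ that encodes the replicate noise.  Residual temperature dependence
is tested by a seeded permutation test on the rank correlation of r with
sampling temperature.  Finally, if the deviation flags form a contiguous
head of the pathway, the enzyme at the boundary — the consumer of the most
downstream deviating metabolite — is reported as the localized perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .errors import ConfigurationError, DomainError
from .kinetic_core import NetworkModel

TABLE_COLUMNS = ["regime", "time_h", "temperature_C", "glucose_mM",
                 "metabolite", "level", "sem", "n"]

DEFAULT_THETA = 0.15
DEFAULT_PERMUTATIONS = 1000


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check MeasurementTable invariants (required columns, positive glucose,
    nonnegative standard errors); returns the table unchanged."""
    missing = [c for c in ("regime", "temperature_C", "glucose_mM",
                           "metabolite", "level") if c not in table.columns]
    if missing:
        raise ConfigurationError(f"measurement table misses columns {missing}")
    if (table["glucose_mM"] <= 0).any():
        raise DomainError("glucose must be > 0 for fitted rows")
    if "sem" in table.columns and (table["sem"].dropna() < 0).any():
        raise DomainError("standard errors must be >= 0")
    return table


@dataclass
class MonotoneCurve:
    """Isotonic fit of level against log10 glucose, interpolating inside the
    fitted range and clipping outside it."""

    log_glucose: np.ndarray
    fitted: np.ndarray
    increasing: bool

    def __call__(self, glucose_mM) -> np.ndarray:
        x = np.log10(np.asarray(glucose_mM, dtype=float))
        return np.interp(x, self.log_glucose, self.fitted)


def fit_reference_curve(glucose_mM, level) -> MonotoneCurve:
    """Monotone nonparametric reference curve ĝ(S).

    The direction is the sign of the rank correlation between log glucose and
    level; isotonic regression then projects onto the closest monotone
    function, so strictly monotone input is reproduced exactly.
    """
    g = np.asarray(glucose_mM, dtype=float)
    y = np.asarray(level, dtype=float)
    if g.size < 5:
        raise DomainError("need at least 5 points to fit a reference curve")
    if np.ptp(g) == 0.0:
        raise DomainError("zero glucose range: reference curve undefined")
    if np.any(g <= 0):
        raise DomainError("glucose must be > 0")
    x = np.log10(g)
    rho = _spearman(x, y)
    increasing = bool(rho >= 0)
    iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
    fitted = iso.fit_transform(x, y)
    order = np.argsort(x)
    return MonotoneCurve(x[order], fitted[order], increasing)


def _spearman(x, y) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def _permutation_pvalue(resid, temperature, n_permutations, rng) -> tuple[float, float]:
    """Two-sided permutation p-value of the rank correlation between residuals
    and temperature, permuting temperature labels."""
    rr = rankdata(resid)
    rr = rr - rr.mean()
    rt = rankdata(temperature)
    rt = rt - rt.mean()
    denom = np.sqrt((rr ** 2).sum() * (rt ** 2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho_obs = float((rr * rt).sum() / denom)
    perm = np.empty(n_permutations)
    for k in range(n_permutations):
        perm[k] = (rr * rng.permutation(rt)).sum() / denom
    p = (np.count_nonzero(np.abs(perm) >= abs(rho_obs) - 1e-12) + 1) / (n_permutations + 1)
    return rho_obs, float(p)


@dataclass
class CollapseRow:
    """Per-metabolite collapse diagnostics."""

    metabolite: str
    c_pooled: float
    c_by_regime: dict[str, float]
    flags: dict[str, bool]
    deviates: bool
    rho_temperature: float
    p_value: float
    theta: float


@dataclass
class CollapseReport:
    rows: dict[str, CollapseRow] = field(default_factory=dict)
    theta: float = DEFAULT_THETA
    seed: int | None = None
    n_permutations: int = DEFAULT_PERMUTATIONS

    def flags(self) -> dict[str, bool]:
        return {m: r.deviates for m, r in self.rows.items()}

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows.values():
            rec = {"metabolite": r.metabolite, "c_pooled": r.c_pooled,
                   "deviates": r.deviates, "rho_temperature": r.rho_temperature,
                   "p_value": r.p_value, "theta": r.theta}
            for q, c in r.c_by_regime.items():
                rec[f"c_{q}"] = c
            recs.append(rec)
        return pd.DataFrame(recs)


def collapse_scores(table: pd.DataFrame, metabolite: str,
                    theta: float = DEFAULT_THETA,
                    n_permutations: int = DEFAULT_PERMUTATIONS,
                    seed: int = 0) -> CollapseRow:
    """Collapse diagnostics for one metabolite against the pooled reference
    curve.  With a single regime only per-regime scores are defined and no
    flag is raised."""
    validate_table(table)
    sub = table[table["metabolite"] == metabolite]
    if sub.empty:
        raise ConfigurationError(f"no rows for metabolite {metabolite!r}")
    curve = fit_reference_curve(sub["glucose_mM"], sub["level"])
    ghat = curve(sub["glucose_mM"])
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(ghat != 0, (sub["level"].to_numpy() - ghat) / ghat, 0.0)
    c_pooled = float(np.median(np.abs(resid)))
    regimes = sub["regime"].unique()
    c_by_regime = {}
    flags = {}
    for q in regimes:
        mask = (sub["regime"] == q).to_numpy()
        c_q = float(np.median(np.abs(resid[mask])))
        c_by_regime[str(q)] = c_q
        flags[str(q)] = bool(c_q > theta)
    single_regime = len(regimes) < 2
    if single_regime:
        flags = {}
    rng = np.random.default_rng(seed)
    rho, p = _permutation_pvalue(resid, sub["temperature_C"].to_numpy(),
                                 n_permutations, rng)
    return CollapseRow(metabolite=metabolite, c_pooled=c_pooled,
                       c_by_regime=c_by_regime, flags=flags,
                       deviates=any(flags.values()) if flags else False,
                       rho_temperature=rho, p_value=p, theta=theta)


def collapse_report(table: pd.DataFrame, theta: float = DEFAULT_THETA,
                    n_permutations: int = DEFAULT_PERMUTATIONS,
                    seed: int = 0) -> CollapseReport:
    """Collapse diagnostics for every metabolite present in the table."""
    report = CollapseReport(theta=theta, seed=seed, n_permutations=n_permutations)
    for k, met in enumerate(pd.unique(table["metabolite"])):
        report.rows[met] = collapse_scores(table, met, theta=theta,
                                           n_permutations=n_permutations,
                                           seed=seed + k)
    return report


@dataclass
class LocalizationResult:
    """Outcome of the upstream/downstream boundary search."""

    candidate: str | None
    pattern: list[tuple[str, bool]]
    consistent: bool


def pathway_metabolite_order(model: NetworkModel,
                             metabolites: list[str]) -> list[str]:
    """Order metabolites by the pathway index of their consuming backbone
    reaction (branches carry pathway_index 0 and are ignored)."""
    def consumer_index(met: str) -> int:
        idx = [r.pathway_index for r in model.reactions
               if r.pathway_index > 0 and r.stoichiometry.get(met, 0) < 0]
        if not idx:
            raise ConfigurationError(
                f"metabolite {met!r} has no backbone consumer in the model")
        return min(idx)

    return sorted(metabolites, key=consumer_index)


def localize_deviant_enzyme(flags: dict[str, bool],
                            model: NetworkModel) -> LocalizationResult:
    """Find the reaction boundary implied by deviation flags.

    A perturbed enzyme leaves every metabolite upstream of itself off the
    collapse curve and every downstream one on it, so a consistent pattern is
    a non-empty contiguous head of deviating metabolites followed only by
    collapsed ones; the candidate is the backbone reaction consuming the last
    deviating metabolite.  All-clear flags return no candidate; any other
    pattern is inconsistent and reported as such.
    """
    if len(flags) < 3:
        raise ConfigurationError("need flags for at least 3 ordered metabolites")
    ordered = pathway_metabolite_order(model, list(flags))
    pattern = [(m, bool(flags[m])) for m in ordered]
    values = [f for _, f in pattern]
    if not any(values):
        return LocalizationResult(None, pattern, True)
    k = max(i for i, f in enumerate(values) if f)
    if not all(values[: k + 1]):
        return LocalizationResult(None, pattern, False)
    last = ordered[k]
    candidates = [(r.pathway_index, r.id) for r in model.reactions
                  if r.pathway_index > 0 and r.stoichiometry.get(last, 0) < 0]
    return LocalizationResult(min(candidates)[1], pattern, True)
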