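"""Pseudo-experimental datasets with the measurement structure of the study.

Sampling emulates the campaign design — duplicate samples at scheduled times,
two independent cultures per condition — with multiplicative lognormal noise
(default CV 10%, a typical magnitude for quantitative metabolomics with
isotope-dilution calibration; the study does not print its replicate CVs).
The lognormal factor is parameterized to have mean exactly one, so reported
levels are unbiased in expectation.  Glucose below the limit of quantification
is censored at LOQ/2, as concentration tables commonly do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .collapse_analysis import TABLE_COLUMNS
from .scenarios import MEASURED_METABOLITES, ScenarioResult


@dataclass
class NoiseModel:
    """Multiplicative measurement-noise description."""

    cv: float = 0.10
    replicates: int = 2
    glucose_loq: float = 0.01      # mM
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


@dataclass
class SyntheticDatasetSpec:
    """Noise plus how many independent cultures are emulated."""

    noise: NoiseModel = field(default_factory=NoiseModel)
    independent_runs: int = 2
    biomass_jitter: float = 0.05   # ±5% on the starting biomass per culture


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative factors with mean exactly 1 and the requested CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def synthesize_measurements(true_samples: pd.DataFrame,
                            noise: NoiseModel) -> pd.DataFrame:
    """Turn noise-free sampled rows into a MeasurementTable.

    ``true_samples`` is a scenario sample table (wide: one row per sampling
    event, metabolite columns).  Per row and metabolite, ``replicates``
    noisy values are drawn; the reported level is their mean and the reported
    error their standard error.  Glucose gets one noisy determination per
    sampling event and LOQ censoring.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(noise.seed)
    rows = []
    mets = [m for m in MEASURED_METABOLITES if m in true_samples.columns]
    if not mets:
        raise ConfigurationError("no metabolite columns in the sample table")
    for _, r in true_samples.iterrows():
        g = float(r["glucose_mM"]) * _lognormal_factors(rng, noise.cv, ())
        g = float(g) if g >= noise.glucose_loq else noise.glucose_loq / 2.0
        for met in mets:
            draws = r[met] * _lognormal_factors(rng, noise.cv, noise.replicates)
            level = float(np.mean(draws))
            sem = float(np.std(draws, ddof=1) / np.sqrt(noise.replicates)) \
                if noise.replicates > 1 else 0.0
            rows.append({"regime": r["regime"], "time_h": r["time_h"],
                         "temperature_C": r["temperature_C"], "glucose_mM": g,
                         "metabolite": met, "level": level, "sem": sem,
                         "n": noise.replicates})
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def synthesize_from_cultures(culture_samples: list[pd.DataFrame],
                             noise: NoiseModel) -> pd.DataFrame:
    """Pool measurements from independent cultures (distinct noise streams
    derived from the base seed)."""
    tables = []
    for k, samples in enumerate(culture_samples):
        tables.append(synthesize_measurements(
            samples, replace(noise, seed=noise.seed + 7919 * (k + 1))))
    return pd.concat(tables, ignore_index=True)


def simulate_culture_pair(model, spec, params, config,
                          dataset: SyntheticDatasetSpec,
                          rtol: float = 1e-8, atol: float = 1e-10
                          ) -> list[pd.DataFrame]:
    """Re-simulate a scenario once per independent culture with jittered
    initial biomass (±``biomass_jitter``), mirroring how duplicate cultures
    differ in practice."""
    from .scenarios import run_scenario

    rng = np.random.default_rng(dataset.noise.seed)
    out = []
    for _ in range(dataset.independent_runs):
        factor = 1.0 + rng.uniform(-dataset.biomass_jitter, dataset.biomass_jitter)
        res: ScenarioResult = run_scenario(model, spec, params, config,
                                           rtol=rtol, atol=atol,
                                           initial_biomass_factor=factor)
        out.append(res.samples)
    return out


FIXTURE_CASES = ("collapsed", "offset_regime", "deviant_enzyme_pattern")


def make_fixture(case: str, seed: int = 0) -> pd.DataFrame:
    """Small deterministic MeasurementTables with known ground truth.

    collapsed              — two regimes on one saturating curve, no noise.
    offset_regime          — regime B sits at 1.5× the regime-A curve.
    deviant_enzyme_pattern — upstream metabolites (G6P…TRIO) carry the offset
                             in regime B, downstream ones (PEP, PYR) collapse;
                             the implied boundary is the TRIO-consuming step.
    """
    if case not in FIXTURE_CASES:
        raise ConfigurationError(f"unknown fixture case {case!r}")
    rng = np.random.default_rng(seed)
    n_glc = 5 if case == "deviant_enzyme_pattern" else 10   # keeps tables <= 60 rows
    glucose = np.geomspace(0.05, 50.0, n_glc)
    curve = lambda s: 8.0 * s / (2.0 + s)          # saturating mM response

    def block(regime, mets, factor):
        rows = []
        for s in glucose:
            temp = float(rng.uniform(12.0, 30.0))
            for met in mets:
                rows.append({"regime": regime, "time_h": 0.0,
                             "temperature_C": temp, "glucose_mM": float(s),
                             "metabolite": met,
                             "level": factor * curve(s), "sem": 0.0, "n": 2})
        return rows

    if case == "collapsed":
        rows = block("A", ["M1"], 1.0) + block("B", ["M1"], 1.0)
    elif case == "offset_regime":
        # regime A dominates the pooled fit (3 duplicate series), so only the
        # offset regime B exceeds the default threshold:
        # fit = 1.125·curve → |r| is 1/9 for A and 1/3 for B
        rows = (block("A", ["M1"], 1.0) + block("A", ["M1"], 1.0)
                + block("A", ["M1"], 1.0) + block("B", ["M1"], 1.5))
    else:
        upstream = ["G6P", "F6P", "FBP", "TRIO"]
        downstream = ["PEP", "PYR"]
        rows = (block("A", upstream + downstream, 1.0)
                + block("B", upstream, 1.6) + block("B", downstream, 1.0))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
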