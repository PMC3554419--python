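#!/usr/bin/env python
"""The two in-silico rounds across the three temperature regimes.

Round A ('identical'): every enzyme shares the normalized Ratkowsky capacity
function.  Round B ('single_enzyme_different'): the lumped TDH step is made
two-fold less temperature-sensitive (PFK and PYK variants are also written).
Each round covers sequential batches at 12/18/24/30 °C (SBR), a 3-h linear
temperature shift on a 30 °C chemostat (LTS30), and two circadian cycles of a
sinusoidal profile (CTC), sampled as in the measurement campaign.  Writes the
normalized metabolite tables (results/figure2_*.csv) and example chemostat
trajectories.
"""

import pandas as pd

from glycotherm import (RatkowskyParams, ReactorConfig, SensitivitySpec,
                        load_packaged_model)
from glycotherm.runconfig import write_table
from glycotherm.scenarios import MEASURED_METABOLITES, ScenarioSpec, run_round, \
    run_scenario


def main():
    model = load_packaged_model()
    params = RatkowskyParams()
    config = ReactorConfig()

    tables = {"identical": run_round(model, "identical", params, config)}
    for enzyme in ("TDHL", "PFK", "PYK"):
        tables[f"perturbed_{enzyme}"] = run_round(
            model, "single_enzyme_different", params, config,
            sensitivity=SensitivitySpec(enzyme, 2.0))

    for name, tab in tables.items():
        write_table(tab, f"results/figure2_{name.lower()}.csv")

    keep = ["time_h", "temperature_C", "GLCo", "biomass_gdw_l", "mu_h",
            "q_CO2"] + MEASURED_METABOLITES
    ctc = run_scenario(model, ScenarioSpec(regime="CTC"), params, config)
    write_table(ctc.trajectories["CTC"].data[keep].iloc[::10],
                "results/trajectory_ctc.csv")
    lts = run_scenario(model, ScenarioSpec(regime="LTS30"), params, config)
    write_table(lts.trajectories["LTS30"].data[keep].iloc[::2],
                "results/trajectory_lts30.csv")

    ident = tables["identical"]
    sbr = ident[ident["regime"].str.startswith("SBR")]
    spread = max(
        float(sbr[sbr["sample_index"] == i][f"norm_{m}"].max()
              / sbr[sbr["sample_index"] == i][f"norm_{m}"].min() - 1.0)
        for m in MEASURED_METABOLITES for i in sbr["sample_index"].unique())
    print(f"Identical sensitivities: batch metabolite levels are temperature-"
          f"independent (worst spread across 12-30 C at matched sampling "
          f"positions: {spread * 100:.2f}%).")

    pert = tables["perturbed_TDHL"]
    sbr12 = pert[(pert["regime"] == "SBR12") & (pert["sample_index"] == 0)]
    norms = {m: float(sbr12[f"norm_{m}"].iloc[0]) for m in MEASURED_METABOLITES}
    print("TDH-lump 2x less sensitive, 12 C batch vs 30 C reference "
          "(normalized levels):")
    print("  " + "  ".join(f"{m}={v:.2f}" for m, v in norms.items()))
    print("  -> only metabolites upstream of the perturbed step deviate; "
          "PEP and PYR remain at their 30 C values.")

    glc = ctc.trajectories["CTC"].data
    print(f"CTC chemostat: residual glucose oscillates "
          f"{glc['GLCo'].min():.2f}-{glc['GLCo'].max():.2f} mM in antiphase "
          "with the 12-30 C temperature cycle (transport capacity falls when "
          "it cools), while the dilution rate pins the average flux.")


if __name__ == "__main__":
    main()
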