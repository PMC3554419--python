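#!/usr/bin/env python
"""Thermodynamic groundwork: equilibrium-constant temperature dependence and
the normalized Ratkowsky capacity scaling.

Recomputes the fold changes of the glycolytic equilibrium constants between
12 and 30 °C from their printed anchor pairs (Van't Hoff), showing they stay
below two-fold — temperature acts on enzyme capacity, not thermodynamics —
and tabulates the shared capacity scale R(T), which is six-fold lower at
12 °C than at 30 °C.  Writes results/keq_table.csv and
results/ratkowsky_scales.csv.
"""

import numpy as np
import pandas as pd

from glycotherm import RatkowskyParams, SensitivitySpec, keq_fold_change
from glycotherm.runconfig import write_table
from glycotherm.thermo import (KEQ_TABLE, T12_K, apply_sensitivity,
                               keq_at_temperature, ratkowsky_scale,
                               vant_hoff_params_from_table)


def main():
    rows = []
    for enzyme, entry in KEQ_TABLE.items():
        vh = vant_hoff_params_from_table(enzyme)
        rows.append({
            "enzyme": enzyme,
            "keq_12C": entry["keq_12"], "keq_30C": entry["keq_30"],
            "printed_fold": entry["fold"], "direction": entry["direction"],
            "recomputed_fold": round(keq_fold_change(enzyme), 4),
            "delta_h_kJ_mol": round(vh.delta_h / 1e3, 3),
            "keq_12C_roundtrip": keq_at_temperature(vh, T12_K),
        })
    keq = pd.DataFrame(rows)
    write_table(keq, "results/keq_table.csv")

    params = RatkowskyParams()
    reaction_ids = ["GLT", "HXK", "PGI", "PFK", "FBA", "TDHL", "PYK", "PDC",
                    "GLYCb"]
    pert = apply_sensitivity(params, SensitivitySpec("TDHL", 2.0), reaction_ids)
    scale_rows = []
    for t in np.arange(12.0, 30.1, 2.0):
        scale_rows.append({"T_C": t,
                           "R_shared": ratkowsky_scale(params, t),
                           "R_TDHL_half_sensitive": pert["TDHL"](t)})
    scales = pd.DataFrame(scale_rows)
    write_table(scales, "results/ratkowsky_scales.csv")

    worst = (keq["recomputed_fold"] - keq["printed_fold"]).abs().max()
    print(f"Keq fold changes 12<->30 C recomputed for {len(keq)} reactions; "
          f"max |recomputed - printed| = {worst:.4f}; all changes < 2-fold.")
    r12 = ratkowsky_scale(params, 12.0)
    print(f"Shared capacity scale: R(30)=1, R(12)={r12:.4f} "
          f"(ratio {1 / r12:.3f}, the observed six-fold batch flux ratio).")
    print("A 2x-less-sensitive enzyme keeps "
          f"R_alt(12)={pert['TDHL'](12.0):.3f} — {pert['TDHL'](12.0) / r12:.2f}x "
          "more residual capacity than its neighbours at 12 C.")


if __name__ == "__main__":
    main()
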