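#!/usr/bin/env python
"""Power and specificity of the collapse pipeline on noisy synthetic data.

Emulates the measurement campaign (duplicate samples, two independent
cultures with jittered inocula, 10% multiplicative CV) on the glucose-excess
batches, then asks over 50 noise seeds per condition: is the perturbed enzyme
recovered, is anything falsely flagged under identical sensitivities, and
does the permutation test for residual temperature dependence hold its size?
Writes results/recovery_summary.csv.
"""

import argparse

import pandas as pd

from glycotherm import RatkowskyParams, ReactorConfig, load_packaged_model
from glycotherm.runconfig import write_table
from glycotherm.study import localization_study, permutation_type1_error


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=101)
    ap.add_argument("--n-seeds", type=int, default=50)
    args = ap.parse_args()

    model = load_packaged_model()
    params = RatkowskyParams()
    config = ReactorConfig()

    rows = []
    for target in ("TDHL", "PYK", "PFK", None):
        res = localization_study(model, params, config, target,
                                 n_seeds=args.n_seeds, base_seed=args.seed)
        rows.append({"condition": target or "identical",
                     "n_seeds": res.n_seeds,
                     "recovered": res.recovered,
                     "recovery_rate": res.recovery_rate,
                     "flagged_any": res.flagged_any,
                     "downstream_calls": res.downstream_calls})
        if target is None:
            print(f"identical sensitivities: {res.flagged_any}/{res.n_seeds} "
                  "replicates raise any flag (false-flag rate "
                  f"{res.false_flag_rate:.2f}).")
        else:
            print(f"{target} 2x less sensitive: recovered in "
                  f"{res.recovered}/{res.n_seeds} replicates "
                  f"({res.recovery_rate:.0%}); {res.downstream_calls} calls "
                  "downstream of the true step.")

    t1 = permutation_type1_error(n_tables=500, alpha=0.05,
                                 n_permutations=1000, base_seed=args.seed)
    rows.append({"condition": "permutation_type1_at_0.05", "n_seeds": 500,
                 "recovered": None, "recovery_rate": t1,
                 "flagged_any": None, "downstream_calls": None})
    print(f"Permutation test size at alpha = 0.05: {t1:.3f} "
          "(500 synthetic null tables).")

    write_table(pd.DataFrame(rows), "results/recovery_summary.csv")


if __name__ == "__main__":
    main()
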