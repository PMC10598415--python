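#!/usr/bin/env python
"""Prepare the scores and estimate twin / CTCT correlations.

Applies the study's preparation chain (log(1+x), residualize on sex and
birth year, standardize), persists the prepared tables, runs the
saturated-model equality assumption tests, and tabulates per-zygosity
twin and cross-twin cross-trait correlations with 95% profile CIs.
"""

import pandas as pd

from common import COHORTS, PREPARED, TABLES, TRAITS, cohort_map, ensure_dirs
from twinace.data_io import read_pairs_csv, write_pairs_csv
from twinace.pipeline import prepare_cohort
from twinace.saturated import bivariate_correlation_table, test_equality


def main() -> None:
    ensure_dirs()
    frames = []
    for trait in TRAITS:
        cohort = read_pairs_csv(COHORTS / f"{trait}.csv", cohort_map(trait))
        prepared = prepare_cohort(cohort)
        write_pairs_csv(prepared, PREPARED / f"{trait}.csv")
        if trait == TRAITS[0]:
            print("assumption tests (synaesthesia):")
            for which in ("order_means", "order_variances",
                          "zygosity_means", "zygosity_variances"):
                mc = test_equality(prepared, which, traits="synaesthesia")
                print(f"  {which}: delta -2lnL = {mc.delta_minus2ll:.2f}, "
                      f"df = {mc.delta_df}, p = {mc.p_value:.3f}")
        tbl = bivariate_correlation_table(prepared, ["synaesthesia", trait])
        tbl.insert(0, "trait_pair", f"synaesthesia x {trait}")
        frames.append(tbl)
    table = pd.concat(frames, ignore_index=True)
    print("\ntwin and CTCT correlations (constrained saturated models):")
    print(table.round(3).to_string(index=False))
    table.to_csv(TABLES / "correlations.csv", index=False)


if __name__ == "__main__":
    main()
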