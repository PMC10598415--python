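#!/usr/bin/env python
"""Univariate variance decomposition of the synaesthesia score.

Fits ACE and its nested AE / CE / E submodels to the prepared score,
compares them by likelihood ratio against ACE, and reports the
standardized components with 95% profile CIs for the selected model.
"""

import pandas as pd

from common import PREPARED, TABLES, TRAITS, cohort_map, ensure_dirs
from twinace.biometric import compare_nested, fit_univariate
from twinace.data_io import read_pairs_csv


def main() -> None:
    ensure_dirs()
    cohort = read_pairs_csv(PREPARED / f"{TRAITS[0]}.csv",
                            cohort_map(TRAITS[0]))
    fits = {m: fit_univariate(cohort, "synaesthesia", model=m,
                              ci=("A", "C", "E") if m in ("ACE", "AE") else ())
            for m in ("ACE", "AE", "CE", "E")}
    comp_rows = []
    for nested in ("AE", "CE", "E"):
        c = compare_nested(fits["ACE"], fits[nested])
        comp_rows.append({"nested": nested,
                          "delta_minus2ll": c.delta_minus2ll,
                          "delta_df": c.delta_df, "p": c.p_value,
                          "p_boundary": c.p_value_boundary})
    comparisons = pd.DataFrame(comp_rows)
    print("model comparisons against ACE:")
    print(comparisons.round(4).to_string(index=False))

    keep = comparisons.loc[comparisons.p >= 0.05, "nested"].tolist()
    order = {"E": 0, "CE": 1, "AE": 2}
    selected = min(keep, key=order.get) if keep else "ACE"
    fit = fits[selected]
    print(f"\nselected model: {selected}")
    rows = []
    for q in ("A", "C", "E"):
        if q in fit.ci95:
            lo, hi = fit.ci95[q]
            val = getattr(fit.params, q)
            rows.append({"component": q, "estimate": val,
                         "lo95": lo, "hi95": hi})
            print(f"  {q} = {100 * val:.0f}% "
                  f"(95% CI {100 * lo:.0f}-{100 * hi:.0f}%)")
    pd.DataFrame(rows).to_csv(TABLES / "univariate_components.csv",
                              index=False)
    comparisons.to_csv(TABLES / "univariate_comparisons.csv", index=False)


if __name__ == "__main__":
    main()
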