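#!/usr/bin/env python
"""Statistics stage: contrasts, correlations and regressions on the cohort.

Re-derives the group statistics from the measured cohort table produced by
02_cohort_pipeline.py (run that first): the group contrast table, pooled and
per-group Spearman correlation of choroid plexus perfusion against the
suprasellar decay rate, and the separate cohort/age/sex regressions. Writes
results/03_statistics/.
"""
import os

import pandas as pd

from csfmotion import cohort_report, covariate_regression

IN = os.path.join(os.path.dirname(__file__), "..", "results", "02_pipeline",
                  "cohort_table.csv")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "03_statistics")


def main():
    if not os.path.exists(IN):
        raise SystemExit(f"{IN} missing - run analysis/02_cohort_pipeline.py first")
    os.makedirs(OUT, exist_ok=True)
    table = pd.read_csv(IN)

    report, text = cohort_report(table, stratified_correlation=True)
    report.to_csv(os.path.join(OUT, "cohort_report.csv"), index=False)
    print(text)

    sub = table.dropna(subset=["D_suprasellar_csf"])
    reg = covariate_regression(sub["D_suprasellar_csf"],
                               sub[["group", "age", "sex"]], combined=True)
    reg.to_csv(os.path.join(OUT, "regressions.csv"), index=False)
    print("\nSeparate (and combined) regressions of suprasellar decay rate:")
    print(reg.to_string(index=False))

    pd_grp = sub[sub["group"] == "pd"].dropna(subset=["updrs"])
    if len(pd_grp) > 4:
        print("\nExploratory: UPDRS and MoCA on decay rate (PD group only):")
        for score in ("updrs", "moca"):
            r = covariate_regression(pd_grp[score], pd_grp[["D_suprasellar_csf"]])
            row = r.iloc[0]
            print(f"  {score}: slope {row['coef']:.3g}, p = {row['p_value']:.3f}")


if __name__ == "__main__":
    main()
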