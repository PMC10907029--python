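#!/usr/bin/env python
"""Group-level statistics on the analyzed cohort.

Reads results/cohort_results.csv and computes the full report: mixed
phase-by-group ANOVAs for every per-phase MSNA metric, omnibus group
comparisons of the resting and change variables, proportions of
subjects with significant positive MSNA-pressure coupling, and the
correlations between respiratory sympathetic modulation and resting
hemodynamics.  Writes one CSV per report table to results/.
"""

from pathlib import Path

import pandas as pd

from respsym.stats import cohort_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    cohort = pd.read_csv(results / "cohort_results.csv")
    tables = cohort_report(cohort)
    for name, df in tables.items():
        df.to_csv(results / f"group_{name}.csv", index=False)

    anova = tables["anova"].set_index(["metric", "effect"])
    inter = anova.loc[("incidence", "interaction")]
    phase = anova.loc[("incidence", "phase")]
    print("burst incidence, mixed phase-by-group ANOVA:")
    print(f"  phase effect       F({phase['df1']:.0f},{phase['df2']:.0f}) = "
          f"{phase['F']:.2f}, p = {phase['p']:.2g}, partial eta2 = {phase['np2']:.2f}")
    print(f"  phase x group      F({inter['df1']:.0f},{inter['df2']:.0f}) = "
          f"{inter['F']:.2f}, p = {inter['p']:.2g}, partial eta2 = {inter['np2']:.2f}")
    print("\ngroup comparisons (auto test choice):")
    print(tables["comparisons"].round(4).to_string(index=False))
    corr = tables["correlations"]
    print("\nmodulation vs resting hemodynamics (coef, p):")
    print(corr[corr.scope.isin(["all", "postmenopausal_female"])]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
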