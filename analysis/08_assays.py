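#!/usr/bin/env python
"""Derived assays: TEER per unit area, ΔΔCt fold changes, group tests.

Closes the analysis with the non-imaging quantities: barrier integrity
from transwell resistance readings, double-normalized qPCR fold changes
recovered from a synthetic Ct table with known folds, and the delegated
nonparametric group comparisons.  Tables under results/assays/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gastruloid_quant.assays import (TEERRecord, compare_groups,
                                     qpcr_fold_change, teer_unit_area)

OUT = Path(__file__).resolve().parents[1] / "results" / "assays"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    teer = [teer_unit_area(TEERRecord(s, 300.0, 0.33))["teer_ohm_cm2"]
            for s in (1500.0, 1450.0, 900.0)]
    pd.DataFrame({"sample_ohm": [1500.0, 1450.0, 900.0],
                  "teer_ohm_cm2": teer}).to_csv(OUT / "teer.csv",
                                                index=False)
    print("TEER (Ω·cm²):", [round(t, 1) for t in teer],
          "— the low value mimics the barrier-compromised genotype")

    folds = {"LEFTY1": 2.0, "EOMES": 8.0, "CER1": 1.0}
    rows = []
    for cond, on in (("baseline", False), ("stimulated", True)):
        for clone in range(3):
            for rep in range(4):
                rows.append({"sample": f"{cond}_c{clone}", "gene": "GAPDH",
                             "condition": cond, "timepoint": 0.0,
                             "Ct": 18.0 + rng.normal(0, 0.2),
                             "replicate": rep})
                for gene, fold in folds.items():
                    ct = 26.0 - (np.log2(fold) if on else 0.0)
                    rows.append({"sample": f"{cond}_c{clone}", "gene": gene,
                                 "condition": cond, "timepoint": 0.0,
                                 "Ct": ct + rng.normal(0, 0.2),
                                 "replicate": rep})
    out = qpcr_fold_change(pd.DataFrame(rows), "GAPDH", ("baseline", 0.0))
    out.to_csv(OUT / "qpcr_folds.csv", index=False)
    stim = out.loc[out["condition"] == "stimulated"].set_index("gene")
    for gene, fold in folds.items():
        print(f"qPCR {gene}: recovered fold "
              f"{stim.loc[gene, 'fold_mean']:.2f} (truth {fold})")

    groups = {"20CAG": rng.normal(1.0, 0.2, 20),
              "56CAG": rng.normal(1.6, 0.2, 20),
              "KO": rng.normal(1.7, 0.2, 20)}
    stats = compare_groups(groups)
    stats.to_csv(OUT / "group_comparison.csv", index=False)
    kw = stats.loc[stats["test"] == "kruskal-wallis"].iloc[0]
    print(f"Kruskal-Wallis H={kw['statistic']:.1f}, p={kw['p_value']:.2e}; "
          f"{(stats['test'] == 'posthoc-mann-whitney').sum()} post-hoc pairs")


if __name__ == "__main__":
    main()
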