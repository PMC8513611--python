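"""Derived assay calculations and group-comparison delegation.

TEER (transepithelial electrical resistance) per unit membrane area,
ΔΔCt fold changes for RT-qPCR with double normalization (reference gene,
then pre-stimulus baseline condition), and a thin delegation layer over
standard two-group / multi-group nonparametric tests.  No bespoke
statistics are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TEERRecord",
    "teer_unit_area",
    "qpcr_fold_change",
    "compare_groups",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TEERRecord:
    """One TEER measurement against a no-cell (laminin-only) control well."""

    sample_ohm: float
    control_ohm: float
    membrane_area_cm2: float

    def __post_init__(self):
        if self.membrane_area_cm2 <= 0:
            raise ValueError("membrane area must be positive")


def teer_unit_area(rec: TEERRecord) -> dict:
    """Tissue resistance per unit area: (sample − control) × area, Ω·cm².

    A sample below the no-cell control indicates a measurement problem;
    the value is still returned, flagged with a warning.
    """
    value = (rec.sample_ohm - rec.control_ohm) * rec.membrane_area_cm2
    warning = rec.sample_ohm < rec.control_ohm
    if warning:
        log.warning("sample resistance below control; TEER flagged")
    return {"teer_ohm_cm2": float(value), "warning": bool(warning)}


def qpcr_fold_change(table: pd.DataFrame, reference_gene: str,
                     baseline: tuple) -> pd.DataFrame:
    """ΔΔCt fold changes with replicate sd propagated on the log2 scale.

    ``table`` columns: sample, gene, condition, timepoint, Ct, replicate.
    Per sample, ΔCt = Ct(gene) − Ct(reference gene); replicate Ct values
    are averaged first (Ct-first aggregation).  ΔΔCt subtracts the mean
    ΔCt of the ``baseline`` (condition, timepoint) for the same gene, and
    fold = 2^(−ΔΔCt) (efficiency-2 arithmetic).  Samples lacking the
    reference gene are dropped (logged).  Baseline rows must exist for
    every gene.
    """
    required = {"sample", "gene", "condition", "timepoint", "Ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if (table["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    # mean Ct over technical replicates, per sample x gene
    ct = (table.groupby(["sample", "condition", "timepoint", "gene"],
                        as_index=False)["Ct"].mean())
    ref = ct.loc[ct["gene"] == reference_gene,
                 ["sample", "Ct"]].rename(columns={"Ct": "Ct_ref"})
    genes = ct.loc[ct["gene"] != reference_gene]
    merged = genes.merge(ref, on="sample", how="left")
    dropped = merged["Ct_ref"].isna()
    if dropped.any():
        log.warning("dropping %d sample/gene rows lacking the reference gene",
                    int(dropped.sum()))
        merged = merged.loc[~dropped]
    merged = merged.assign(dCt=merged["Ct"] - merged["Ct_ref"])

    cond0, t0 = baseline
    base = merged.loc[(merged["condition"] == cond0)
                      & (merged["timepoint"] == t0)]
    base_means = base.groupby("gene")["dCt"].mean()
    missing_genes = set(merged["gene"]) - set(base_means.index)
    if missing_genes:
        raise ValueError(f"no baseline rows for genes: {sorted(missing_genes)}")

    merged = merged.assign(
        ddCt=merged["dCt"] - merged["gene"].map(base_means),
    )
    merged = merged.assign(fold=2.0 ** (-merged["ddCt"]))

    out = (merged.groupby(["gene", "condition", "timepoint"])
           .agg(fold_mean=("fold", lambda f: 2.0 ** np.mean(np.log2(f))),
                log2_sd=("ddCt", lambda d: np.std(d, ddof=1) if len(d) > 1
                         else np.nan),
                n=("fold", "size"))
           .reset_index())
    # sd back-propagated to the fold scale as a multiplicative factor
    out["fold_sd_factor"] = 2.0 ** out["log2_sd"]
    return out


def compare_groups(values_by_group: dict, design: str = "auto") -> pd.DataFrame:
    """Delegated nonparametric group comparison.

    Two groups → two-sided Mann-Whitney rank-sum test; three or more →
    Kruskal-Wallis rank ANOVA followed by pairwise Mann-Whitney post-hoc
    tests with Holm correction.  Returns a tidy table of test rows plus
    per-group summaries.  Every group needs n ≥ 3.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in names]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, g in zip(names, groups):
        if g.size < 3:
            raise ValueError(f"group {name!r} has n < 3")
    if design == "auto":
        design = "two-group" if len(groups) == 2 else "multi-group"

    rows = []
    if design == "two-group":
        stat, p = stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided")
        rows.append({"test": "mann-whitney", "group_a": names[0],
                     "group_b": names[1], "statistic": float(stat),
                     "p_value": float(p), "p_adjusted": float(p)})
    elif design == "multi-group":
        stat, p = stats.kruskal(*groups)
        rows.append({"test": "kruskal-wallis", "group_a": "all",
                     "group_b": "", "statistic": float(stat),
                     "p_value": float(p), "p_adjusted": float(p)})
        pair_rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                s, pv = stats.mannwhitneyu(groups[i], groups[j],
                                           alternative="two-sided")
                pair_rows.append({"test": "posthoc-mann-whitney",
                                  "group_a": names[i], "group_b": names[j],
                                  "statistic": float(s), "p_value": float(pv)})
        adj = multipletests([r["p_value"] for r in pair_rows],
                            method="holm")[1]
        for r, pa in zip(pair_rows, adj):
            r["p_adjusted"] = float(pa)
        rows.extend(pair_rows)
    else:
        raise ValueError(f"unknown design {design!r}")

    result = pd.DataFrame(rows)
    summaries = pd.DataFrame([
        {"test": "summary", "group_a": name, "group_b": "",
         "statistic": float(np.median(g)), "p_value": np.nan,
         "p_adjusted": np.nan, "mean": float(g.mean()),
         "sd": float(g.std(ddof=1)), "n": int(g.size)}
        for name, g in zip(names, groups)
    ])
    return pd.concat([result, summaries], ignore_index=True)
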