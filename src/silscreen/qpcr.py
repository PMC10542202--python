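"""qPCR calculators used for hit validation.

Two small, exact computations: relative expression by the ddCt method
(target Ct normalised to ACT1 within each sample, then to the wild-type
genotype; fold change = 2**(-ddCt), i.e. perfect doubling efficiency), and
the nucleosome-scanning (NuSA) relative protection of tiled amplicons as a
ratio to the VCX1 control amplicon, which sits inside a well-positioned
nucleosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

QPCR_COLUMNS = ("sample_id", "genotype", "target", "replicate", "ct")


def delta_delta_ct(table: pd.DataFrame, target: str, *,
                   reference_gene: str = "ACT1",
                   reference_genotype: str = "WT",
                   efficiency: float = 2.0) -> pd.DataFrame:
    """Relative expression of ``target`` per genotype by the ddCt method.

    For each replicate, dCt = Ct(target) - Ct(reference_gene); per genotype,
    ddCt = mean dCt(genotype) - mean dCt(reference_genotype) and fold change
    = efficiency**(-ddCt) (the reference genotype is exactly 1 by
    construction).  ``fold_sd`` is the sd of per-replicate fold changes and
    ``t_p`` a two-sided two-sample t-test of the genotype's dCt values
    against the reference genotype's.
    """
    missing = [c for c in ("genotype", "target", "replicate", "ct") if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    sub = table[table["target"].isin([target, reference_gene])]
    if reference_gene not in set(sub["target"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if target not in set(sub["target"]):
        raise ValueError(f"target {target!r} absent from table")
    genotypes = list(dict.fromkeys(sub["genotype"]))
    if reference_genotype not in genotypes:
        raise ValueError(f"reference genotype {reference_genotype!r} absent from table")
    if len(genotypes) < 2:
        raise ValueError("need at least one genotype besides the reference")

    wide = sub.pivot_table(index=["genotype", "replicate"], columns="target",
                           values="ct", aggfunc="mean")
    if wide[[target, reference_gene]].isna().any().any():
        raise ValueError("each (genotype, replicate) needs a Ct for target and reference gene")
    dct = (wide[target] - wide[reference_gene]).rename("delta_ct")
    ref_dct = dct.loc[reference_genotype].to_numpy(dtype=float)
    ref_mean = float(np.mean(ref_dct))

    rows = []
    for g in genotypes:
        d = dct.loc[g].to_numpy(dtype=float)
        ddct = float(np.mean(d)) - ref_mean
        folds = efficiency ** (-(d - ref_mean))
        if g == reference_genotype:
            ddct, fold = 0.0, 1.0
            t_p = np.nan
        else:
            fold = float(efficiency ** (-ddct))
            if len(d) > 1 and len(ref_dct) > 1 and (np.ptp(d) > 0 or np.ptp(ref_dct) > 0):
                t_p = float(stats.ttest_ind(d, ref_dct).pvalue)
            else:
                t_p = np.nan
        rows.append({"genotype": g, "target": target, "n_replicates": len(d),
                     "delta_ct_mean": float(np.mean(d)), "delta_delta_ct": ddct,
                     "fold_change": fold,
                     "fold_sd": float(np.std(folds, ddof=1)) if len(folds) > 1 else np.nan,
                     "t_p": t_p})
    return pd.DataFrame(rows)


def nusa_relative_protection(table: pd.DataFrame, *, control: str = "VCX1",
                             mode: str = "ct", value_column: str = "value") -> pd.DataFrame:
    """MNase protection of tiled amplicons relative to the control amplicon.

    ``table`` is long-format with columns ``amplicon_id``, ``midpoint``
    (bp relative to the ATG at +1), ``replicate`` and ``value`` holding Ct
    values (``mode='ct'``) or pre-quantified template amounts
    (``mode='quantity'``).  Per replicate, protection = Q/Q_control in
    quantity mode or 2**(Ct_control - Ct_query) in Ct mode (doubling
    efficiency assumed).  Returns per-amplicon mean, sd and replicate count,
    sorted by midpoint.
    """
    required = {"amplicon_id", "midpoint", "replicate", value_column}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"NuSA table missing columns: {sorted(missing)}")
    if mode not in ("ct", "quantity"):
        raise ValueError(f"unknown mode {mode!r}")
    ctrl = table[table["amplicon_id"] == control]
    if ctrl.empty:
        raise ValueError(f"control amplicon {control!r} absent from table")
    ctrl_by_rep = ctrl.set_index("replicate")[value_column]
    if mode == "quantity" and (ctrl_by_rep <= 0).any():
        raise ValueError("control quantity must be positive")

    query = table[table["amplicon_id"] != control].copy()
    ctrl_vals = query["replicate"].map(ctrl_by_rep)
    if ctrl_vals.isna().any():
        raise ValueError("every replicate needs a control measurement")
    if mode == "ct":
        query["relative_protection"] = 2.0 ** (ctrl_vals - query[value_column])
    else:
        query["relative_protection"] = query[value_column] / ctrl_vals

    out = (query.groupby(["amplicon_id", "midpoint"])["relative_protection"]
           .agg(relative_protection="mean",
                sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
                n_replicates="count")
           .reset_index()
           .sort_values("midpoint", kind="mergesort")
           .reset_index(drop=True))
    mids = out["midpoint"].to_numpy(dtype=float)
    if len(mids) > 1 and not (np.diff(mids) > 0).all():
        raise ValueError("amplicon midpoints must be strictly ordered along the locus")
    return out
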