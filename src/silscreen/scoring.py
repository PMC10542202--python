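"""Si-score computation, FDR hit calling and between-screen concordance.

The silencing score (Si) of a knockout strain is the ratio of the mean GFP
signal of its population to that of the co-cultured wild-type reference in
the same well.  Si > 1 means the deletion de-repressed the reporter
(diminished silencing); Si < 1 means increased silencing.  Means are
arithmetic on linear fluorescence; a geometric-mean option exists behind a
flag, and an optional autofluorescence background can be subtracted from both
means before taking the ratio.

Hit calling is deliberately pluggable (``method`` key): the default converts
log2 Si to robust z-scores against the screen median/MAD, computes two-sided
normal p-values and applies Benjamini–Hochberg, splitting calls by sign at
q <= fdr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cytometry import DemuxResult, EventTable, demultiplex, well_qc

#: Consistency scale factor making the MAD unbiased for a normal sd.
MAD_SCALE = 1.4826

CALL_DECREASED = "decreased_silencing"   # Si > 1, reporter de-repressed
CALL_INCREASED = "increased_silencing"   # Si < 1
CALL_NONE = "no_call"


class DegenerateScreenError(ValueError):
    """The screen's null spread cannot be estimated (MAD = 0)."""


@dataclass(frozen=True)
class SiScore:
    """Si score of one well."""

    si: float
    log2_si: float
    n_mutant: int
    n_reference: int


def si_score(mutant_gfp: np.ndarray, reference_gfp: np.ndarray,
             background: float = 0.0, *, geometric: bool = False) -> SiScore:
    """Ratio of mutant to reference mean GFP, optionally background-subtracted.

    ``background`` (default 0) is subtracted from both means before the
    ratio; it must sit below both means.  With ``geometric=True`` the means
    are geometric (computed on log signal; background must then be 0).
    """
    mutant_gfp = np.asarray(mutant_gfp, dtype=float)
    reference_gfp = np.asarray(reference_gfp, dtype=float)
    if mutant_gfp.size == 0 or reference_gfp.size == 0:
        raise ValueError("both populations must be nonempty")
    if geometric:
        if background != 0.0:
            raise ValueError("background subtraction is only defined for arithmetic means")
        m = float(np.exp(np.mean(np.log(mutant_gfp + 1.0))))
        r = float(np.exp(np.mean(np.log(reference_gfp + 1.0))))
    else:
        m = float(np.mean(mutant_gfp)) - background
        r = float(np.mean(reference_gfp)) - background
    if r <= 0.0 or m <= 0.0:
        raise ValueError("nonpositive population mean after background subtraction")
    si = m / r
    return SiScore(si=si, log2_si=math.log2(si),
                   n_mutant=mutant_gfp.size, n_reference=reference_gfp.size)


def score_screen(tables: Sequence[EventTable], strains, *,
                 demux_method: str = "log_ratio_threshold",
                 min_per_population: int = 1000, background: float = 0.0,
                 geometric: bool = False, n_bins: int = 10,
                 **demux_kwargs) -> pd.DataFrame:
    """Score every well of a screen into a ScreenTable DataFrame.

    ``strains`` is a sequence of objects with ``gene_id`` and ``locus_id``
    (e.g. ``StrainSpec``) aligned with ``tables``.  Wells failing QC get
    ``qc_pass=False`` and missing Si; ranks and deciles cover qc-passing
    strains only (rank 1 = lowest Si, ties broken by gene_id).
    """
    from .enrichment import decile_partition

    rows = []
    for table, strain in zip(tables, strains):
        rec = {"gene_id": strain.gene_id, "locus_id": strain.locus_id,
               "n_mutant": 0, "n_reference": 0, "si": np.nan, "log2_si": np.nan,
               "qc_pass": False}
        dm = demultiplex(table, demux_method, **demux_kwargs)
        qc = well_qc(dm, min_per_population)
        rec["n_mutant"], rec["n_reference"] = dm.n_mutant, dm.n_reference
        if qc.passed:
            gfp = table.channels["GFP"]
            s = si_score(gfp[dm.mutant_indices], gfp[dm.reference_indices],
                         background, geometric=geometric)
            rec.update(si=s.si, log2_si=s.log2_si, qc_pass=True)
        rows.append(rec)
    df = pd.DataFrame(rows)

    ok = df["qc_pass"].to_numpy()
    df["rank"] = pd.array([pd.NA] * len(df), dtype="Int64")
    if ok.any():
        sub = df.loc[ok, ["si", "gene_id"]].sort_values(["si", "gene_id"], kind="mergesort")
        df.loc[sub.index, "rank"] = np.arange(1, len(sub) + 1)
    if ok.sum() >= n_bins:
        df["decile"] = decile_partition(df, n_bins=n_bins)
    else:
        df["decile"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


#: Asymptotic relative efficiency of the MAD versus the sample sd for normal
#: data; sets the effective degrees of freedom of the scale estimate.
MAD_ARE = 0.37


def _robust_z_bh(log2_si: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Robust z against the screen median/MAD -> (z, BH-adjusted q).

    Tail probabilities come from a Student-t with 0.37*(n-1) effective
    degrees of freedom rather than a normal: the MAD is only ~37% efficient
    as a scale estimator, and ignoring its sampling noise makes the extreme
    z-scores that drive hit calling anti-conservative.
    """
    med = float(np.median(log2_si))
    mad = float(np.median(np.abs(log2_si - med)))
    if mad == 0.0:
        raise DegenerateScreenError("MAD of log2 Si is zero; cannot calibrate null")
    z = (log2_si - med) / (MAD_SCALE * mad)
    df = MAD_ARE * (log2_si.size - 1)
    p = 2.0 * stats.t.sf(np.abs(z), df)
    q = multipletests(p, method="fdr_bh")[1]
    return z, q


HIT_CALLERS: dict[str, Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]] = {
    "robust_z_bh": _robust_z_bh,
}


def call_hits(screen: pd.DataFrame, fdr: float = 0.10,
              method: str = "robust_z_bh", *, min_strains: int = 50) -> pd.DataFrame:
    """Two-sided FDR hit calls on a scored screen.

    Adds ``fdr_q`` and ``call`` columns (a copy is returned; hits only among
    qc-passing strains).  Calls are split by sign: ``decreased_silencing``
    requires Si > 1 and ``increased_silencing`` Si < 1 at q <= fdr.
    Input order does not influence the calls.
    """
    ok = screen["qc_pass"].to_numpy()
    if int(ok.sum()) < min_strains:
        raise ValueError(f"need >= {min_strains} qc-passing strains to estimate the null")
    out = screen.copy()
    out["fdr_q"] = np.nan
    out["call"] = CALL_NONE
    x = out.loc[ok, "log2_si"].to_numpy(dtype=float)
    z, q = HIT_CALLERS[method](x)
    out.loc[ok, "fdr_q"] = q
    if fdr > 0:
        si = out.loc[ok, "si"].to_numpy(dtype=float)
        hit = q <= fdr
        calls = np.where(hit & (z > 0) & (si > 1.0), CALL_DECREASED,
                         np.where(hit & (z < 0) & (si < 1.0), CALL_INCREASED, CALL_NONE))
        out.loc[ok, "call"] = calls
    return out


def screen_concordance(a: pd.DataFrame, b: pd.DataFrame, *, value: str = "si",
                       min_common: int = 10) -> dict:
    """Spearman rank correlation of Si between two screens on shared genes.

    Only strains qc-passing in both screens enter; ties are mid-ranked
    (scipy's default).
    """
    aa = a.loc[a["qc_pass"], ["gene_id", value]]
    bb = b.loc[b["qc_pass"], ["gene_id", value]]
    merged = aa.merge(bb, on="gene_id", suffixes=("_a", "_b"))
    if len(merged) < min_common:
        raise ValueError(f"need >= {min_common} shared qc-passing genes, got {len(merged)}")
    rho, p = stats.spearmanr(merged[f"{value}_a"], merged[f"{value}_b"])
    return {"n_common": int(len(merged)), "spearman_rho": float(rho), "p_value": float(p)}


def replicate_summary(replicates: pd.DataFrame) -> pd.DataFrame:
    """Aggregate technical replicates per strain.

    Expects long-format columns ``gene_id`` and ``log2_si``; returns per-gene
    mean log2 Si, sd, replicate count and the one-sample t-test p-value
    against 0 (the validation experiments' criterion of a significant GFP
    change vs the reference).
    """
    def agg(g: pd.Series) -> pd.Series:
        x = g.to_numpy(dtype=float)
        if x.size > 1 and np.ptp(x) > 0:
            t_p = float(stats.ttest_1samp(x, 0.0).pvalue)
        else:
            t_p = np.nan
        return pd.Series({"mean_log2_si": float(np.mean(x)),
                          "sd_log2_si": float(np.std(x, ddof=1)) if x.size > 1 else np.nan,
                          "n_replicates": x.size, "t_p": t_p})

    return replicates.groupby("gene_id")["log2_si"].apply(agg).unstack().reset_index()
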