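"""Decile partitioning of a screen and catalog enrichment tests.

A screen's qc-passing strains are ranked by Si score and cut into ten
near-equal bins (decile 1 = lowest Si).  For a curated catalog of known
silencing genes, each decile is tested for over-representation with a
one-sided hypergeometric tail at p < 0.05, uncorrected — one test per decile,
as screens of this kind conventionally display them.  Catalog genes absent
from the screen are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Catalog:
    """Curated set of known silencing genes with a provenance label each."""

    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("catalog must be nonempty")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.sources)

    @classmethod
    def from_genes(cls, genes: Iterable[str], source: str = "curation") -> "Catalog":
        return cls({g: source for g in genes})

    @classmethod
    def read_tsv(cls, path) -> "Catalog":
        df = pd.read_csv(path, sep="\t")
        if "source" in df.columns:
            return cls(dict(zip(df["gene_id"], df["source"])))
        return cls.from_genes(df["gene_id"])

    def write_tsv(self, path) -> None:
        pd.DataFrame({"gene_id": sorted(self.sources),
                      "source": [self.sources[g] for g in sorted(self.sources)]}
                     ).to_csv(path, sep="\t", index=False)


def _as_gene_set(catalog) -> frozenset[str]:
    return catalog.genes if isinstance(catalog, Catalog) else frozenset(catalog)


def decile_partition(screen: pd.DataFrame, n_bins: int = 10) -> pd.Series:
    """Decile labels (1 = lowest Si) for the qc-passing strains of a screen.

    Bin sizes differ by at most one (the lower deciles absorb the remainder);
    ties in Si are broken by gene_id so the partition is invariant under input
    shuffling.  Non-passing strains get NA.
    """
    ok = screen["qc_pass"].to_numpy(dtype=bool)
    n = int(ok.sum())
    if n < n_bins:
        raise ValueError(f"need >= {n_bins} qc-passing strains, got {n}")
    labels = pd.array([pd.NA] * len(screen), dtype="Int64")
    sub = screen.loc[ok, ["si", "gene_id"]].sort_values(["si", "gene_id"], kind="mergesort")
    chunks = np.array_split(np.asarray(sub.index), n_bins)
    pos = {idx: i for i, idx in enumerate(screen.index)}
    for d, chunk in enumerate(chunks, start=1):
        for idx in chunk:
            labels[pos[idx]] = d
    return pd.Series(labels, index=screen.index, name="decile")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-decile catalog enrichment plus the extreme-decile summary."""

    per_decile: pd.DataFrame
    extreme_fraction: float
    n_catalog_evaluated: int
    k_per_end: int


def _decile_table(screen: pd.DataFrame) -> pd.DataFrame:
    ok = screen["qc_pass"] & screen["decile"].notna()
    return screen.loc[ok, ["gene_id", "decile"]]


def decile_enrichment(screen: pd.DataFrame, catalog, *, alpha: float = 0.05,
                      k_per_end: int = 2, n_bins: int = 10) -> EnrichmentResult:
    """Hypergeometric enrichment of catalog genes per Si decile.

    For each decile the one-sided tail probability of observing at least the
    seen number of catalog genes, given decile size, screen size and the
    number of catalog genes evaluated in the screen.  ``enriched`` flags
    p < alpha with no multiplicity correction.
    """
    sub = _decile_table(screen)
    genes = _as_gene_set(catalog)
    in_cat = sub["gene_id"].isin(genes)
    n_screen = len(sub)
    n_cat = int(in_cat.sum())
    if n_cat == 0:
        raise ValueError("catalog does not intersect the screen")
    rows = []
    for d in range(1, n_bins + 1):
        mask = sub["decile"] == d
        n_d = int(mask.sum())
        k = int((mask & in_cat).sum())
        # P(X >= k) for X ~ Hypergeom(N=n_screen, K=n_cat, n=n_d)
        p = float(stats.hypergeom.sf(k - 1, n_screen, n_cat, n_d))
        rows.append({"decile": d, "n_in_decile": n_d, "n_catalog_in_decile": k,
                     "hypergeometric_p": p, "enriched": p < alpha})
    per_decile = pd.DataFrame(rows)
    frac = extreme_decile_fraction(screen, catalog, k_per_end=k_per_end, n_bins=n_bins)
    return EnrichmentResult(per_decile=per_decile, extreme_fraction=frac,
                            n_catalog_evaluated=n_cat, k_per_end=k_per_end)


def extreme_decile_fraction(screen: pd.DataFrame, catalog, *, k_per_end: int = 2,
                            n_bins: int = 10) -> float:
    """Fraction of evaluated catalog genes in the k outermost deciles per end.

    ``k_per_end=2`` reads "the two higher or lower deciles" as deciles
    {1, 2, 9, 10}; ``k_per_end=1`` as the single extreme decile at each end;
    0 gives 0 by construction.
    """
    if k_per_end < 0:
        raise ValueError("k_per_end must be >= 0")
    sub = _decile_table(screen)
    genes = _as_gene_set(catalog)
    cat = sub[sub["gene_id"].isin(genes)]
    if len(cat) == 0:
        raise ValueError("catalog does not intersect the screen")
    if k_per_end == 0:
        return 0.0
    low = cat["decile"] <= k_per_end
    high = cat["decile"] >= n_bins + 1 - k_per_end
    return float((low | high).mean())


def permutation_decile_pvalues(screen: pd.DataFrame, catalog, *, n_draws: int = 10000,
                               seed: int = 0, n_bins: int = 10) -> pd.DataFrame:
    """Permutation analogue of the per-decile hypergeometric test.

    Catalog membership is shuffled across the screen ``n_draws`` times; the
    reported p-value per decile is the fraction of draws with at least the
    observed catalog count (add-one estimator).  Serves as an independent
    check of the closed-form tail.
    """
    sub = _decile_table(screen)
    genes = _as_gene_set(catalog)
    in_cat = sub["gene_id"].isin(genes).to_numpy()
    n_cat = int(in_cat.sum())
    if n_cat == 0:
        raise ValueError("catalog does not intersect the screen")
    deciles = sub["decile"].to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    n = len(sub)
    counts = np.zeros((n_draws, n_bins), dtype=int)
    flat = np.zeros(n, dtype=bool)
    flat[:n_cat] = True
    for i in range(n_draws):
        perm = rng.permutation(flat)
        counts[i] = np.bincount(deciles[perm], minlength=n_bins + 1)[1:]
    rows = []
    for d in range(1, n_bins + 1):
        obs = int(in_cat[deciles == d].sum())
        exceed = int((counts[:, d - 1] >= obs).sum())
        rows.append({"decile": d, "n_catalog_in_decile": obs,
                     "permutation_p": (exceed + 1) / (n_draws + 1)})
    return pd.DataFrame(rows)


def plot_decile_bubbles(result: EnrichmentResult, path) -> None:
    """Bubble plot of catalog counts per decile (radius ~ count; gray = enriched)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.per_decile
    fig, ax = plt.subplots(figsize=(6, 2.2))
    sizes = 60.0 * df["n_catalog_in_decile"].to_numpy(dtype=float)
    colors = ["0.5" if e else "white" for e in df["enriched"]]
    ax.scatter(df["decile"], np.ones(len(df)), s=np.maximum(sizes, 5),
               c=colors, edgecolors="black")
    for _, r in df.iterrows():
        ax.annotate(str(int(r["n_catalog_in_decile"])), (r["decile"], 1.0),
                    ha="center", va="center", fontsize=7)
    ax.set_xticks(df["decile"])
    ax.set_yticks([])
    ax.set_xlabel("Si-score decile (1 = lowest Si)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
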