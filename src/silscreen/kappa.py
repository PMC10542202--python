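"""Cohen's-kappa functional clustering over a binary gene-by-term matrix.

Two genes that are annotated to similar sets of GO/phenotype terms get a high
chance-corrected agreement kappa = (Pr(a) - Pr(e)) / (1 - Pr(e)), where Pr(a)
is the fraction of terms on which the pair agrees (both annotated or both
not) and Pr(e) the agreement expected by chance from the two genes' marginal
annotation rates.  Pairs above a threshold (0.35, the top ~5% of kappa values
for matrices of this kind) are treated as functionally associated, seed
two-gene clusters, and clusters sharing more than half of their members are
merged iteratively to a fixpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AnnotationMatrix:
    """Binary m x n gene-by-term incidence matrix."""

    gene_ids: list[str]
    term_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 2 or bits.shape != (len(self.gene_ids), len(self.term_ids)):
            raise ValueError("bits must be an (n_genes, n_terms) matrix")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("entries must be 0/1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.term_ids)) != len(self.term_ids):
            raise ValueError("duplicate term ids")
        bits = bits.copy()
        bits.setflags(write=False)
        object.__setattr__(self, "bits", bits)

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        return len(self.term_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.gene_ids, columns=self.term_ids)

    @classmethod
    def read_tsv(cls, path) -> "AnnotationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(gene_ids=[str(g) for g in df.index],
                   term_ids=[str(t) for t in df.columns],
                   bits=df.to_numpy(dtype=np.uint8))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_triplets(cls, path) -> "AnnotationMatrix":
        """Sparse triplet TSV: columns gene_id, term_id (one row per 1-bit)."""
        df = pd.read_csv(path, sep="\t")
        genes = sorted(df["gene_id"].astype(str).unique())
        terms = sorted(df["term_id"].astype(str).unique())
        gi = {g: i for i, g in enumerate(genes)}
        ti = {t: j for j, t in enumerate(terms)}
        bits = np.zeros((len(genes), len(terms)), dtype=np.uint8)
        for g, t in zip(df["gene_id"].astype(str), df["term_id"].astype(str)):
            bits[gi[g], ti[t]] = 1
        return cls(gene_ids=genes, term_ids=terms, bits=bits)

    def write_triplets(self, path) -> None:
        gi, tj = np.nonzero(self.bits)
        pd.DataFrame({"gene_id": [self.gene_ids[i] for i in gi],
                      "term_id": [self.term_ids[j] for j in tj]}
                     ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class KappaEdge:
    """Agreement between one gene pair."""

    gene_a: str
    gene_b: str
    pr_a: float
    pr_e: float
    kappa: float


def cohen_kappa(row_a: Sequence[int], row_b: Sequence[int], *,
                gene_a: str = "a", gene_b: str = "b") -> KappaEdge:
    """Cohen's kappa between two equal-length binary annotation vectors.

    Pr(a) = (both-1 + both-0) / n; Pr(e) = p_a*p_b + (1-p_a)*(1-p_b).  When
    Pr(e) = 1 (two identical constant rows) kappa is undefined and reported
    as 0 with a warning — such pairs carry no discriminative annotation.
    """
    a = np.asarray(row_a, dtype=np.uint8)
    b = np.asarray(row_b, dtype=np.uint8)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("rows must be equal-length 1-D vectors of length >= 1")
    n = a.size
    both1 = int(np.sum((a == 1) & (b == 1)))
    both0 = int(np.sum((a == 0) & (b == 0)))
    pr_a = (both1 + both0) / n
    p_a, p_b = float(a.mean()), float(b.mean())
    pr_e = p_a * p_b + (1.0 - p_a) * (1.0 - p_b)
    if pr_e == 1.0:
        warnings.warn("Pr(e) = 1 (constant identical rows); kappa set to 0",
                      RuntimeWarning, stacklevel=2)
        kappa = 0.0
    else:
        kappa = (pr_a - pr_e) / (1.0 - pr_e)
    return KappaEdge(gene_a, gene_b, pr_a, pr_e, kappa)


def pairwise_kappa(matrix: AnnotationMatrix) -> np.ndarray:
    """Full m x m kappa matrix, vectorised through pairwise cell counts."""
    B = matrix.bits.astype(np.float64)
    n = matrix.n
    both1 = B @ B.T
    ann = B.sum(axis=1)
    both0 = n - (ann[:, None] + ann[None, :] - both1)
    pr_a = (both1 + both0) / n
    p = ann / n
    pr_e = np.outer(p, p) + np.outer(1.0 - p, 1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (pr_a - pr_e) / (1.0 - pr_e)
    degenerate = pr_e == 1.0
    if degenerate.any():
        kappa[degenerate] = 0.0
        off = degenerate.copy()
        np.fill_diagonal(off, False)
        if off.any():
            warnings.warn("some gene pairs have Pr(e) = 1; their kappa set to 0",
                          RuntimeWarning, stacklevel=2)
    return kappa


@dataclass(frozen=True)
class EdgeSet:
    """Retained association edges plus where the threshold sits empirically."""

    edges: list[KappaEdge]
    threshold: float
    threshold_quantile: float
    n_pairs: int


def build_association_edges(matrix: AnnotationMatrix, threshold: float = 0.35) -> EdgeSet:
    """Evaluate all gene pairs and keep those with kappa strictly above threshold.

    Also reports the empirical quantile of the threshold among all pairwise
    kappa values (the reference analysis chose 0.35 as the top ~5%).
    """
    if matrix.m < 2:
        raise ValueError("need at least two genes")
    K = pairwise_kappa(matrix)
    n = matrix.n
    B = matrix.bits.astype(np.float64)
    both1 = B @ B.T
    ann = B.sum(axis=1)
    both0 = n - (ann[:, None] + ann[None, :] - both1)
    pr_a = (both1 + both0) / n
    p = ann / n
    pr_e = np.outer(p, p) + np.outer(1.0 - p, 1.0 - p)
    iu = np.triu_indices(matrix.m, k=1)
    vals = K[iu]
    quantile = float(np.mean(vals <= threshold))
    edges = []
    for i, j, k in zip(iu[0], iu[1], vals):
        if k > threshold:
            edges.append(KappaEdge(matrix.gene_ids[i], matrix.gene_ids[j],
                                   float(pr_a[i, j]), float(pr_e[i, j]), float(k)))
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return EdgeSet(edges=edges, threshold=threshold, threshold_quantile=quantile,
                   n_pairs=vals.size)


@dataclass(frozen=True)
class MergeEvent:
    iteration: int
    cluster_a: tuple[str, ...]
    cluster_b: tuple[str, ...]
    shared_fraction: float


@dataclass(frozen=True)
class ClusterSet:
    """Final clusters, iteration count and a replayable merge log."""

    clusters: list[frozenset[str]]
    n_iterations: int
    merge_log: list[MergeEvent] = field(default_factory=list)


def iterative_cluster(edges: Sequence[KappaEdge], merge_share: float = 0.5, *,
                      rule: str = "member_share") -> ClusterSet:
    """Grow clusters from association-edge seeds by member-sharing merges.

    Each retained edge seeds a two-gene cluster.  Under the default
    ``member_share`` rule, a cluster whose members are covered by other
    clusters in a fraction strictly above ``merge_share`` is merged with
    every cluster it overlaps; the scan repeats to a fixpoint.  With pair
    seeds this is the only non-vacuous reading of "clusters sharing over
    half of their members are merged": a pairwise shared-over-smaller test
    can never exceed 1/2 between two-gene seeds, so a triangle of edges
    {A-B, A-C, B-C} collapses to {A,B,C} (every seed has both members
    shared) while a path {A-B, B-C} stays as two clusters (each seed shares
    only half its members).

    ``rule='pairwise_smaller'`` applies the literal pairwise test (shared
    count over the smaller cluster's size, strictly above ``merge_share``)
    for comparison.

    Clusters are scanned in lexicographic order of sorted member lists, so
    the result does not depend on edge input order.
    """
    if not edges:
        raise ValueError("edge list is empty")
    clusters = sorted({frozenset((e.gene_a, e.gene_b)) for e in edges},
                      key=lambda c: tuple(sorted(c)))
    log: list[MergeEvent] = []
    iteration = 0
    while True:
        iteration += 1
        merged_any = False
        clusters.sort(key=lambda c: tuple(sorted(c)))
        if rule == "member_share":
            i = 0
            while i < len(clusters):
                x = clusters[i]
                others = [c for j, c in enumerate(clusters) if j != i]
                covered = {g for c in others for g in c & x}
                share = len(covered) / len(x)
                if share > merge_share:
                    overlapping = [c for c in others if c & x]
                    merged = x.union(*overlapping)
                    for c in overlapping:
                        log.append(MergeEvent(iteration, tuple(sorted(x)),
                                              tuple(sorted(c)), share))
                    clusters = [c for c in clusters if c not in overlapping and c != x]
                    clusters.append(merged)
                    clusters.sort(key=lambda c: tuple(sorted(c)))
                    merged_any = True
                    i = 0
                else:
                    i += 1
        elif rule == "pairwise_smaller":
            i = 0
            while i < len(clusters):
                j = i + 1
                while j < len(clusters):
                    a, b = clusters[i], clusters[j]
                    share = len(a & b) / min(len(a), len(b))
                    if share > merge_share:
                        log.append(MergeEvent(iteration, tuple(sorted(a)),
                                              tuple(sorted(b)), share))
                        clusters[i] = a | b
                        del clusters[j]
                        merged_any = True
                        j = i + 1
                    else:
                        j += 1
                i += 1
        else:
            raise ValueError(f"unknown merge rule {rule!r}")
        clusters = sorted(set(clusters), key=lambda c: tuple(sorted(c)))
        if not merged_any:
            break
    clusters.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return ClusterSet(clusters=clusters, n_iterations=iteration, merge_log=log)


def cluster_ids(cluster_set: ClusterSet) -> dict[frozenset, int]:
    """Stable numeric ids: 1..K by decreasing size, then lexicographic."""
    return {c: i for i, c in enumerate(cluster_set.clusters, start=1)}


def export_network(cluster_set: ClusterSet, edges: Sequence[KappaEdge], path) -> None:
    """TSV edge list (gene_a, gene_b, kappa, cluster_id) for network tools.

    Each edge is tagged with the lowest-id cluster containing both endpoints;
    genes outside every cluster never appear (singletons are omitted).
    """
    ids = cluster_ids(cluster_set)
    rows = []
    for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b)):
        cid = min((i for c, i in ids.items() if e.gene_a in c and e.gene_b in c),
                  default=None)
        if cid is None:
            continue
        rows.append({"gene_a": e.gene_a, "gene_b": e.gene_b,
                     "kappa": e.kappa, "cluster_id": cid})
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "kappa", "cluster_id"]
                 ).to_csv(path, sep="\t", index=False)


def read_network(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
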