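"""Synthetic data generators for the silencing-screen pipeline.

Everything downstream of the flow cytometer is testable against data produced
here: single wells of co-cultured mutant/reference populations, whole screens
with known ground-truth effects, binary gene-by-term annotation matrices with
planted functional clusters, and qPCR Ct tables.

The variegated single-cell GFP signal at a silenced subtelomeric locus is
modelled as a two-component lognormal mixture: a fraction ``p_silenced`` of
cells sit in a low-expression ("off") state and the rest in an expressing
("on") state.  A gene deletion that weakens or strengthens silencing is
represented by a single number, the log2 change it causes in the linear-scale
mean of that mixture.  All channel intensities are generated and stored on
linear scale; log transforms are downstream choices.

Multiplicative measurement noise (coefficient of variation
``channel_noise_cv``) is a unit-mean lognormal factor.  Because a lognormal
times a lognormal is lognormal, the noise is folded analytically into each
component's (mu, sigma); this is exactly equivalent to drawing the factor
separately and keeps the closed-form component means exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cytometry import EventTable

LN10 = math.log(10.0)
LN2 = math.log(2.0)

__all__ = [
    "LocusModel",
    "StrainSpec",
    "GeneratorConfig",
    "EffectModel",
    "GroundTruth",
    "LOCUS_PRESETS",
    "simulate_well",
    "simulate_screen",
    "simulate_annotation_matrix",
    "simulate_qpcr",
    "layout_frame",
    "load_locus_presets",
    "dump_locus_presets",
]


@dataclass(frozen=True)
class LocusModel:
    """Variegated-expression model of one reporter locus.

    ``mu``/``sigma`` are location/scale of log10 fluorescence (arbitrary
    units) for the silenced ("off") and expressing ("on") states;
    ``autofluorescence_mu`` is the log10 background every cell emits in the
    GFP channel regardless of reporter state.
    """

    locus_id: str
    p_silenced: float
    mu_off: float
    sigma_off: float
    mu_on: float
    sigma_on: float
    autofluorescence_mu: float = 1.0
    autofluorescence_sigma: float = 0.10

    def __post_init__(self) -> None:
        vals = [self.p_silenced, self.mu_off, self.sigma_off, self.mu_on,
                self.sigma_on, self.autofluorescence_mu, self.autofluorescence_sigma]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("LocusModel parameters must be finite")
        if not 0.0 <= self.p_silenced <= 1.0:
            raise ValueError("p_silenced must be in [0, 1]")
        if not self.mu_off < self.mu_on:
            raise ValueError("mu_off must be below mu_on")
        if self.sigma_off <= 0 or self.sigma_on <= 0 or self.autofluorescence_sigma <= 0:
            raise ValueError("sigma parameters must be positive")

    def signal_mean(self, log2_effect: float = 0.0) -> float:
        """Closed-form linear-scale mean of the reporter mixture (no background)."""
        m_off = math.exp(self.mu_off * LN10 + 0.5 * (self.sigma_off * LN10) ** 2)
        m_on = math.exp(self.mu_on * LN10 + 0.5 * (self.sigma_on * LN10) ** 2)
        mix = self.p_silenced * m_off + (1.0 - self.p_silenced) * m_on
        return (2.0 ** log2_effect) * mix

    def mean_gfp(self, log2_effect: float = 0.0) -> float:
        """Closed-form linear-scale mean GFP, background included.

        Unit-mean measurement noise does not move means, so this is exact for
        any ``channel_noise_cv``.
        """
        bg = math.exp(self.autofluorescence_mu * LN10
                      + 0.5 * (self.autofluorescence_sigma * LN10) ** 2)
        return bg + self.signal_mean(log2_effect)


#: Illustrative presets spanning the silencing range seen across subtelomeres:
#: strong variegated silencing (COS12-like), weak silencing (YFR057W-like) and
#: an unsilenced internal control locus (CUP9 5' intergenic).  The study that
#: motivates them reports distributions but no fitted parameters, so these are
#: invented values chosen to reproduce the qualitative phenomenology.
LOCUS_PRESETS: dict[str, LocusModel] = {
    "COS12": LocusModel("COS12", p_silenced=0.85, mu_off=1.6, sigma_off=0.20,
                        mu_on=3.0, sigma_on=0.25),
    "YFR057W": LocusModel("YFR057W", p_silenced=0.45, mu_off=1.8, sigma_off=0.20,
                          mu_on=3.0, sigma_on=0.25),
    "CUP9-5prime": LocusModel("CUP9-5prime", p_silenced=0.05, mu_off=1.8,
                              sigma_off=0.20, mu_on=3.2, sigma_on=0.25),
}


@dataclass(frozen=True)
class StrainSpec:
    """One screened strain: a gene deletion with a known true effect.

    The screen's labelling convention is fixed: knockout mutants carry the
    constitutive RFP (mCherry) marker, the co-cultured wild-type reference
    carries BFP.
    """

    gene_id: str
    true_log2_effect: float = 0.0
    label_channel: str = "RFP"
    locus_id: str = "COS12"

    def __post_init__(self) -> None:
        if self.label_channel not in ("RFP", "BFP"):
            raise ValueError("label_channel must be 'RFP' or 'BFP'")
        if not math.isfinite(self.true_log2_effect):
            raise ValueError("true_log2_effect must be finite")


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition-scale knobs for a simulated well.

    Defaults mirror the screen's acquisition contract: the cytometer stops at
    15,000 events per well, i.e. 7,500 per population at even mixing.  Marker
    log10 levels give a 10x separation between the constitutive BFP/RFP
    channels of the two populations; ``spillover`` mixes the observed BFP/RFP
    channels (rows: observed BFP, observed RFP; identity = no cross-talk).
    """

    n_events_per_population: int = 7500
    mixing_fraction: float = 0.5
    seed: int = 0
    channel_noise_cv: float = 0.05
    spillover: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    marker_mu_high: float = 3.0
    marker_mu_low: float = 2.0
    marker_sigma: float = 0.12

    def __post_init__(self) -> None:
        if self.n_events_per_population < 1:
            raise ValueError("n_events_per_population must be >= 1")
        if not 0.0 < self.mixing_fraction < 1.0:
            raise ValueError("mixing_fraction must be in (0, 1)")
        if self.channel_noise_cv < 0:
            raise ValueError("channel_noise_cv must be >= 0")
        s = np.asarray(self.spillover, dtype=float)
        if s.shape != (2, 2) or (s < 0).any():
            raise ValueError("spillover must be a nonnegative 2x2 matrix")
        if (s.sum(axis=1) > 1.5).any():
            raise ValueError("spillover rows must sum to <= 1.5 (weak cross-talk only)")

    @property
    def noise_ln_sd(self) -> float:
        """ln-scale sd of the unit-mean lognormal noise factor."""
        return math.sqrt(math.log1p(self.channel_noise_cv ** 2))


@dataclass(frozen=True)
class EffectModel:
    """Distribution of true effects across a screen.

    A fraction ``fraction_nonnull`` of strains get a nonzero log2 effect,
    drawn N(0, effect_sd) or, if ``effect_magnitude`` is set, +-magnitude with
    random sign.
    """

    fraction_nonnull: float = 0.1
    effect_sd: float | None = 1.0
    effect_magnitude: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_nonnull <= 1.0:
            raise ValueError("fraction_nonnull must be in [0, 1]")
        if self.effect_magnitude is None and (self.effect_sd is None or self.effect_sd <= 0):
            raise ValueError("need effect_sd > 0 or an explicit effect_magnitude")


@dataclass(frozen=True)
class GroundTruth:
    """Per-strain true effects of a simulated screen."""

    effects: dict[str, float]
    tp_threshold: float = 0.0

    @property
    def true_positives(self) -> list[str]:
        return sorted(g for g, e in self.effects.items() if abs(e) > self.tp_threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.effects), "true_log2_effect": list(self.effects.values())}
        )


def _lognormal10(rng: np.random.Generator, n: int, mu10, sigma10, noise_ln_sd: float
                 ) -> np.ndarray:
    """Linear-scale draws of 10**N(mu10, sigma10) times unit-mean lognormal noise."""
    mu = np.asarray(mu10, dtype=float) * LN10 - 0.5 * noise_ln_sd ** 2
    sd = np.sqrt((np.asarray(sigma10, dtype=float) * LN10) ** 2 + noise_ln_sd ** 2)
    return np.exp(mu + sd * rng.standard_normal(n))


def simulate_well(locus: LocusModel, mutant: StrainSpec, config: GeneratorConfig,
                  *, rng: np.random.Generator | None = None,
                  return_truth: bool = False):
    """Simulate one co-culture well (mutant + BFP reference) as an EventTable.

    Mutant events are drawn from the locus mixture with its linear-scale mean
    scaled by 2**true_log2_effect; reference events from the unshifted
    mixture.  Events carry no population label — demultiplexing has to recover
    it from the BFP/RFP channels — but with ``return_truth=True`` the boolean
    is-mutant vector is returned alongside for validation.
    """
    if mutant.locus_id != locus.locus_id:
        raise ValueError(
            f"strain locus {mutant.locus_id!r} does not match locus model {locus.locus_id!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_total = 2 * config.n_events_per_population
    n_mut = int(rng.binomial(n_total, config.mixing_fraction))
    is_mut = np.zeros(n_total, dtype=bool)
    is_mut[:n_mut] = True
    rng.shuffle(is_mut)

    s_noise = config.noise_ln_sd

    # GFP: reporter mixture (+ per-strain effect on the mutant side) plus
    # autofluorescent background.
    silenced = rng.random(n_total) < locus.p_silenced
    mu10 = np.where(silenced, locus.mu_off, locus.mu_on)
    sg10 = np.where(silenced, locus.sigma_off, locus.sigma_on)
    ln_mu = mu10 * LN10 - 0.5 * s_noise ** 2
    if mutant.true_log2_effect != 0.0:
        ln_mu = ln_mu + np.where(is_mut, mutant.true_log2_effect * LN2, 0.0)
    ln_sd = np.sqrt((sg10 * LN10) ** 2 + s_noise ** 2)
    signal = np.exp(ln_mu + ln_sd * rng.standard_normal(n_total))
    background = _lognormal10(rng, n_total, locus.autofluorescence_mu,
                              locus.autofluorescence_sigma, s_noise)
    gfp = signal + background

    # Constitutive markers: mutants are RFP-high/BFP-low, the reference the
    # opposite.  Spillover mixes the two observed channels.
    hi, lo, ms = config.marker_mu_high, config.marker_mu_low, config.marker_sigma
    bfp = _lognormal10(rng, n_total, np.where(is_mut, lo, hi), ms, s_noise)
    rfp = _lognormal10(rng, n_total, np.where(is_mut, hi, lo), ms, s_noise)
    (s00, s01), (s10, s11) = config.spillover
    bfp_obs = s00 * bfp + s01 * rfp
    rfp_obs = s10 * bfp + s11 * rfp

    fsc = _lognormal10(rng, n_total, 2.6, 0.08, s_noise)
    ssc = _lognormal10(rng, n_total, 2.4, 0.10, s_noise)

    table = EventTable(
        well_id=f"{mutant.gene_id}@{locus.locus_id}",
        channels={"FSC": fsc, "SSC": ssc, "GFP": gfp, "BFP": bfp_obs, "RFP": rfp_obs},
    )
    if return_truth:
        return table, is_mut
    return table


def simulate_screen(n_strains: int, effect_model: EffectModel, locus: LocusModel,
                    config: GeneratorConfig, *, gene_ids: Sequence[str] | None = None,
                    return_truth_labels: bool = False):
    """Simulate a whole screen: one co-culture well per knockout strain.

    Returns ``(tables, strains, truth)``; with ``return_truth_labels=True``
    each table is paired with its per-event is-mutant vector.  Fully
    reproducible from ``config.seed``.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if gene_ids is None:
        gene_ids = [f"GENE{i:04d}" for i in range(n_strains)]
    elif len(gene_ids) != n_strains:
        raise ValueError("gene_ids length must equal n_strains")

    children = np.random.SeedSequence(config.seed).spawn(n_strains + 1)
    eff_rng = np.random.default_rng(children[0])
    effects = np.zeros(n_strains)
    nonnull = eff_rng.random(n_strains) < effect_model.fraction_nonnull
    n_nn = int(nonnull.sum())
    if n_nn:
        if effect_model.effect_magnitude is not None:
            signs = eff_rng.choice([-1.0, 1.0], size=n_nn)
            effects[nonnull] = effect_model.effect_magnitude * signs
        else:
            effects[nonnull] = eff_rng.normal(0.0, effect_model.effect_sd, size=n_nn)

    strains = [StrainSpec(g, float(e), "RFP", locus.locus_id)
               for g, e in zip(gene_ids, effects)]
    out = []
    for i, strain in enumerate(strains):
        well_rng = np.random.default_rng(children[i + 1])
        out.append(simulate_well(locus, strain, config, rng=well_rng,
                                 return_truth=return_truth_labels))
    truth = GroundTruth(effects=dict(zip(gene_ids, map(float, effects))))
    return out, strains, truth


def layout_frame(strains: Sequence[StrainSpec]) -> pd.DataFrame:
    """Plate layout table (well, gene_id, locus_id, label_channel)."""
    return pd.DataFrame({
        "well": [f"{s.gene_id}@{s.locus_id}" for s in strains],
        "gene_id": [s.gene_id for s in strains],
        "locus_id": [s.locus_id for s in strains],
        "label_channel": [s.label_channel for s in strains],
    })


def simulate_annotation_matrix(n_genes: int, n_terms: int,
                               planted_clusters: Sequence[tuple[Sequence[int], Sequence[int]]],
                               noise_rate: float, *, seed: int = 0,
                               gene_ids: Sequence[str] | None = None,
                               term_ids: Sequence[str] | None = None):
    """Binary gene-by-term incidence with planted functional clusters.

    Genes in a planted cluster are annotated to exactly that cluster's terms;
    every entry outside the planted blocks is an independent Bernoulli
    ``noise_rate`` bit flip (i.e. a spurious annotation).
    """
    from .kappa import AnnotationMatrix

    if n_genes < 1 or n_terms < 1:
        raise ValueError("matrix dimensions must be positive")
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    bits = np.zeros((n_genes, n_terms), dtype=np.uint8)
    planted = np.zeros((n_genes, n_terms), dtype=bool)
    for genes, terms in planted_clusters:
        ix = np.ix_(np.asarray(genes, dtype=int), np.asarray(terms, dtype=int))
        bits[ix] = 1
        planted[ix] = True
    if noise_rate > 0:
        flips = rng.random((n_genes, n_terms)) < noise_rate
        flips &= ~planted
        bits[flips] ^= 1
    if gene_ids is None:
        gene_ids = [f"GENE{i:04d}" for i in range(n_genes)]
    if term_ids is None:
        term_ids = [f"TERM{j:05d}" for j in range(n_terms)]
    return AnnotationMatrix(gene_ids=list(gene_ids), term_ids=list(term_ids), bits=bits)


def simulate_qpcr(true_fold_change: float, ct_noise_sd: float, n_replicates: int,
                  *, seed: int = 0, target: str = "YFR057W",
                  mutant_genotype: str = "mutant", reference_gene: str = "ACT1",
                  ct_target_wt: float = 25.0, ct_reference: float = 20.0) -> pd.DataFrame:
    """Ct table for a WT-vs-mutant RT-qPCR experiment.

    Constructed so that the expected ddCt of the mutant equals
    -log2(true_fold_change): a 2-fold expression increase shifts the target Ct
    down by one cycle.  Gaussian noise of sd ``ct_noise_sd`` is added to every
    Ct independently.
    """
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    ct_target_mut = ct_target_wt - math.log2(true_fold_change)
    for genotype, ct_t in (("WT", ct_target_wt), (mutant_genotype, ct_target_mut)):
        for rep in range(1, n_replicates + 1):
            rows.append((f"{genotype}_r{rep}", genotype, target, rep,
                         ct_t + ct_noise_sd * rng.standard_normal()))
            rows.append((f"{genotype}_r{rep}", genotype, reference_gene, rep,
                         ct_reference + ct_noise_sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "target", "replicate", "ct"])


def load_locus_presets(path) -> dict[str, LocusModel]:
    """Read LocusModel presets from a YAML mapping {locus_id: params}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: LocusModel(locus_id=k, **v) for k, v in raw.items()}


def dump_locus_presets(presets: dict[str, LocusModel], path) -> None:
    out = {}
    for k, m in presets.items():
        d = {f: getattr(m, f) for f in ("p_silenced", "mu_off", "sigma_off", "mu_on",
                                        "sigma_on", "autofluorescence_mu",
                                        "autofluorescence_sigma")}
        out[k] = d
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh)
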