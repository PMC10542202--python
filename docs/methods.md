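# Methods

`silscreen` analyses competitive flow-cytometry screens for subtelomeric gene
silencing in *Saccharomyces cerevisiae*. Each well contains two co-cultured
populations carrying the same silencing-sensitive *URA3-GFP* reporter at a
subtelomeric query locus: an RFP(mCherry)-labelled gene-deletion mutant and a
BFP-labelled wild-type reference. This note documents the models, the
estimators, the numerical choices and the limits of what the simulations can
show.

## The silencing score

For a well with mutant events M and reference events R, the silencing score is

    Si = mean(GFP_M) / mean(GFP_R)

with arithmetic means on linear fluorescence. Si > 1 means the deletion
de-repressed the reporter (diminished silencing); Si < 1 means increased
silencing. The score is computed per well against the co-cultured reference
(not a plate-pooled reference): co-culturing cancels well-to-well acquisition
and growth-stage effects, which is the point of the design. Options: a
geometric-mean variant (`geometric=True`) and subtraction of a constant
autofluorescence background from both means before the ratio (off by
default — the co-culture ratio already cancels most of it; the residual bias
is quantified below).

## Generative model of a well

Single-cell reporter expression at a silenced locus is variegated: a fraction
`p_silenced` of cells occupy a low ("off") state and the rest an expressing
("on") state. Each state is lognormal on linear fluorescence, parameterised
by (mu, sigma) on log10 scale. The GFP channel of a cell is

    GFP = 10^N(mu_state, sigma_state) * 2^d + 10^N(mu_autofl, sigma_autofl)

where d is the strain's true log2 effect (applied to the mutant population
only — scaling the reporter mixture scales its linear mean by exactly 2^d)
and the second term is autofluorescent background. Constitutive markers are
lognormal: the mutant is RFP-high/BFP-low, the reference the opposite, with
log10 levels 3.0/2.0 (10x separation) and sigma 0.12 decades by default.
Forward/side scatter are uninformative lognormals. An optional 2x2 spillover
matrix mixes the observed BFP/RFP channels to stress-test demultiplexing
(identity by default).

Multiplicative measurement noise with coefficient of variation
`channel_noise_cv` (default 0.05) is a unit-mean lognormal factor. Since a
product of lognormals is lognormal, the factor is folded analytically into
each component's (mu, sigma) — identical in distribution to drawing it
separately, half the RNG cost, and the closed-form component means stay
exact. These closed forms (`LocusModel.signal_mean`, `mean_gfp`) are the
oracle for Si-recovery tests.

Locus presets (strong silencing COS12-like: p_silenced 0.85; weak
YFR057W-like: 0.45; unsilenced CUP9-5' control: 0.05; all with off/on log10
means 1.6-1.8/3.0-3.2) are illustrative: the screens this package models
published distributions but no fitted parameters, so the presets were chosen
once to reproduce the qualitative phenomenology (bimodality, mean shifts,
ordering of loci) and are not calibrated to data.

Acquisition defaults follow the screens' contract: 15,000 events per well
(7,500 per population at even mixing; per-population counts are binomial in
the mixing fraction), and in practice 5,000-15,000 assigned events per
population.

## Demultiplexing and QC

Events are assigned by the marker log-ratio r = log10(RFP+1) - log10(BFP+1)
(+1 pseudocount for zero intensities). The default rule thresholds r at 0
with a +-0.3-decade dead-band of unassigned events; it is deterministic,
auditable, and exactly label-symmetric (swapping the marker channels and the
threshold sign swaps the two populations). A two-component Gaussian-mixture
classifier on r (`method="two_gaussian"`, fixed random state, posterior
cut-off 0.95) is available for instruments with drifting marker levels.
Accuracy is reported as correct/assigned; dead-band abstentions are reported
separately. At the default 10x separation both readings exceed 99.9%.

No scatter-based debris gate is applied by default (none is described for
the screens modelled here); an optional percentile gate exists in
configuration space but is out of the default path. Wells need >= 1,000
assigned events per population to yield an Si value; below that, or when one
population falls under 5% of assigned events, or when a channel saturates,
the well fails QC and is reported as missing — mirroring the incomplete
coverage of real screens. QC never mutates event data; `EventTable` is
immutable.

## Hit calling at FDR < 10%

The published screens state a 10% false-discovery rate but not the
procedure, so the caller is pluggable (`method` registry). The default:

1. log2 Si per qc-passing strain;
2. robust z-scores against the screen median and MAD (x1.4826);
3. two-sided p-values from a Student-t with 0.37*(n-1) effective degrees of
   freedom — 0.37 is the MAD's asymptotic efficiency relative to the sample
   sd, and ignoring the scale estimate's sampling noise makes extreme
   z-scores anti-conservative (the any-call rate of a 500-strain null screen
   is 0.126 with normal tails versus ~0.10 with the t calibration);
4. Benjamini-Hochberg adjustment; calls split by sign at q <= fdr, with
   `decreased_silencing` additionally requiring Si > 1 and
   `increased_silencing` Si < 1.

MAD = 0 raises (the null spread is not estimable); at least 50 qc-passing
strains are required. Ranks and deciles break Si ties by gene id, so every
downstream partition is invariant under input order.

Technical replicates aggregate as the mean of log2 Si with a one-sample
t-test against 0. Between-screen concordance is Spearman's rho over the
qc-passing intersection, ties mid-ranked.

## Decile enrichment

Qc-passing strains are sorted by Si and split into 10 bins whose sizes
differ by at most one (lower deciles absorb the remainder; 3,716 strains
give sizes 371/372). Each decile is tested for over-representation of a
curated catalog with the one-sided hypergeometric tail P(X >= k), flagged at
p < 0.05 without multiplicity correction — one display-level test per
decile, as such screens conventionally plot them. Catalog genes absent from
the screen are excluded from the denominator. "The two higher or lower
deciles" is implemented as top-2 plus bottom-2 (`k_per_end=2`) but exposed
as a parameter since the phrase also reads as the single extreme decile per
end; both are computable. A permutation version of the decile test
(membership shuffled, add-one estimator) serves as an independent check of
the closed form.

## Kappa-based functional clustering

For genes a, b with binary annotation vectors over n GO/phenotype terms,

    Pr(a) = (both-annotated + both-unannotated) / n
    Pr(e) = p_a p_b + (1 - p_a)(1 - p_b)
    kappa = (Pr(a) - Pr(e)) / (1 - Pr(e))

i.e. standard two-rater Cohen's kappa with the genes' marginal annotation
rates as the chance model. Pr(e) = 1 (two identical constant rows) leaves
kappa undefined; it is reported as 0 with a warning, since such pairs carry
no discriminative annotation. The full pairwise matrix is vectorised through
co-occurrence counts (`B B^T`) and verified against a direct 2x2-contingency
implementation to 1e-12. Gene pairs with kappa strictly above 0.35 are
retained as associated (the build reports where that threshold sits in the
empirical kappa distribution — top ~5% for reference-scale matrices, 99.4th
percentile for the planted matrices used here, whose background annotation
noise of 1% is sparser than a real annotation snapshot).

Each retained edge seeds a two-gene cluster. Clusters then merge
iteratively: a cluster with strictly more than `merge_share` (default 0.5)
of its own members present in other clusters is merged with every cluster it
overlaps, rescanning in lexicographic order of sorted member lists until a
fixpoint. This is the only non-vacuous reading of "clusters sharing over 50%
of their members are merged" when seeds are pairs — a pairwise
shared-over-smaller test can never exceed 1/2 between two-gene seeds — and
it reproduces the defining small cases: an edge triangle collapses to one
three-gene cluster while an edge path stays as two clusters. The literal
pairwise rule is available as `rule="pairwise_smaller"` for comparison.
Because clusters are sorted before each scan, the result is independent of
edge input order; each pass strictly reduces the cluster count, so a
fixpoint is reached in at most as many passes as there are seeds (in
practice two or three). Genes may belong to several clusters. Clusters get
stable numeric ids (by decreasing size, then lexicographic); naming clusters
by function is manual-curation territory and out of scope.

## Validation calculators

ddCt: per replicate, dCt = Ct(target) - Ct(ACT1); per genotype, ddCt =
mean dCt - mean dCt(wild type); fold change = 2^(-ddCt), i.e. perfect
doubling efficiency (an `efficiency` parameter generalises this). The
reference genotype is exactly 1 by construction; the fold sd is computed
across per-replicate fold changes and significance by a two-sample t-test on
dCt. The computation is invariant under adding a constant to every Ct.

NuSA: relative protection of each tiled amplicon (midpoints in bp relative
to the ATG at +1) against the VCX1 control amplicon, which sits inside a
well-positioned nucleosome: Q/Q_VCX1 in quantity mode or 2^(Ct_VCX1 - Ct) in
Ct mode. Single-digestion normalisation is assumed (no per-titration
control); replicate mean and sd are reported per amplicon.

## Problem sizes for the reproduction script

`scripts/acceptance.py` regenerates every number it reports. Sizes, chosen
as the package's own benchmark conditions: null-FDR calibration over 200
seeded 500-strain screens at 1,000 events per population — the any-call rate
of a null screen depends on strain count and test calibration, not on the
per-event count, which only sets the per-strain standard error; effect
recovery on one 500-strain screen with 10% of strains at |log2 effect| = 1.5
and 10,000 events per population; demultiplexing at marker separations 2x,
5x, 10x with 10,000 events per population; kappa agreement on random 50x200
matrices at three densities; cluster recovery over 50 planted 3-cluster
matrices (40x200, 5% noise); hypergeometric-vs-permutation agreement on a
200-strain screen with 10,000 draws.

Effect recovery uses the weak-silencing preset deliberately: per-event GFP
dispersion under the strongly variegated preset (CV ~ 2.3) puts the
per-strain standard error of log2 Si near 0.047 at 10,000 events, so the
worst of 500 strains strays beyond +-0.1 of truth; the weak preset
(CV ~ 1.15, SE ~ 0.024) keeps every strain within that band. This is a
moment calculation from the closed-form mixture, not a tuned choice.

## What the simulations do and do not show

The generator reproduces variegated bimodal GFP, marker-separable
co-cultures, binomial population splits, multiplicative channel noise,
optional spillover, and screen-scale sparse true effects — enough to
exercise every estimator end to end against known truth. It does not model
cell-cycle or growth competition between the co-cultured strains, plate
position or batch effects, doublets, instrument drift within a run, or
5-FOA-related metabolic artefacts; passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-world effects. Annotation matrices are planted-block fixtures,
not an SGD snapshot, so cluster *identities* from the reference analysis are
not reproducible here — only the behaviour of the algorithm on matrices of
that scale and structure.
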