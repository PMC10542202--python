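# silscreen

Quantitative analysis of competitive flow-cytometry screens for
**subtelomeric gene silencing** (telomere position effect) in budding yeast.

In these screens, a silencing-sensitive *URA3-GFP* reporter sits at a
subtelomeric query locus (e.g. *COS12* or *YFR057W*). Each RFP-labelled
gene-deletion mutant is grown in co-culture with a BFP-labelled wild-type
reference carrying the same reporter, and both populations are read out
simultaneously by flow cytometry. The **silencing score** of a deletion is

> *Si* = mean GFP of the mutant population / mean GFP of the co-cultured
> reference population

so *Si* > 1 means the deletion de-repressed the reporter (diminished
silencing) and *Si* < 1 increased silencing. `silscreen` implements the full
analysis path around this statistic:

- **cytometry**: event I/O (TSV dialect and minimal FCS 3.0/3.1), marker
  log-ratio demultiplexing of the co-cultured populations, well-level QC;
- **scoring**: per-well *Si*, robust-z/Benjamini–Hochberg hit calling at
  FDR < 10% in both directions, replicate aggregation, Spearman concordance
  between screens;
- **enrichment**: *Si*-decile partitioning and one-sided hypergeometric
  enrichment of a curated catalog of known silencing genes (p < 0.05 per
  decile), extreme-decile fractions;
- **kappa**: pairwise Cohen's kappa over a binary gene×term annotation
  matrix, κ = (Pr(a) − Pr(e))/(1 − Pr(e)), association edges at κ > 0.35,
  and iterative >50% member-sharing cluster merges;
- **qpcr**: ΔΔCt relative expression normalised to *ACT1* and a reference
  genotype (fold change = 2^−ΔΔCt), and nucleosome-scanning (NuSA) relative
  protection against the *VCX1* control amplicon;
- **simulate**: a generative model of variegated reporter expression
  (two-component lognormal mixture per locus), whole screens with known
  ground truth, planted-cluster annotation matrices and qPCR fixtures, so
  every stage is testable without instrument data.

See `docs/methods.md` for models, estimators and numerical choices.

## Worked example

Simulate a 400-strain screen at the strong-silencing locus preset, score it
and call hits:

```sh
$ silscreen simulate --locus COS12 --n-strains 60 --events 600 --seed 5 --out wells/
wrote 60 wells to wells
$ silscreen score --events-dir wells/ --layout wells/layout.tsv \
      --min-per-population 200 --out screen.tsv
60 strains scored; 3 decreased / 5 increased silencing at FDR<10%
```

or drive the whole analysis from Python (this is what the numbered scripts
under `analysis/` do at larger sizes):

```python
import silscreen as ss

cfg = ss.GeneratorConfig(n_events_per_population=2500, seed=20230711)
tables, strains, truth = ss.simulate_screen(
    400, ss.EffectModel(fraction_nonnull=0.10, effect_sd=1.0),
    ss.LOCUS_PRESETS["COS12"], cfg)
screen = ss.call_hits(ss.score_screen(tables, strains), fdr=0.10)
```

Running the analysis chain (`analysis/01…06`) prints, for one seeded
realisation:

```
COS12: 400/400 wells pass QC; 17 decreased / 20 increased silencing at FDR<10% (observed FDP 0.00)
YFR057W: 400/400 wells pass QC; 21 decreased / 22 increased silencing at FDR<10% (observed FDP 0.05)
replicate screens (same locus):   rho = 0.27 (n = 400, p = 2.8e-08)
between loci (shared knockouts):  rho = 0.25 (n = 400, p = 4.2e-07)
COS12: 99/132 catalog genes evaluated; 59% in the two extreme deciles per end; enriched deciles [1, 10]
35245 gene pairs evaluated (266 genes x 2234 terms)
kappa > 0.35 keeps 195 edges (threshold at the 99.4th percentile of pairwise kappas)
11 clusters after 2 iterations; sizes [12, 9, 8, 7, 6, 5, 4, 4, 3, 3, 3]
ddCt: lge1d expresses YFR057W 1.76-fold vs WT (true fold 2.0, t-test p = 0.0036)
```

Reading these numbers: the hit caller recovers planted silencing effects in
both directions with the false-discovery proportion at or under the nominal
10%; known-gene catalogs concentrate in the extreme *Si* deciles (decile 1 =
strongest *increased* silencing, decile 10 = strongest de-repression); the
kappa clustering recovers all eleven planted functional modules at their
exact sizes; and the ΔΔCt calculator recovers an engineered 2-fold
de-repression from noisy triplicate Ct values with the corresponding
significance call. Replicate and cross-locus rank correlations are positive
and highly significant at this effect fraction and noise level.

Per-locus tables (ScreenTable TSVs with gene, *Si*, rank, decile, q-value,
call), enrichment tables, the kappa network edge list and validation
profiles are written under `results/`.

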