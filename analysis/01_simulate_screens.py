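#!/usr/bin/env python
"""Simulate the two genome-wide silencing screens with known ground truth.

Generates a strong-silencing (COS12-like) and a weak-silencing (YFR057W-like)
screen over the same knockout collection: the two screens share each gene's
true silencing effect, as two query loci assayed over one deletion library
would, but have independent measurement noise.  Writes the plate layouts and
ground-truth tables under results/; the (large) per-well event data are
regenerated on demand by later steps from the same seeds, so nothing bulky is
stored.
"""

import pathlib
import sys

import numpy as np

import silscreen as ss

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"

# Study conditions: a few hundred strains keep this demonstration quick; the
# screens it emulates covered ~4,000 knockouts with 5,000-15,000 events per
# population.  10% of deletions carry true silencing effects of sd 1 (log2).
N_STRAINS = 400
N_EVENTS = 2500
FRACTION_NONNULL = 0.10
EFFECT_SD = 1.0
SEED = 20230711


def shared_effect_screens():
    """Two locus screens over one knockout collection with shared effects."""
    rng = np.random.default_rng(SEED)
    genes = [f"GENE{i:04d}" for i in range(N_STRAINS)]
    effects = np.where(rng.random(N_STRAINS) < FRACTION_NONNULL,
                       rng.normal(0.0, EFFECT_SD, N_STRAINS), 0.0)
    screens = {}
    for locus_name, sub_seed in (("COS12", SEED + 1), ("YFR057W", SEED + 2)):
        locus = ss.LOCUS_PRESETS[locus_name]
        cfg = ss.GeneratorConfig(n_events_per_population=N_EVENTS, seed=sub_seed)
        strains = [ss.StrainSpec(g, float(e), "RFP", locus_name)
                   for g, e in zip(genes, effects)]
        children = np.random.SeedSequence(sub_seed).spawn(N_STRAINS)
        tables = [ss.simulate_well(locus, s, cfg, rng=np.random.default_rng(c))
                  for s, c in zip(strains, children)]
        screens[locus_name] = (tables, strains)
    truth = ss.GroundTruth(effects=dict(zip(genes, map(float, effects))))
    return screens, truth


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    screens, truth = shared_effect_screens()
    truth.to_frame().to_csv(RESULTS / "ground_truth.tsv", sep="\t", index=False)
    for locus_name, (tables, strains) in screens.items():
        ss.layout_frame(strains).to_csv(RESULTS / f"layout_{locus_name}.tsv",
                                        sep="\t", index=False)
    n_nonnull = sum(1 for e in truth.effects.values() if e != 0.0)
    print(f"simulated {len(screens)} screens x {N_STRAINS} strains "
          f"({N_EVENTS} events/population/well)")
    print(f"{n_nonnull} strains carry true effects (sd {EFFECT_SD} log2 units); "
          f"layouts and ground truth in {RESULTS}/")


if __name__ == "__main__":
    sys.exit(main())
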