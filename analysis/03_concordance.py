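#!/usr/bin/env python
"""Replicate and between-locus rank concordance of Si scores.

Reads the two scored screens from 02 and, for the replicate check, rescores
the strong-silencing screen from an independent noise realisation of the
same ground truth.  Spearman rank correlations play the role of the screens'
replicate (r = 0.63 there) and cross-locus (r = 0.56) agreement statistics;
the exact values here depend on the simulated effect fraction and noise.
"""

import importlib.util
import pathlib
import sys

import numpy as np
import pandas as pd

import silscreen as ss

HERE = pathlib.Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"

spec = importlib.util.spec_from_file_location("sim01", HERE / "01_simulate_screens.py")
sim01 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim01)


def main() -> None:
    a = pd.read_csv(RESULTS / "screen_COS12.tsv", sep="\t")
    b = pd.read_csv(RESULTS / "screen_YFR057W.tsv", sep="\t")

    # replicate screen: same strains and effects, fresh acquisition noise
    locus = ss.LOCUS_PRESETS["COS12"]
    truth = pd.read_csv(RESULTS / "ground_truth.tsv", sep="\t")
    strains = [ss.StrainSpec(g, float(e), "RFP", "COS12")
               for g, e in zip(truth["gene_id"], truth["true_log2_effect"])]
    cfg = ss.GeneratorConfig(n_events_per_population=sim01.N_EVENTS,
                             seed=sim01.SEED + 99)
    children = np.random.SeedSequence(cfg.seed).spawn(len(strains))
    tables = [ss.simulate_well(locus, s, cfg, rng=np.random.default_rng(c))
              for s, c in zip(strains, children)]
    replicate = ss.score_screen(tables, strains, min_per_population=1000)

    rep = ss.screen_concordance(a, replicate)
    cross = ss.screen_concordance(a, b)
    out = pd.DataFrame([
        {"comparison": "COS12_replicates", **rep},
        {"comparison": "COS12_vs_YFR057W", **cross},
    ])
    out.to_csv(RESULTS / "concordance.tsv", sep="\t", index=False)
    print(f"replicate screens (same locus):   rho = {rep['spearman_rho']:.2f} "
          f"(n = {rep['n_common']}, p = {rep['p_value']:.2g})")
    print(f"between loci (shared knockouts):  rho = {cross['spearman_rho']:.2f} "
          f"(n = {cross['n_common']}, p = {cross['p_value']:.2g})")


if __name__ == "__main__":
    sys.exit(main())
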