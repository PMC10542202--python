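#!/usr/bin/env python
"""Decile enrichment of a known-silencing-gene catalog in the scored screens.

Builds a 132-gene catalog the way a literature curation would relate to a
screen: most entries are genes that truly affect silencing in the simulation
(some of them not screened, mirroring catalog genes absent from the deletion
collection), a minority are historical false leads with no effect.  Tests
each Si decile with a one-sided hypergeometric at p < 0.05 and reports the
fraction of evaluated catalog genes in the two extreme deciles per end.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

import silscreen as ss

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
CATALOG_SIZE = 132
SEED = 4


def build_catalog(truth: pd.DataFrame) -> ss.Catalog:
    rng = np.random.default_rng(SEED)
    nonnull = truth.loc[truth["true_log2_effect"] != 0, "gene_id"].tolist()
    sources = {}
    for g in nonnull:
        sources[g] = "screen_literature"
    # catalog genes never screened here (absent from this collection)
    for i in range(CATALOG_SIZE // 4):
        sources[f"UNSCREENED{i:03d}"] = "older_report"
    # historical false leads: catalogued but without true effect
    null_genes = truth.loc[truth["true_log2_effect"] == 0, "gene_id"]
    for g in rng.choice(null_genes, CATALOG_SIZE - len(sources), replace=False):
        sources[g] = "older_report"
    return ss.Catalog(sources)


def main() -> None:
    truth = pd.read_csv(RESULTS / "ground_truth.tsv", sep="\t")
    catalog = build_catalog(truth)
    catalog.write_tsv(RESULTS / "catalog.tsv")
    for locus in ("COS12", "YFR057W"):
        screen = pd.read_csv(RESULTS / f"screen_{locus}.tsv", sep="\t")
        res = ss.decile_enrichment(screen, catalog)
        res.per_decile.to_csv(RESULTS / f"enrichment_{locus}.tsv", sep="\t",
                              index=False)
        from silscreen.enrichment import plot_decile_bubbles
        plot_decile_bubbles(res, RESULTS / f"enrichment_{locus}.png")
        enriched = res.per_decile.loc[res.per_decile["enriched"], "decile"].tolist()
        print(f"{locus}: {res.n_catalog_evaluated}/{len(catalog.genes)} catalog genes "
              f"evaluated; {100 * res.extreme_fraction:.0f}% in the two extreme "
              f"deciles per end; enriched deciles {enriched}")


if __name__ == "__main__":
    sys.exit(main())
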