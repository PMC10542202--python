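#!/usr/bin/env python
"""Score both simulated screens: demultiplex, Si, FDR<10% hit calls.

Regenerates the wells from 01's seeds, runs the scoring pipeline and writes
one ScreenTable per locus (gene, Si, rank, decile, q-value, call) under
results/.  Prints the hit counts per direction — the analogue of the screens'
"N deletions decreased / M increased silencing at FDR < 10%" summary — and
how they compare with the planted truth.
"""

import importlib.util
import pathlib
import sys

import silscreen as ss

HERE = pathlib.Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"

spec = importlib.util.spec_from_file_location("sim01", HERE / "01_simulate_screens.py")
sim01 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim01)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    screens, truth = sim01.shared_effect_screens()
    for locus_name, (tables, strains) in screens.items():
        screen = ss.score_screen(tables, strains, min_per_population=1000)
        screen = ss.call_hits(screen, fdr=0.10)
        screen.to_csv(RESULTS / f"screen_{locus_name}.tsv", sep="\t", index=False)
        n_dec = int((screen["call"] == "decreased_silencing").sum())
        n_inc = int((screen["call"] == "increased_silencing").sum())
        called = screen.loc[screen["call"] != "no_call", "gene_id"]
        true_pos = set(truth.true_positives)
        fdp = 1.0 - (called.isin(true_pos).mean() if len(called) else 0.0)
        print(f"{locus_name}: {screen['qc_pass'].sum()}/{len(screen)} wells pass QC; "
              f"{n_dec} decreased / {n_inc} increased silencing at FDR<10% "
              f"(observed FDP {fdp:.2f})")


if __name__ == "__main__":
    sys.exit(main())
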