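#!/usr/bin/env python
"""Copy-number analysis: equal-coverage bins, 5-state segmentation,
genome fractions per state, and the T1-vs-T2 state diff.

Reads the tracks written by 01_simulate_cohort.py; writes binned
ratios, segment tables, per-state genome fractions and the
loss->gain / gain->loss region lists under results/copy_number/.
"""

from pathlib import Path

import pandas as pd

from oncotrace import binning, cnv, io

BASE = Path(__file__).resolve().parent.parent / "results"
INP = BASE / "scenario_inputs"
OUT = BASE / "copy_number"


def main() -> None:
    normal = io.read_depth_track(INP / "depth_normal.tsv")
    bins = binning.build_bins(normal, reads_per_bin=200)

    segments = {}
    for tp in ("T1", "T2"):
        tumor = io.read_depth_track(INP / f"depth_tumor_{tp}.tsv")
        ratios = binning.fill_ratios(bins, tumor)
        io.write_table(ratios, OUT / f"binned_ratios_{tp}.tsv")
        segments[tp] = cnv.viterbi_segment(ratios)
        io.write_table(segments[tp], OUT / f"cnv_segments_{tp}.tsv")
        frac = cnv.genome_fraction_by_state(segments[tp])
        pd.DataFrame({"state": range(1, 6), "fraction": frac}).to_csv(
            OUT / f"genome_fraction_{tp}.tsv", sep="\t", index=False)
        print(f"{tp}: {len(segments[tp])} segments; "
              + "; ".join(f"state {s}: {f:.2%}"
                          for s, f in zip(range(1, 6), frac) if f > 0))

    diff = cnv.compare_timepoints(segments["T1"], segments["T2"])
    io.write_table(diff["delta"], OUT / "state_delta.tsv")
    io.write_table(diff["loss_to_gain"], OUT / "loss_to_gain.tsv")
    io.write_table(diff["gain_to_loss"], OUT / "gain_to_loss.tsv")
    print(f"T1->T2: {len(diff['loss_to_gain'])} loss->gain region(s), "
          f"{len(diff['gain_to_loss'])} gain->loss region(s)")

    genes = io.read_table(INP / "gene_models.tsv")
    amplified = cnv.genes_in_state(segments["T1"], genes, min_state=3)
    high = cnv.genes_in_state(segments["T1"], genes, min_state=5)
    print(f"T1: {len(amplified)} genes in gained/amplified regions, "
          f"{len(high)} highly amplified: {high}")


if __name__ == "__main__":
    main()
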