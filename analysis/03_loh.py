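#!/usr/bin/env python
"""LOH analysis: tumor zygosity at germline-het sites, equal-SNP bins,
3-state segmentation, genome fractions, and copy-neutral LOH regions.

Reads SNP tables from 01 and CNV segments from 02; writes LOH bins,
segments and copy-neutral regions under results/loh/.
"""

from pathlib import Path

from oncotrace import io, loh

BASE = Path(__file__).resolve().parent.parent / "results"
INP = BASE / "scenario_inputs"
OUT = BASE / "loh"


def main() -> None:
    sites_panel = io.read_table(INP / "germline_sites.tsv")
    het = sites_panel[sites_panel["genotype"] == "het"]
    keys = set(zip(het["chrom"], het["pos"]))

    for tp in ("T1", "T2"):
        table = io.read_table(INP / f"snp_tumor_{tp}.tsv")
        at_het = table[[k in keys for k in zip(table["chrom"], table["pos"])]]
        sites = at_het[["chrom", "pos"]].copy()
        sites["is_het"] = loh.classify_zygosity(at_het).to_numpy()
        bins = loh.bin_het_rate(sites.sort_values(["chrom", "pos"]))
        io.write_table(bins, OUT / f"loh_bins_{tp}.tsv")
        segments = loh.segment_loh(bins)
        io.write_table(segments, OUT / f"loh_segments_{tp}.tsv")
        frac = loh.loh_genome_fractions(segments)
        print(f"{tp}: incomplete LOH {frac['low']:.1%}, "
              f"complete LOH {frac['high']:.1%} of covered genome")

        cnv_segments = io.read_table(
            BASE / "copy_number" / f"cnv_segments_{tp}.tsv")
        cn = loh.copy_neutral_loh(segments, cnv_segments)
        io.write_table(cn, OUT / f"copy_neutral_loh_{tp}.tsv")
        events = loh.merge_contiguous(cn)
        print(f"{tp}: {len(events)} copy-neutral LOH event(s)"
              + (f" at {[f'{r.chrom}:{r.start}-{r.end}' for r in events.itertuples()]}"
                 if len(events) else ""))


if __name__ == "__main__":
    main()
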