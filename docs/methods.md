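# Methods

This note documents the models, defaults and design decisions behind
each pipeline layer, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Coordinate frame and data containers

All genomic coordinates are 0-based half-open, BED-like on disk
(plain TSV). A `GenomeLayout` fixes chromosome names and lengths; a
`TruthSet` carries planted CNV segments, LOH segments, germline-het
sites, somatic variants and differentially expressed genes, optionally
tagged with the tumor timepoint they apply to. Expression lives in an
`ExpressionMatrix` (genes × libraries of aligned-base counts, library
role tags, per-library totals that may exceed the column sums).

## Depth binning

Bins are defined on the reference (normal) track so that every
complete bin holds exactly `reads_per_bin` reference reads (default
200 — small enough to resolve ~100 kb events at 100× window depth,
large enough that the per-bin log-ratio standard deviation is ≈
`sqrt(2/reads_per_bin)/ln 2` ≈ 0.14). Reads within a track window are
treated as uniformly spread, so a bin boundary may split a window pro
rata; the trailing bin per chromosome keeps the remainder and is
flagged partial (excluded from segmentation by default). We count read
mass, i.e. the window counts, rather than modelling individual read
extents.

The per-bin statistic is the median-centered log2 ratio

    r_i = log2( ((t_i + c·T/R)/T) / ((n_i + c)/R) ) − median_j(...)

with pseudocount `c = 1` (configurable, 0 allowed for exact
arithmetic). The tumor-side pseudocount is expressed in
reference-library units (`c·T/R`) so that rescaling the tumor library
leaves every ratio unchanged exactly — a plain `t_i + c` breaks that
invariance; the two forms coincide when `T = R`. Median centering is
robust to aneuploidy shifting the mean ploidy.

## Copy-number HMM

Five states (loss, neutral, gain, amplification, high-level
amplification) with fixed emission means (−1.0, 0.0, 0.58, 1.0, 2.0
log2 units, i.e. ~1, 2, 3, 4 and 8 copies against a diploid
reference). Emissions are Student-t with 4 degrees of freedom — heavy
tails keep isolated outlier bins from forcing state changes — with one
shared scale, estimated as 1.4826 × the median absolute residual to
the nearest state mean (floored at 0.05) unless supplied. Transitions
have a single smoothing knob: self-transition 0.999, the remainder
uniform; at bin widths of a few kb this implies an expected segment
length of roughly a thousand bins and keeps the all-neutral false-call
genome fraction well under 2%. Decoding is hard Viterbi in log space,
chromosomes independent, ties broken toward the lower state; no
parameter re-estimation is performed. Segments are run-length-encoded
maximal constant-state runs.

Gene-level summaries use the any-overlap rule (`genes_in_state`) or,
for the per-gene evidence table, the maximum state among overlapping
segments — chosen so a focal amplicon inside a larger region still
marks its gene as highly amplified. Timepoint comparison intersects
the two segment boundary sets and reports Δ = state(T2) − state(T1)
per region, with loss→gain (1 → ≥3) and gain→loss (≥3 → 1) listed
separately.

## LOH HMM

Informative sites are those heterozygous in the germline sample; the
tumor's zygosity at exactly those sites feeds the bins. This isolates
allelic loss from SNP-discovery noise, at the cost of ignoring
tumor-only SNVs (deliberate: those are the somatic layer's job).
Zygosity is thresholded at p(het) ≥ 0.5. Bins hold 25 informative
sites each, with boundaries midway between the flanking sites of
adjacent bins so bin width tracks SNP density.

Emissions are Binomial(n_sites, ρ_s) with default het rates
ρ = (0.95, 0.50, 0.02): germline-het sites stay het up to call noise
in retained regions; a 50/50 tumor/normal mixture that lost one allele
reads hom at about half the sites (the "low" state is explicitly a
mixture signal); complete loss leaves only misclassification residue.
Self-transition 0.999 as for copy number. Copy-neutral LOH is the
boundary intersection of LOH state ≠ normal with CNV state = 2; LOH
over a deletion is excluded as deletion LOH. When counting
copy-neutral *events*, touching regions are merged: the boundary bins
of a complete-LOH region often decode as "low" (mixed sites) and are
part of the same event.

## Somatic filter cascade

Tumor calls must pass all of: consensus quality ≥ 30, depth ≥ 8,
minimum mapping quality ≥ 60 (strictest per-site reading; an RMS
interpretation would be configurable here), base quality ≥ 20, and
variant reads ≥ 1/3 of total reads (inclusive; the comparison is
cross-multiplied with a 1e-9 slack so 3 of 9 passes despite binary
rounding). Germline calls pass at consensus ≥ 10, depth ≥ 1, mapping
quality ≥ 20 with no base-quality or fraction rule — deliberately lax
so marginal germline evidence still vetoes a somatic candidate. The
cascade is a conjunction, hence order-independent; rejection reasons
are reported in a fixed canonical order. Known-polymorphism
subtraction takes plain blocklist tables (chrom, pos, and optionally
alt for allele-aware matching) — no live database access.

Coding annotation maps a variant into its gene's CDS (single-interval
models, length divisible by 3), reverse-complements on the minus
strand, and translates reference and alternate codons with the
standard genetic code (Biopython); classes are missense, nonsense
(alternate codon is a stop), synonymous, non-coding. A recurrence
variant is "new" only if absent from the first tumor's calls *and*
supported by zero first-tumor reads; a single supporting read
downgrades it to "pre-existing at low level".

## Differential expression

Genes with fewer than 20% non-zero compendium libraries are removed
first (a small tumor count would receive an inflated rank against
all-zero references); exactly 20% survives. Expression is aligned
bases per library total (per million); fold changes add one count per
library before normalizing and use the signed convention (ratio 0.25
reports as −4.0).

The tumor-vs-compendium comparison uses the empirical rank outlier
probability p = (k + 1)/(N + 1), k = number of compendium libraries at
least as extreme in the tested direction (the direction the tumor
falls on relative to the compendium median). The statistic is isolated
behind `outlier_p` so a median/MAD z-score could be swapped in. Note
its floor: with N = 50 the smallest possible p is 1/51 ≈ 0.0196.
**Consequently the significance gate on the outlier family uses the
raw p < 0.05** — a Benjamini–Hochberg-adjusted outlier p can never
fall below `0.0196·m/k` and would veto every call in any
realistically sized gene set. The Fisher family has no such floor and
is gated on its BH-adjusted q < 0.05; both adjusted families are
reported. Fisher's test is two-sided by summing hypergeometric
probabilities at most as likely as the observed table; margins above
1e8 are proportionally down-scaled first (aligned-base totals can
reach billions; the enumeration itself only costs O(gene margin)).

A gene is called up iff outlier p < 0.05, Fisher q < 0.05, FC vs
compendium > 2 and FC vs blood > 1.5; down mirrors with the negative
signed gates.

## Integration

The association between copy number and expression change is Spearman
rank correlation of per-gene CNV state with log2 FC vs compendium
(rank-based, hence invariant under monotone FC transforms), with a
seeded label-permutation p (default 10,000 permutations, two-sided on
|ρ|). Over-representation is the upper-tail hypergeometric with BH
across sets. The target table requires, per gene: at least one of
amplified (state ≥ 3), up-called, or non-synonymously mutated; at
least one pathway membership; at least one mapped drug — sorted by
evidence count then gene id, fully deterministic.

## Synthetic data: what it emulates, and what it does not

Depth tracks are window counts (1 kb default) with negative-binomial
noise, Var = μ + φμ², Poisson at φ = 0 (default φ = 0.01 for depth);
the tumor expectation is scaled by the state factor of the covering
truth segment (defaults 0.5, 1.0, 1.5, 2.5, 4.0 — chosen so states 1,
2, 3 and 5 sit on the HMM emission means; state 4's factor
deliberately reflects ~5 copies, between the state-4 and state-5
means). SNP tables carry the quality fields the filters consume;
genuine calls draw qualities clearing the strict gates, error sites
(rate per bp) draw systematically low qualities and 1–2 variant
reads. Somatic variant reads are Binomial(site depth, allele
fraction); planted allele fractions default to 0.5 (clonal
heterozygous, pure tumor) — note the ≥1/3 fraction gate itself rejects
~60% of true sites at VAF 0.3 and depth 30, so recovery benchmarks are
statements about clonal variants. Expression counts are NB around
gene-specific log-normal baselines; planted genes multiply the tumor
expectation by their effect size; library totals model the simulated
genes as ~10% of each library's aligned bases so a planted outlier
cannot meaningfully shift its own normalizer (the compositional caveat
of total-count normalization is real, and visible if the annotated
fraction is set to 1).

The generator does **not** model read-level artifacts (FASTQ,
alignment, GC/mappability bias), B-allele frequencies from raw counts,
subclonal structure beyond the 50/50 LOH mixture, or biological
compendium heterogeneity. The last point matters for interpreting the
DE benchmarks: the configured compendium dispersion is φ = 0.05
(coefficient of variation ≈ 0.23), the regime in which the printed
gates (outlier p < 0.05 with FC > 2) control the false-discovery rate
— measured null call rates are ~0.2–0.5% and planted-outlier FDR
≈ 0.05–0.1. Real tumor compendia are far more variable; at φ = 0.1
the same gates already admit ~3% of null genes (any
compendium-minimum gene has p = 2/51 by construction, and only the
fold-change gates stand between it and a call), so on real data this
procedure's effective FDR is substantially higher than the benchmark
suggests. Passing tests demonstrate correct mechanics and calibration
under the stated generative law, not performance on real libraries.

The packaged end-to-end scenario additionally tightens expression
dispersion to φ = 0.01 and embeds its 40 modelled genes in a
2,000-gene transcriptome, because its contract is exact: the report
must surface precisely the planted features (9 new mutations, 1
loss→gain and 1 gain→loss region, 1 copy-neutral LOH event only at
recurrence, 2 up and 2 down genes, the amplified over-expressed kinase
as top target). Planted scenario VAFs are 0.7 and truth LOH regions
keep ≥ 1 LOH-bin margin inside their copy-number context so bin-level
boundary jitter cannot create or destroy events.

## Numerical conventions and degenerate inputs

Viterbi runs entirely in log space; ties break toward the lower state
index, making decoding deterministic. Non-finite log ratios abort with
the offending bin named. Bins without SNPs are skipped with a warning.
Empty or unsorted tracks, probabilities outside [0, 1], variant reads
exceeding total reads, effect sizes ≤ 0, and truth outside the layout
all raise immediately. All randomness flows from one integer seed
through `numpy.random.Generator`; no global RNG state is touched.
Benchmarks and the reproducibility script use problem sizes that run
in seconds to a couple of minutes on a single core (≈2,000 bins for
copy number, ≈160 LOH bins, 500 planted variants, 2,000-gene
matrices, 200 permutation replicates).

## Known limitations

No ploidy/purity estimation; breakpoints are bin-resolution; no
indels or structural variants; no isoform-level expression; gene
models are single-interval CDS (no introns/UTRs); length (RPKM-style)
normalization is not applied — expression is normalized by library
total only; the amplitude separating amplification from high-level
amplification is a convention (emission means), not an estimate.
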