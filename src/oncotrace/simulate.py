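"""Synthetic tumor/normal sequencing data with planted ground truth.

Emulates the three input layers the pipeline consumes:

* paired normal/tumor read-depth tracks (piecewise-constant copy-number
  signal, negative-binomial count noise, Poisson in the zero-
  overdispersion limit);
* per-site SNP call tables (germline het/hom sites, regional allele
  loss, somatic variants at stated allele fractions, sequencing-error
  false positives with low quality scores);
* a tumor/blood/compendium expression matrix of aligned base counts
  with planted outlier genes.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` instances; identical seeds give identical
output. Quality scores are on the Phred scale; reads below Q10 are
assumed already dropped upstream, so tracks model post-filter counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout, TruthSet

#: Multiplicative tumor depth factor per copy-number state, relative to
#: the diploid normal. Conventions, configurable per call.
STATE_DEPTH_FACTOR = {1: 0.5, 2: 1.0, 3: 1.5, 4: 2.5, 5: 4.0}

BASES = np.array(list("ACGT"))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             overdispersion: float) -> np.ndarray:
    """Counts with E=mean and Var=mean+overdispersion*mean^2."""
    mean = np.asarray(mean, dtype=float)
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    if overdispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / overdispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_depth_tracks(
    layout: GenomeLayout,
    truth: TruthSet,
    mean_depth: float = 100.0,
    overdispersion: float = 0.01,
    window: int = 1000,
    timepoint: str = "T1",
    state_factor: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired (normal, tumor) window read-count tracks.

    ``mean_depth`` is the expected reads per window in the normal. The
    tumor expectation in a window is scaled by the depth factor of the
    truth CNV segment covering the window midpoint (neutral factor 1
    where uncovered).
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    factors = STATE_DEPTH_FACTOR if state_factor is None else state_factor
    truth.validate(layout)
    cnv = truth.cnv_for(timepoint)
    rng = np.random.default_rng(seed)

    frames_n, frames_t = [], []
    for chrom, length in layout.lengths.items():
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        frac = (ends - starts) / window
        mid = (starts + ends) / 2
        tumor_mean = np.full(len(starts), mean_depth, dtype=float)
        for row in cnv[cnv["chrom"] == chrom].itertuples(index=False):
            inside = (mid >= row.start) & (mid < row.end)
            tumor_mean[inside] = mean_depth * factors[int(row.state)]
        normal = _nb_draw(rng, mean_depth * frac, overdispersion)
        tumor = _nb_draw(rng, tumor_mean * frac, overdispersion)
        frames_n.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "count": normal}))
        frames_t.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "count": tumor}))
    return (pd.concat(frames_n, ignore_index=True),
            pd.concat(frames_t, ignore_index=True))


SNP_COLUMNS = [
    "chrom", "pos", "ref", "alt", "consensus_quality", "depth",
    "min_mapq", "base_quality", "variant_reads", "total_reads", "p_het",
]


@dataclass
class SnpCallSet:
    """Simulated SNP tables plus the germline site panel used."""

    normal: pd.DataFrame
    tumors: dict[str, pd.DataFrame]
    germline_sites: pd.DataFrame  # chrom, pos, genotype ('het'/'hom')
    somatic_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _good_qualities(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Quality fields for genuine calls: clear the strict tumor filter."""
    return {
        "consensus_quality": rng.integers(35, 70, n),
        "min_mapq": rng.integers(60, 95, n),
        "base_quality": rng.integers(25, 45, n),
    }


def _noise_qualities(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Quality fields for sequencing-error sites: systematically low."""
    return {
        "consensus_quality": rng.integers(0, 30, n),
        "min_mapq": rng.integers(0, 60, n),
        "base_quality": rng.integers(0, 25, n),
    }


def simulate_snp_calls(
    layout: GenomeLayout,
    truth: TruthSet,
    n_germline_sites: int = 2000,
    error_rate: float = 0.0,
    mean_depth: float = 30.0,
    het_fraction: float = 0.67,
    low_loh_hom_prob: float = 0.5,
    timepoints: tuple[str, ...] = ("T1",),
    seed: int = 0,
) -> SnpCallSet:
    """SNP call tables for the normal and each tumor timepoint.

    Germline het sites stay het in the tumor except inside truth LOH
    segments: in a 'high' segment they read hom (complete allelic
    loss), in a 'low' segment they read hom with probability
    ``low_loh_hom_prob`` (only part of the cell population lost the
    allele). Somatic variants appear only in their timepoint's table
    with variant reads ~ Binomial(site depth, allele fraction).
    ``error_rate`` is the per-bp rate of spurious low-quality candidate
    sites; it also sets the per-site zygosity misread probability.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error rate must lie in [0, 0.1]")
    if n_germline_sites > layout.total_length // 2:
        raise ValueError("n germline sites exceeds layout capacity")
    truth.validate(layout)
    rng = np.random.default_rng(seed)

    sites = _draw_site_panel(layout, truth, n_germline_sites, het_fraction, rng)
    normal = _germline_table(sites, mean_depth, rng)

    tumors: dict[str, pd.DataFrame] = {}
    for tp in timepoints:
        loh = truth.loh_for(tp)
        parts = [_tumor_germline_rows(sites, loh, mean_depth, error_rate,
                                      low_loh_hom_prob, rng)]
        som = truth.somatic_for(tp)
        if len(som):
            parts.append(_somatic_rows(som, mean_depth, rng))
        n_noise = rng.poisson(error_rate * layout.total_length)
        if n_noise:
            # error sites never coincide with planted somatic positions:
            # read support at a true site is governed by its allele
            # fraction (zero outside its timepoints), not by noise
            exclude = set(zip(truth.somatic_variants.get("chrom", []),
                              truth.somatic_variants.get("pos", [])))
            parts.append(_noise_rows(layout, n_noise, mean_depth, rng, exclude))
        table = pd.concat(parts, ignore_index=True)
        tumors[tp] = table.sort_values(["chrom", "pos"]).reset_index(drop=True)

    return SnpCallSet(normal=normal, tumors=tumors, germline_sites=sites,
                      somatic_truth=truth.somatic_variants.copy())


def _draw_site_panel(layout, truth, n_sites, het_fraction, rng) -> pd.DataFrame:
    """Germline SNP panel: truth het sites plus random filler sites."""
    rows = []
    fixed = truth.germline_het_sites
    for r in fixed.itertuples(index=False):
        rows.append((r.chrom, int(r.pos), "het"))
    n_extra = max(0, n_sites - len(rows))
    chroms = list(layout.lengths)
    probs = np.array([layout.lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    picks = rng.choice(len(chroms), n_extra, p=probs)
    taken = {(c, p) for c, p, _ in rows}
    taken |= set(zip(truth.somatic_variants.get("chrom", []),
                     truth.somatic_variants.get("pos", [])))
    for k in picks:
        chrom = chroms[k]
        pos = int(rng.integers(0, layout.lengths[chrom]))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        gt = "het" if rng.random() < het_fraction else "hom"
        rows.append((chrom, pos, gt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "genotype"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _ref_alt(rng, n):
    ref = BASES[rng.integers(0, 4, n)]
    alt = BASES[(np.char.find("ACGT", ref) + rng.integers(1, 4, n)) % 4]
    return ref, alt


def _germline_table(sites, mean_depth, rng) -> pd.DataFrame:
    n = len(sites)
    depth = np.maximum(1, rng.poisson(mean_depth, n))
    het = (sites["genotype"] == "het").to_numpy()
    var_reads = np.where(het, rng.binomial(depth, 0.5), depth)
    ref, alt = _ref_alt(rng, n)
    q = _good_qualities(rng, n)
    return pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(), "pos": sites["pos"].to_numpy(),
        "ref": ref, "alt": alt, **q, "depth": depth,
        "variant_reads": var_reads, "total_reads": depth,
        "p_het": np.where(het, rng.uniform(0.9, 1.0, n),
                          rng.uniform(0.0, 0.1, n)),
    })[SNP_COLUMNS]


def _tumor_germline_rows(sites, loh, mean_depth, error_rate,
                         low_hom_prob, rng) -> pd.DataFrame:
    n = len(sites)
    het = (sites["genotype"] == "het").to_numpy().copy()
    # regional allele loss flips het sites toward hom
    if len(loh):
        loh_state = np.full(n, "", dtype=object)
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy()
        for row in loh.itertuples(index=False):
            m = ((chrom_arr == row.chrom) & (pos_arr >= row.start)
                 & (pos_arr < row.end))
            loh_state[m] = row.state
        lost = (loh_state == "high") | (
            (loh_state == "low") & (rng.random(n) < low_hom_prob))
        het = het & ~lost
    # zygosity misreads at the stated error rate
    if error_rate > 0:
        flip = rng.random(n) < error_rate
        het = np.where(flip, ~het, het)
    depth = np.maximum(1, rng.poisson(mean_depth, n))
    var_reads = np.where(het, rng.binomial(depth, 0.5), depth)
    ref, alt = _ref_alt(rng, n)
    q = _good_qualities(rng, n)
    return pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(), "pos": sites["pos"].to_numpy(),
        "ref": ref, "alt": alt, **q, "depth": depth,
        "variant_reads": var_reads, "total_reads": depth,
        "p_het": np.where(het, rng.uniform(0.9, 1.0, n),
                          rng.uniform(0.0, 0.1, n)),
    })[SNP_COLUMNS]


def _somatic_rows(som, mean_depth, rng) -> pd.DataFrame:
    n = len(som)
    depth = np.maximum(8, rng.poisson(mean_depth, n))
    vaf = som["vaf"].astype(float).to_numpy()
    var_reads = rng.binomial(depth, vaf)
    q = _good_qualities(rng, n)
    return pd.DataFrame({
        "chrom": som["chrom"].to_numpy(), "pos": som["pos"].to_numpy(),
        "ref": som["ref"].to_numpy(), "alt": som["alt"].to_numpy(),
        **q, "depth": depth,
        "variant_reads": var_reads, "total_reads": depth,
        "p_het": rng.uniform(0.6, 1.0, n),
    })[SNP_COLUMNS]


def _noise_rows(layout, n_noise, mean_depth, rng,
                exclude: set | None = None) -> pd.DataFrame:
    chroms = list(layout.lengths)
    probs = np.array([layout.lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    picks = rng.choice(len(chroms), n_noise, p=probs)
    chrom = np.array(chroms)[picks]
    pos = np.array([rng.integers(0, layout.lengths[c]) for c in chrom])
    if exclude:
        keep = np.array([(c, p) not in exclude for c, p in zip(chrom, pos)])
        chrom, pos = chrom[keep], pos[keep]
        n_noise = len(pos)
    depth = np.maximum(1, rng.poisson(mean_depth, n_noise))
    var_reads = np.minimum(depth, 1 + rng.poisson(0.5, n_noise))
    ref, alt = _ref_alt(rng, n_noise)
    q = _noise_qualities(rng, n_noise)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, **q,
        "depth": depth, "variant_reads": var_reads, "total_reads": depth,
        "p_het": rng.uniform(0.3, 0.9, n_noise),
    })[SNP_COLUMNS]


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionMatrix:
    """Aligned-base counts per gene per library, with per-library totals.

    ``roles`` maps each library to 'tumor', 'blood' or 'compendium';
    ``totals`` are total aligned bases per library and may exceed the
    column sum (bases aligning outside the annotated gene set).
    """

    counts: pd.DataFrame  # genes x libraries
    roles: pd.Series  # library -> role
    totals: pd.Series  # library -> total aligned bases

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        colsum = self.counts.sum(axis=0)
        if (self.totals.reindex(self.counts.columns) < colsum).any():
            raise ValueError("library totals must cover the column sums")

    def libraries(self, role: str) -> list[str]:
        return [lib for lib, r in self.roles.items() if r == role]


def simulate_expression(
    n_genes: int = 2000,
    n_compendium: int = 50,
    truth_de: pd.DataFrame | None = None,
    dispersion: float = 0.05,
    baseline_mean: float = 2000.0,
    zero_inflated_genes: list[str] | None = None,
    zero_inflation: float = 0.9,
    tumor_libs: tuple[str, ...] = ("tumor_T1",),
    gene_ids: list[str] | None = None,
    annotated_fraction: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Tumor/blood/compendium count matrix with planted DE genes.

    Non-DE genes share one negative-binomial law across all libraries
    (gene-specific log-normal baseline mean). A gene in ``truth_de``
    has its tumor expectation multiplied by its effect size, versus
    both blood and the compendium. ``zero_inflated_genes`` drop out of
    compendium libraries with probability ``zero_inflation`` each, to
    exercise the low-information filter.

    Library totals model the whole transcriptome: the simulated genes
    make up ``annotated_fraction`` of each library's aligned bases and
    the remainder is un-modelled background, so a planted outlier
    cannot meaningfully shift its own library's normalizer (the usual
    compositional caveat of total-count normalization).
    """
    if n_compendium < 5:
        raise ValueError("need at least 5 compendium libraries")
    if truth_de is not None and len(truth_de):
        if (truth_de["effect_size"].astype(float) <= 0).any():
            raise ValueError("effect sizes must be positive")
    rng = np.random.default_rng(seed)

    if gene_ids is not None:
        genes = list(gene_ids)
        n_genes = len(genes)
    else:
        genes = [f"G{i:05d}" for i in range(n_genes)]
    libs = list(tumor_libs) + ["blood"] + [
        f"comp_{i:02d}" for i in range(n_compendium)]
    roles = pd.Series(
        {lib: ("tumor" if lib in tumor_libs else
               "blood" if lib == "blood" else "compendium") for lib in libs})

    base = np.exp(rng.normal(np.log(baseline_mean), 1.0, n_genes))
    effect = np.ones(n_genes)
    if truth_de is not None and len(truth_de):
        idx = {g: i for i, g in enumerate(genes)}
        for r in truth_de.itertuples(index=False):
            if r.gene_id in idx:
                effect[idx[r.gene_id]] = float(r.effect_size)

    cols = {}
    for lib in libs:
        mean = base * effect if roles[lib] == "tumor" else base
        cols[lib] = _nb_draw(rng, mean, dispersion)
    counts = pd.DataFrame(cols, index=genes)

    if zero_inflated_genes:
        comp = [lib for lib in libs if roles[lib] == "compendium"]
        zi = [g for g in zero_inflated_genes if g in counts.index]
        drop = rng.random((len(zi), len(comp))) < zero_inflation
        block = counts.loc[zi, comp].to_numpy()
        block[drop] = 0
        counts.loc[zi, comp] = block

    rest_mean = (1.0 / annotated_fraction - 1.0) * base.sum()
    rest = rng.poisson(rest_mean, len(libs))
    totals = pd.Series(
        counts.sum(axis=0).to_numpy(np.int64) + rest, index=libs)
    return ExpressionMatrix(counts=counts, roles=roles, totals=totals)
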