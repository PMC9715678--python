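"""Synthetic two-cell-type stranded modification experiment with planted truth.

Generates a miniature genome (sequence, genes, repeats), negative-binomial
expression tables, Poisson stranded modification reads with planted
differential clusters, nested strand-asymmetric domains and
expression-coupled gene-body signal, and TFBS sets with planted enrichment.
Every planted object is recorded in the returned truth tables; everything is
deterministic given the seed.

The generative model is this module's own stated assumption set, chosen so
that each downstream statistic has an analytically checkable expectation:
reads are drawn per 1-kb cell per strand from Poisson laws whose means
compose multiplicatively (baseline x cluster fold x gene-body factor) and
whose strand split is the planted plus-strand fraction of the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    InvalidParameterError,
    StrandedReadSet,
)

CELL_TYPES = ("D1", "D2")


@dataclass
class SimulationConfig:
    seed: int
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    # gene models
    n_genes: int = 300
    gene_length_range: tuple = (5_000, 30_000)
    gene_min_gap: int = 5_000
    gene_edge_margin: int = 10_000
    biotype_props: dict = field(
        default_factory=lambda: {"coding": 0.8, "lncRNA": 0.15, "other": 0.05}
    )
    family_props: dict = field(
        default_factory=lambda: {"ribosomal-like": 0.06, "olfactory-like": 0.06}
    )
    max_exons: int = 8
    # repeats
    n_repeats: int = 400
    repeat_length_range: tuple = (500, 5_000)
    repeat_family_template_frac: dict = field(
        default_factory=lambda: {"LINE": 0.8, "LTR": 0.7, "SINE": 0.6, "DNA": 0.5}
    )
    # sequence
    gc_content: float = 0.42
    ch_bias: float = 0.5  # P(G | C-or-G site) on the plus strand, outside genes
    gene_ch_template_bias: float = 0.5  # P(template-strand C | C-or-G site) in genes
    # expression
    rna_reads_per_sample: int = 1_000_000
    expr_log2_range: tuple = (0.0, 10.0)
    dispersion: float = 0.2
    silent_fraction: float = 0.15
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    n_replicates: int = 3
    # modification reads
    reads_per_sample: dict = field(
        default_factory=lambda: {"5mC": 500_000, "5hmC": 500_000, "input": 200_000}
    )
    fragment_length: dict = field(
        default_factory=lambda: {"5mC": 150, "5hmC": 250, "input": 150}
    )
    cell_size: int = 1_000
    assays: tuple = ("5mC", "5hmC", "input")
    # planted differential clusters
    n_clusters: int = 12
    cluster_span_range: tuple = (4_000, 300_000)
    cluster_fold: float = 4.0
    cluster_min_gap: int = 200_000
    # gene-body modification coupling
    mc_decile_factor_range: tuple = (1.0, 0.6)  # 5mC body factor, decile 1 -> 10
    tss_dip_depth: float = 0.8
    tss_dip_halfwidth: int = 500
    # strand-asymmetric domains (outside genes)
    large_domain_bp: int = 200_000
    small_domain_bp: int = 2_000
    domain_frac_range: tuple = (0.3, 0.7)
    small_domain_delta: float = 0.15
    # per-expression-stratum gene template fractions
    template_frac_silent: float = 0.50
    template_frac_deciles: tuple = tuple(np.round(np.linspace(0.51, 0.63, 10), 4))
    # TFBS
    n_tfs: int = 60
    n_enriched_tfs: int = 5
    sites_per_tf: int = 200
    site_length: int = 200
    enriched_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory")
        if self.dispersion <= 0:
            raise InvalidParameterError("dispersion must be > 0")
        for name, value in (
            ("gc_content", self.gc_content),
            ("ch_bias", self.ch_bias),
            ("gene_ch_template_bias", self.gene_ch_template_bias),
            ("silent_fraction", self.silent_fraction),
            ("enriched_fraction", self.enriched_fraction),
            ("tss_dip_depth", self.tss_dip_depth),
            ("template_frac_silent", self.template_frac_silent),
        ):
            if not (0.0 <= value <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {value}")
        for frac in self.template_frac_deciles:
            if not (0.0 <= frac <= 1.0):
                raise InvalidParameterError("decile template fractions must be in [0, 1]")
        if abs(sum(self.biotype_props.values()) - 1.0) > 1e-9:
            raise InvalidParameterError("biotype proportions must sum to 1")
        if sum(self.family_props.values()) > 1.0:
            raise InvalidParameterError("family proportions exceed 1")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chrom_sizes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["template_frac_deciles"] = [float(x) for x in self.template_frac_deciles]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in (
            "gene_length_range", "repeat_length_range", "expr_log2_range",
            "cluster_span_range", "mc_decile_factor_range", "domain_frac_range",
            "template_frac_deciles", "assays",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenome:
    layout: GenomeLayout
    sequences: dict
    genes: list
    gene_table: pd.DataFrame
    repeats: pd.DataFrame


def _place_intervals(
    rng: np.random.Generator,
    layout: GenomeLayout,
    lengths: Sequence[int],
    min_gap: int,
    edge_margin: int,
    max_tries_per_item: int = 200,
) -> list[tuple[str, int, int]]:
    """Place intervals without mutual overlap (plus min_gap separation)."""
    chroms = layout.chroms
    clens = np.array([layout.length(c) for c in chroms], dtype=float)
    probs = clens / clens.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out = []
    for length in lengths:
        ok = False
        for _ in range(max_tries_per_item):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            clen = layout.length(chrom)
            lo, hi = edge_margin, clen - edge_margin - length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length
            if all(
                end + min_gap <= s or start >= e + min_gap for s, e in placed[chrom]
            ):
                placed[chrom].append((start, end))
                out.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise InvalidParameterError(
                "could not place non-overlapping intervals; use a larger genome "
                "or fewer/smaller features"
            )
    return out


def _random_exons(
    rng: np.random.Generator, start: int, end: int, max_exons: int
) -> tuple[tuple[int, int], ...]:
    length = end - start
    n_exons = int(rng.integers(1, max_exons + 1))
    if n_exons == 1 or length < 2 * n_exons * 50:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
    edges = np.concatenate([[0], cuts, [length]]) + start
    return tuple((int(edges[i]), int(edges[i + 1])) for i in range(0, 2 * n_exons - 1, 2))


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedGenome:
    """Random genome sequence, non-overlapping gene models and repeats."""
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[0]
    )
    layout = config.layout

    # genes
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    spots = _place_intervals(
        rng, layout, lengths, config.gene_min_gap, config.gene_edge_margin
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    biotypes = rng.choice(
        list(config.biotype_props),
        size=config.n_genes,
        p=list(config.biotype_props.values()),
    )
    families = np.full(config.n_genes, None, dtype=object)
    coding_idx = np.flatnonzero(biotypes == "coding")
    fam_names = list(config.family_props)
    fam_probs = list(config.family_props.values())
    if fam_names and len(coding_idx):
        draw = rng.choice(
            fam_names + [None],
            size=len(coding_idx),
            p=fam_probs + [1.0 - sum(fam_probs)],
        )
        families[coding_idx] = draw

    genes = []
    for i, ((chrom, start, end), strand, biotype, family) in enumerate(
        zip(spots, strands, biotypes, families)
    ):
        exons = (
            _random_exons(rng, start, end, config.max_exons)
            if biotype == "coding"
            else ((start, end),)
        )
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                interval=GenomicInterval(chrom, start, end, strand),
                biotype=str(biotype),
                family=family,
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    gene_table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.interval.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "strand": [g.strand for g in genes],
            "biotype": [g.biotype for g in genes],
            "family": [g.family if g.family else "" for g in genes],
        }
    )

    # repeats (may overlap genes; not each other constraint not needed)
    fam_list = list(config.repeat_family_template_frac)
    rep_rows = []
    chroms = layout.chroms
    clens = np.array([layout.length(c) for c in chroms], dtype=float)
    rprobs = clens / clens.sum()
    rep_cols = ["chrom", "start", "end", "name", "score", "strand"]
    rep_lengths = rng.integers(
        config.repeat_length_range[0],
        config.repeat_length_range[1] + 1,
        config.n_repeats,
    )
    for i in range(config.n_repeats):
        chrom = chroms[rng.choice(len(chroms), p=rprobs)]
        clen = layout.length(chrom)
        start = int(rng.integers(0, clen - int(rep_lengths[i])))
        rep_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + int(rep_lengths[i]),
                "name": fam_list[i % len(fam_list)],
                "score": 0,
                "strand": str(rng.choice(["+", "-"])),
            }
        )
    repeats = (
        pd.DataFrame(rep_rows, columns=rep_cols)
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )

    # sequence with per-region CH strand bias
    sequences = {}
    for chrom in chroms:
        clen = layout.length(chrom)
        bias = np.full(clen, config.ch_bias)  # P(G | C-or-G) on plus strand
        if config.gene_ch_template_bias != 0.5:
            for g in genes:
                if g.interval.chrom != chrom:
                    continue
                # template-strand C == reference G for plus genes
                b = (
                    config.gene_ch_template_bias
                    if g.strand == "+"
                    else 1.0 - config.gene_ch_template_bias
                )
                bias[g.interval.start : g.interval.end] = b
        u = rng.random(clen)
        at_half = (1.0 - config.gc_content) / 2.0
        base = np.full(clen, b"T"[0], dtype=np.uint8)
        base[u < at_half] = b"A"[0]
        cg = u >= 2 * at_half
        is_g = rng.random(clen) < bias
        base[cg & is_g] = b"G"[0]
        base[cg & ~is_g] = b"C"[0]
        sequences[chrom] = base.tobytes().decode("ascii")

    return SimulatedGenome(
        layout=layout,
        sequences=sequences,
        genes=genes,
        gene_table=gene_table,
        repeats=repeats,
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count tables for both cell types plus truth labels.

    Returns (counts, truth): counts indexed by gene_id with one column per
    rna sample; truth carries planted means, DE labels, log2 fold changes
    and the planted expression decile ("silent" for zero-mean genes).
    """
    if config.dispersion <= 0:
        raise InvalidParameterError("dispersion must be > 0")
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[1]
    )
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    lo, hi = config.expr_log2_range
    weight = 2.0 ** rng.uniform(lo, hi, n)

    families = np.array([g.family if g.family else "" for g in genes], dtype=object)
    silent = rng.random(n) < config.silent_fraction
    silent |= families == "olfactory-like"  # forced silent
    weight[silent] = 0.0
    weight[families == "ribosomal-like"] = 2.0 ** hi  # forced top decile

    # planted DE genes among ordinary expressed genes
    eligible = np.flatnonzero((~silent) & (families == ""))
    n_de = min(config.n_de_genes, len(eligible))
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    log2fc = np.zeros(n)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    log2fc[de_idx] = signs * config.de_log2fc

    mean_a = weight * 2.0 ** (log2fc / 2.0)
    mean_b = weight * 2.0 ** (-log2fc / 2.0)

    counts = {}
    for ct, means in (("D1", mean_a), ("D2", mean_b)):
        tot = means.sum()
        lam = means / tot * config.rna_reads_per_sample if tot > 0 else means
        shape = 1.0 / config.dispersion
        for rep in range(1, config.n_replicates + 1):
            noisy = np.where(
                lam > 0, rng.gamma(shape, 1.0, size=n) * lam / shape, 0.0
            )
            counts[f"{ct}_rna_r{rep}"] = rng.poisson(noisy)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))

    # planted decile over non-silent genes by planted weight (ties by order)
    decile = np.full(n, "silent", dtype=object)
    expressed = np.flatnonzero(weight > 0)
    order = expressed[np.argsort(weight[expressed], kind="mergesort")]
    chunks = np.array_split(order, 10)
    for d, idx in enumerate(chunks, start=1):
        decile[idx] = f"q{d}"

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "weight": weight,
            "mean_D1": mean_a,
            "mean_D2": mean_b,
            "de": log2fc != 0.0,
            "log2fc": log2fc,
            "decile": decile,
            "family": families,
        }
    ).set_index("gene_id")
    return counts_df, truth


# ---------------------------------------------------------------------------
# Modification reads
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    clusters: pd.DataFrame  # chrom/start/end/direction/fold
    domains: pd.DataFrame  # chrom/start/end/plus_frac/scale
    gene_truth: pd.DataFrame  # expression truth + planted template fractions
    enriched_tfs: list = field(default_factory=list)

    def differential_windows(self, window_size: int = 1000) -> pd.DataFrame:
        """All tiling windows inside planted clusters (the expected calls)."""
        rows = []
        for c in self.clusters.itertuples(index=False):
            for s in range(c.start, c.end, window_size):
                rows.append(
                    {
                        "chrom": c.chrom,
                        "start": s,
                        "end": min(s + window_size, c.end),
                        "direction": c.direction,
                    }
                )
        return pd.DataFrame(rows)


def _plant_clusters(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Plant differential clusters so the truth is recoverable in principle.

    Under the gap/density clustering rule two same-direction clusters with
    n1 and n2 significant 1-kb windows merge whenever their gap is below
    ~(n1 + n2) / density_threshold window widths; planted same-direction
    clusters are therefore separated by more than 8 x (span_i + span_j)
    plus a margin, so the planted partition is the unique fixpoint.
    """
    if config.n_clusters == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction", "fold"])
    w = config.cell_size
    lo, hi = config.cluster_span_range
    spans = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_clusters))
    spans = (np.maximum((spans // w).astype(int), 1) * w).astype(int)
    order = np.argsort(spans)[::-1]  # place big ones first
    directions = {}
    for rank, idx in enumerate(order):
        directions[idx] = "D1-up" if rank % 2 == 0 else "D2-up"

    chroms = config.layout.chroms
    clens = np.array([config.layout.length(c) for c in chroms], dtype=float)
    probs = clens / clens.sum()
    placed: list[dict] = []
    margin = config.cluster_min_gap
    for idx in order:
        span = int(spans[idx])
        direction = directions[idx]
        ok = False
        for _ in range(500):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            clen = config.layout.length(chrom)
            hi_pos = clen - span - w
            if hi_pos <= w:
                continue
            start = int(rng.integers(w, hi_pos)) // w * w
            end = start + span
            good = True
            for p in placed:
                if p["chrom"] != chrom:
                    continue
                gap = max(p["start"] - end, start - p["end"])
                need = (
                    8 * (span + (p["end"] - p["start"])) + margin
                    if p["direction"] == direction
                    else margin
                )
                if gap < need:
                    good = False
                    break
            if good:
                placed.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "direction": direction,
                        "fold": config.cluster_fold,
                    }
                )
                ok = True
                break
        if not ok:
            raise InvalidParameterError(
                "could not place merge-safe clusters; use a larger genome or "
                "fewer/smaller clusters"
            )
    return (
        pd.DataFrame(placed).sort_values(["chrom", "start"]).reset_index(drop=True)
    )


def _plant_domains(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Two-scale nested plus-strand-fraction domains covering the genome.

    Large-domain fractions are drawn uniformly and then re-centred to mean
    0.5 per chromosome, so chromosome-scale strand bias (which would
    confound the very-large-window concordance control) is exactly zero by
    construction.
    """
    rows = []
    f_lo, f_hi = config.domain_frac_range
    for chrom in config.layout.chroms:
        clen = config.layout.length(chrom)
        large_edges = np.arange(0, clen + config.large_domain_bp, config.large_domain_bp)
        large_edges = np.clip(large_edges, 0, clen)
        n_large = int((np.diff(large_edges) > 0).sum())
        bases = rng.uniform(f_lo, f_hi, size=n_large)
        if n_large > 1 and f_hi > f_lo:
            bases = np.clip(bases - bases.mean() + 0.5, 0.05, 0.95)
        k = 0
        for i in range(len(large_edges) - 1):
            ls, le = int(large_edges[i]), int(large_edges[i + 1])
            if le <= ls:
                continue
            base = float(bases[k])
            k += 1
            rows.append(
                {"chrom": chrom, "start": ls, "end": le, "plus_frac": base, "scale": "large"}
            )
            small_edges = np.arange(ls, le + config.small_domain_bp, config.small_domain_bp)
            small_edges = np.clip(small_edges, ls, le)
            for j in range(len(small_edges) - 1):
                ss, se = int(small_edges[j]), int(small_edges[j + 1])
                if se <= ss:
                    continue
                delta = rng.uniform(-config.small_domain_delta, config.small_domain_delta)
                frac = float(np.clip(base + delta, 0.05, 0.95))
                rows.append(
                    {"chrom": chrom, "start": ss, "end": se, "plus_frac": frac, "scale": "small"}
                )
    return pd.DataFrame(rows)


_DECILE_INDEX = {f"q{i}": i - 1 for i in range(1, 11)}


def _gene_template_fraction(config: SimulationConfig, decile: str) -> float:
    if decile == "silent":
        return config.template_frac_silent
    return float(config.template_frac_deciles[_DECILE_INDEX[decile]])


def simulate_modification_reads(
    config: SimulationConfig,
    genome: SimulatedGenome,
    expression_truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[dict, SimulationTruth]:
    """Stranded read sets for every cell type x assay x replicate + truth.

    Per cell of the 1-kb grid the Poisson mean composes multiplicatively:
    baseline x cluster fold (for the up cell type inside planted clusters)
    x gene-body factor (5mC decreasing with expression decile; 5hmC flat
    with a TSS dip scaled by expression).  The strand split is the planted
    per-decile template fraction inside genes and the nested two-scale
    domain fraction elsewhere; input reads are uniform and balanced.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[2]
    )
    layout = genome.layout
    w = config.cell_size

    clusters = _plant_clusters(config, rng)
    domains = _plant_domains(config, rng)
    small_domains = domains[domains["scale"] == "small"]

    # planted per-gene template fraction from the expression decile
    gene_truth = expression_truth.copy()
    gene_truth["template_frac"] = [
        _gene_template_fraction(config, d) for d in gene_truth["decile"]
    ]

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genome.genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)

    # per-chromosome cell grids
    grids = {}
    mc_lo, mc_hi = config.mc_decile_factor_range
    for chrom in layout.chroms:
        clen = layout.length(chrom)
        starts = np.arange(0, clen, w, dtype=np.int64)
        ends = np.minimum(starts + w, clen)
        mids = (starts + ends) // 2
        n_cells = len(starts)

        plus_frac = np.full(n_cells, 0.5)
        sd = small_domains[small_domains["chrom"] == chrom]
        if len(sd):
            idx = np.searchsorted(sd["start"].to_numpy(), mids, side="right") - 1
            idx = np.clip(idx, 0, len(sd) - 1)
            inside = (mids >= sd["start"].to_numpy()[idx]) & (
                mids < sd["end"].to_numpy()[idx]
            )
            plus_frac[inside] = sd["plus_frac"].to_numpy()[idx[inside]]

        # repeat elements override the local domain fraction (genes, applied
        # below, take precedence over repeats)
        for r in genome.repeats[genome.repeats["chrom"] == chrom].itertuples(index=False):
            fam_frac = config.repeat_family_template_frac.get(r.name)
            if fam_frac is None:
                continue
            in_rep = (mids >= r.start) & (mids < r.end)
            # template-style: fam_frac of reads on the strand opposite the element
            plus_frac[in_rep] = fam_frac if r.strand == "-" else 1.0 - fam_frac

        factor_mc = np.ones(n_cells)
        factor_hmc = np.ones(n_cells)
        for g in genes_by_chrom.get(chrom, []):
            in_gene = (mids >= g.interval.start) & (mids < g.interval.end)
            info = gene_truth.loc[g.gene_id]
            tf = float(info["template_frac"])
            # template strand is opposite the gene strand
            plus_frac[in_gene] = 1.0 - tf if g.strand == "+" else tf
            decile = info["decile"]
            expr_scale = 0.0 if decile == "silent" else _DECILE_INDEX[decile] / 9.0
            factor_mc[in_gene] = mc_lo + (mc_hi - mc_lo) * expr_scale
            dip_sel = np.abs(mids - g.tss) <= config.tss_dip_halfwidth
            factor_hmc[dip_sel] *= 1.0 - config.tss_dip_depth * expr_scale

        cluster_fold = {ct: np.ones(n_cells) for ct in CELL_TYPES}
        for c in clusters[clusters["chrom"] == chrom].itertuples(index=False):
            sel = (mids >= c.start) & (mids < c.end)
            up_ct = "D1" if c.direction == "D1-up" else "D2"
            cluster_fold[up_ct][sel] = c.fold

        grids[chrom] = {
            "starts": starts,
            "widths": (ends - starts).astype(np.int64),
            "plus_frac": plus_frac,
            "factor": {"5mC": factor_mc, "5hmC": factor_hmc, "input": np.ones(n_cells)},
            "cluster_fold": cluster_fold,
        }

    samples: dict[str, StrandedReadSet] = {}
    for assay in config.assays:
        frag = int(config.fragment_length.get(assay, 150))
        target = int(config.reads_per_sample.get(assay, 0))
        if target <= 0:
            continue
        for ct in CELL_TYPES:
            weights = {}
            total_weight = 0.0
            for chrom, grid in grids.items():
                # weight composes baseline(=1) x cluster fold x gene factor
                wgt = grid["factor"][assay] * (
                    grid["cluster_fold"][ct] if assay != "input" else 1.0
                )
                if np.any(wgt < 0) or not np.all(np.isfinite(wgt)):
                    raise InvalidParameterError("invalid expected density")
                weights[chrom] = wgt
                total_weight += float(wgt.sum())
            for rep in range(1, config.n_replicates + 1):
                reads = {}
                for chrom, grid in grids.items():
                    lam = weights[chrom] / total_weight * target
                    pf = grid["plus_frac"] if assay != "input" else 0.5
                    k_plus = rng.poisson(lam * pf)
                    k_minus = rng.poisson(lam * (1.0 - pf))
                    clen = layout.length(chrom)
                    parts = []
                    for k_arr, code in ((k_plus, 1), (k_minus, -1)):
                        cell_ids = np.repeat(np.arange(len(k_arr)), k_arr)
                        if len(cell_ids) == 0:
                            continue
                        offs = rng.integers(
                            0, grid["widths"][cell_ids], size=len(cell_ids)
                        )
                        centers = grid["starts"][cell_ids] + offs
                        starts_r = np.clip(centers - frag // 2, 0, clen - frag)
                        parts.append(
                            (
                                starts_r,
                                starts_r + frag,
                                np.full(len(starts_r), code, dtype=np.int8),
                            )
                        )
                    if parts:
                        reads[chrom] = {
                            "starts": np.concatenate([p[0] for p in parts]),
                            "ends": np.concatenate([p[1] for p in parts]),
                            "strands": np.concatenate([p[2] for p in parts]),
                        }
                sid = f"{ct}_{assay}_r{rep}"
                samples[sid] = StrandedReadSet(
                    sample_id=sid,
                    cell_type=ct,
                    assay=assay,
                    replicate=rep,
                    reads=reads,
                )

    truth = SimulationTruth(
        clusters=clusters, domains=domains, gene_truth=gene_truth
    )
    return samples, truth


# ---------------------------------------------------------------------------
# TFBS
# ---------------------------------------------------------------------------


def simulate_tfbs(
    config: SimulationConfig,
    layout: GenomeLayout,
    differential_windows: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[dict, list]:
    """TFBS BED sets with a planted enriched subset.

    Enriched TFs place ``enriched_fraction`` of their sites uniformly inside
    the given differential windows, the remainder uniform genome-wide; null
    TFs are fully uniform.  Returns ({tf: frame}, enriched_tf_names).
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[3]
    )
    chroms = layout.chroms
    clens = np.array([layout.length(c) for c in chroms], dtype=float)
    L = config.site_length
    valid = clens - L + 1
    if (valid <= 0).all():
        raise InvalidParameterError("site length exceeds every chromosome")
    probs = valid / valid.sum()

    n_enriched = config.n_enriched_tfs
    if n_enriched and not len(differential_windows):
        raise InvalidParameterError(
            "cannot plant enriched TFs without differential windows"
        )

    def uniform_sites(k: int) -> pd.DataFrame:
        ci = rng.choice(len(chroms), size=k, p=probs)
        offs = (rng.random(k) * valid[ci]).astype(np.int64)
        return pd.DataFrame(
            {
                "chrom": np.array(chroms, dtype=object)[ci],
                "start": offs,
                "end": offs + L,
            }
        )

    def in_window_sites(k: int) -> pd.DataFrame:
        wi = rng.integers(0, len(differential_windows), size=k)
        rows = differential_windows.iloc[wi]
        ws = rows["start"].to_numpy(np.int64)
        we = rows["end"].to_numpy(np.int64)
        span = np.maximum(we - ws - L, 1)
        offs = ws + (rng.random(k) * span).astype(np.int64)
        return pd.DataFrame(
            {"chrom": rows["chrom"].to_numpy(), "start": offs, "end": offs + L}
        )

    tf_sets = {}
    enriched = []
    for i in range(config.n_tfs):
        name = f"TF{i:03d}"
        if i < n_enriched:
            k_in = int(round(config.enriched_fraction * config.sites_per_tf))
            df = pd.concat(
                [in_window_sites(k_in), uniform_sites(config.sites_per_tf - k_in)],
                ignore_index=True,
            )
            enriched.append(name)
        else:
            df = uniform_sites(config.sites_per_tf)
        df["name"] = name
        df["score"] = 0
        df["strand"] = "."
        tf_sets[name] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return tf_sets, enriched


# ---------------------------------------------------------------------------
# End-to-end bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    genome: SimulatedGenome
    expression_counts: pd.DataFrame
    truth: SimulationTruth
    samples: dict
    tfbs: dict

    def read_sets(self, cell_type: str, assay: str) -> list:
        return [
            s
            for s in self.samples.values()
            if s.cell_type == cell_type and s.assay == assay
        ]


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run all simulation stages with stage-isolated child RNG streams."""
    streams = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
    ]
    genome = simulate_genome(config, rng=streams[0])
    expr_counts, expr_truth = simulate_expression(config, genome.genes, rng=streams[1])
    samples, truth = simulate_modification_reads(
        config, genome, expr_truth, rng=streams[2]
    )
    diff_windows = truth.differential_windows(config.cell_size)
    tfbs, enriched = simulate_tfbs(config, genome.layout, diff_windows, rng=streams[3])
    truth.enriched_tfs = enriched
    return SimulatedExperiment(
        config=config,
        genome=genome,
        expression_counts=expr_counts,
        truth=truth,
        samples=samples,
        tfbs=tfbs,
    )
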