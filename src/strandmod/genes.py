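"""Gene-centric integration: expression strata, metagene profiles, merged
per-gene differential verdicts and modification-expression coupling."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GenomeLayout, InvalidParameterError, StrandedReadSet

SILENT = "silent"
EXCLUDED = "excluded"


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def cpm_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million; columns are samples, rows genes."""
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        raise InvalidParameterError("sample with zero total counts")
    return counts * 1e6 / libs


def stratify_expression(
    mean_cpm: pd.Series,
    n_strata: int = 10,
    expressed_cpm: float = 1.0,
    silent_cpm: float = 0.2,
) -> pd.Series:
    """Stratum label per gene: silent / excluded / q1..qN (qN = highest).

    Expressed genes (mean CPM >= expressed_cpm) split into ``n_strata``
    equal-size rank groups; genes below ``silent_cpm`` are silent; the
    in-between band is excluded from strata.  Ties broken by gene_id order.
    """
    if n_strata < 2:
        raise InvalidParameterError("n_strata must be >= 2")
    labels = pd.Series(EXCLUDED, index=mean_cpm.index, dtype=object)
    labels[mean_cpm < silent_cpm] = SILENT
    expressed = mean_cpm[mean_cpm >= expressed_cpm]
    if len(expressed) < n_strata:
        raise InvalidParameterError(
            f"only {len(expressed)} expressed genes for {n_strata} strata"
        )
    order = expressed.reset_index()
    order.columns = ["gene_id", "cpm"]
    order = order.sort_values(["cpm", "gene_id"], kind="mergesort")
    chunks = np.array_split(np.arange(len(order)), n_strata)
    for q, idx in enumerate(chunks, start=1):
        labels[order.iloc[idx]["gene_id"]] = f"q{q}"
    return labels


def expression_summary(
    counts: pd.DataFrame,
    sample_cell_types: Mapping[str, str],
    n_strata: int = 10,
    expressed_cpm: float = 1.0,
    silent_cpm: float = 0.2,
) -> pd.DataFrame:
    """Per-gene mean CPM per cell type, overall mean, and stratum label."""
    cpm = cpm_table(counts)
    cell_types = sorted(set(sample_cell_types.values()))
    out = pd.DataFrame(index=counts.index)
    for ct in cell_types:
        cols = [s for s, c in sample_cell_types.items() if c == ct]
        out[f"cpm_{ct}"] = cpm[cols].mean(axis=1)
    out["mean_cpm"] = cpm.mean(axis=1)
    out["stratum"] = stratify_expression(
        out["mean_cpm"], n_strata=n_strata,
        expressed_cpm=expressed_cpm, silent_cpm=silent_cpm,
    )
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------


def _gene_bins(gene: GeneModel, flank_bp: int, body_bins: int, flank_bin_bp: int):
    """Bin edges (ascending genomic coords) and the 5'->3' orientation flag."""
    n_flank = flank_bp // flank_bin_bp
    iv = gene.interval
    if gene.strand == "+":
        up = np.arange(iv.start - flank_bp, iv.start + 1, flank_bin_bp)
        body = np.linspace(iv.start, iv.end, body_bins + 1)
        down = np.arange(iv.end, iv.end + flank_bp + 1, flank_bin_bp)
        edges = np.concatenate([up[:-1], body[:-1], down])
        flip = False
    else:
        up = np.arange(iv.end, iv.end + flank_bp + 1, flank_bin_bp)
        body = np.linspace(iv.start, iv.end, body_bins + 1)
        down = np.arange(iv.start - flank_bp, iv.start + 1, flank_bin_bp)
        edges = np.concatenate([down[:-1], body[:-1], up])
        flip = True
    return np.round(edges).astype(np.int64), flip, 2 * n_flank + body_bins


def metagene_profile(
    read_sets: Sequence[StrandedReadSet] | StrandedReadSet,
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    flank_bp: int = 2000,
    body_bins: int = 100,
    flank_bin_bp: int = 50,
    strata: pd.Series | None = None,
    strand_mode: str = "combined",
) -> dict:
    """Mean read density (CPM/bp) in flank + length-normalized body bins.

    Profiles are oriented 5'->3' by gene strand: bin 0 is the far upstream
    flank bin.  ``strand_mode`` "combined" returns one matrix per stratum
    row; "template-vs-coding" returns two (keys "template" and "coding").
    Genes shorter than ``body_bins`` bp, or whose flanks leave the
    chromosome, are skipped and reported.
    """
    if strand_mode not in ("combined", "template-vs-coding"):
        raise InvalidParameterError(f"unknown strand_mode {strand_mode!r}")
    if isinstance(read_sets, StrandedReadSet):
        read_sets = [read_sets]
    lib = sum(rs.library_size for rs in read_sets)

    usable, skipped = [], []
    for g in genes:
        clen = layout.length(g.interval.chrom)
        if len(g.interval) < body_bins:
            skipped.append((g.gene_id, "short"))
        elif g.interval.start - flank_bp < 0 or g.interval.end + flank_bp > clen:
            skipped.append((g.gene_id, "flank-out-of-bounds"))
        else:
            usable.append(g)

    stratum_of = (lambda g: strata.get(g.gene_id)) if strata is not None else (lambda g: "all")
    strata_names = sorted({s for s in (stratum_of(g) for g in usable) if s is not None})
    n_bins = 2 * (flank_bp // flank_bin_bp) + body_bins

    keys = ("combined",) if strand_mode == "combined" else ("template", "coding")
    sums = {k: {s: np.zeros(n_bins) for s in strata_names} for k in keys}
    n_genes = {s: 0 for s in strata_names}

    for g in usable:
        stratum = stratum_of(g)
        if stratum is None:
            continue
        edges, flip, nb = _gene_bins(g, flank_bp, body_bins, flank_bin_bp)
        widths = np.diff(edges).astype(float)
        per_strand = {"+": np.zeros(nb), "-": np.zeros(nb)}
        for rs in read_sets:
            for strand_name, code in (("+", 1), ("-", -1)):
                mids = rs.sorted_midpoints(g.interval.chrom, code)
                cum = np.searchsorted(mids, edges, side="left")
                per_strand[strand_name] += np.diff(cum)
        dens = {k: per_strand[k] / widths / lib * 1e6 for k in per_strand}
        if flip:
            dens = {k: v[::-1] for k, v in dens.items()}
        if strand_mode == "combined":
            sums["combined"][stratum] += dens["+"] + dens["-"]
        else:
            tmpl = g.template_strand
            cod = "+" if tmpl == "-" else "-"
            sums["template"][stratum] += dens[tmpl]
            sums["coding"][stratum] += dens[cod]
        n_genes[stratum] += 1

    profiles = {}
    for k in keys:
        mat = pd.DataFrame(
            {
                s: (sums[k][s] / n_genes[s] if n_genes[s] else np.full(n_bins, np.nan))
                for s in strata_names
            }
        ).T
        mat.index.name = "stratum"
        profiles[k] = mat
    return {
        "profiles": profiles,
        "n_genes": n_genes,
        "skipped": skipped,
        "n_flank_bins": flank_bp // flank_bin_bp,
        "body_bins": body_bins,
    }


# ---------------------------------------------------------------------------
# Merged per-gene differential verdicts
# ---------------------------------------------------------------------------


def merge_gene_calls(
    tss_results: pd.DataFrame,
    body_results: pd.DataFrame,
    window_results: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank: int = 2000,
) -> dict:
    """Evidence sets per gene: TSS / body unit significance plus any
    significant window overlapping [gene start - flank, gene end + flank).

    TSS and body results are keyed by unit_id = gene_id.  Returns the gene
    call table and evidence-combination counts (Venn cells).
    """
    sig_tss = set(tss_results.loc[tss_results["significant"], "unit_id"])
    sig_body = set(body_results.loc[body_results["significant"], "unit_id"])
    sig_win = window_results[window_results["significant"]]
    win_by_chrom = {c: g for c, g in sig_win.groupby("chrom", sort=False)}

    rows = []
    for g in genes:
        evidence = []
        details = {}
        if g.gene_id in sig_tss:
            evidence.append("TSS")
            r = tss_results.set_index("unit_id").loc[g.gene_id]
            details["tss_log2fc"], details["tss_padj"] = r["log2fc"], r["padj"]
        if g.gene_id in sig_body:
            evidence.append("body")
            r = body_results.set_index("unit_id").loc[g.gene_id]
            details["body_log2fc"], details["body_padj"] = r["log2fc"], r["padj"]
        wins = win_by_chrom.get(g.interval.chrom)
        if wins is not None:
            lo, hi = g.interval.start - flank, g.interval.end + flank
            hit = wins[(wins["start"] < hi) & (wins["end"] > lo)]
            if len(hit):
                evidence.append("window")
                details["n_windows"] = len(hit)
                dirs = set(hit["direction"])
                details["window_direction"] = dirs.pop() if len(dirs) == 1 else "mixed"
        if evidence:
            rows.append({"gene_id": g.gene_id, "evidence": "+".join(evidence), **details})
    calls = pd.DataFrame(rows)
    venn = (
        calls["evidence"].value_counts().to_dict() if len(calls) else {}
    )
    return {"calls": calls, "venn": venn}


# ---------------------------------------------------------------------------
# Modification / expression coupling
# ---------------------------------------------------------------------------


def correlate_mod_expression(
    mod_log2fc: pd.Series, mrna_log2fc: pd.Series
) -> dict:
    """Pearson/Spearman and least-squares fit of mRNA fold change on
    modification fold change over the shared gene subset."""
    joined = pd.concat([mod_log2fc, mrna_log2fc], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise InvalidParameterError("need >= 3 genes with both fold changes")
    x = joined.iloc[:, 0].to_numpy(float)
    y = joined.iloc[:, 1].to_numpy(float)
    if np.allclose(x, x[0]):
        raise InvalidParameterError("modification fold changes have zero variance")
    fit = stats.linregress(x, y)
    return {
        "n": len(joined),
        "pearson": float(stats.pearsonr(x, y).statistic),
        "spearman": float(stats.spearmanr(x, y).statistic),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_stderr": float(fit.stderr),
    }


CAT_LESS = "less-expressed-where-more-5hmC"
CAT_MORE = "more-expressed-where-more-5hmC"
CAT_MIXED = "mixed-windows"
CAT_NOT_DE = "not-DE"


def classify_hmc_expression_direction(
    hmc_window_results: pd.DataFrame,
    genes: Sequence[GeneModel],
    de_table: pd.DataFrame,
    flank: int = 2000,
    exclude_gene_ids: set[str] | None = None,
) -> dict:
    """Relate per-gene 5hmC window direction to differential expression.

    ``de_table`` is indexed by gene_id with ``de`` (bool) and ``log2fc``
    (A over B, matching the window test orientation).  Genes in
    ``exclude_gene_ids`` (e.g. also 5mC-significant) are dropped.  Returns
    per-gene categories and category fractions.
    """
    sig_win = hmc_window_results[hmc_window_results["significant"]]
    win_by_chrom = {c: g for c, g in sig_win.groupby("chrom", sort=False)}
    rows = []
    for g in genes:
        if exclude_gene_ids and g.gene_id in exclude_gene_ids:
            continue
        wins = win_by_chrom.get(g.interval.chrom)
        if wins is None:
            continue
        lo, hi = g.interval.start - flank, g.interval.end + flank
        hit = wins[(wins["start"] < hi) & (wins["end"] > lo)]
        if not len(hit):
            continue
        dirs = set(hit["direction"])
        if len(dirs) > 1:
            cat = CAT_MIXED
        elif g.gene_id not in de_table.index or not bool(de_table.loc[g.gene_id, "de"]):
            cat = CAT_NOT_DE
        else:
            mrna_up_in_a = de_table.loc[g.gene_id, "log2fc"] > 0
            hmc_up_in_a = dirs.pop() == "A-up"
            cat = CAT_MORE if mrna_up_in_a == hmc_up_in_a else CAT_LESS
        rows.append({"gene_id": g.gene_id, "category": cat})
    table = pd.DataFrame(rows)
    if len(table):
        fractions = (table["category"].value_counts() / len(table)).to_dict()
    else:
        fractions = {}
    return {"table": table, "fractions": fractions}
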