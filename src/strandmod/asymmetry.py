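"""Strand-asymmetry statistics for stranded modification reads and sequence.

The central quantity for unoriented regions is |plus - minus| / (plus +
minus); gene-oriented regions use the template ratio template / total where
the template strand is the strand opposite the annotated gene strand.
Regions with fewer than ``min_reads`` total reads are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    InvalidParameterError,
    StrandedReadSet,
    overlap_any,
)

DEFAULT_MIN_READS = 20


def asymmetry_coefficient(
    plus: int, minus: int, min_reads: int = DEFAULT_MIN_READS
) -> float | None:
    """|plus - minus| / total, or None when total < min_reads (incl. 0/0)."""
    if plus < 0 or minus < 0:
        raise InvalidParameterError("read counts must be non-negative")
    total = plus + minus
    if total < min_reads:
        return None
    return abs(plus - minus) / total


def coefficient_array(
    plus: np.ndarray, minus: np.ndarray, min_reads: int = DEFAULT_MIN_READS
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized coefficient; returns (values, pass_filter mask)."""
    plus = np.asarray(plus, dtype=np.int64)
    minus = np.asarray(minus, dtype=np.int64)
    total = plus + minus
    ok = total >= max(min_reads, 1)
    coef = np.full(len(total), np.nan)
    coef[ok] = np.abs(plus[ok] - minus[ok]) / total[ok]
    return coef, total >= min_reads


# ---------------------------------------------------------------------------
# Random window sampling
# ---------------------------------------------------------------------------


def sample_windows(
    layout: GenomeLayout,
    size: int,
    n: int = 10_000,
    rng: np.random.Generator | int | None = None,
    exclusion: pd.DataFrame | None = None,
    max_tries: int = 50,
) -> pd.DataFrame:
    """Uniformly placed fixed-size windows, fully inside chromosome bounds.

    Chromosomes are chosen with probability proportional to their number of
    valid placements; sampling is with replacement.  Windows overlapping the
    exclusion set are re-drawn (bounded retries).
    """
    rng = np.random.default_rng(rng)
    chroms = [c for c in layout.chroms if layout.length(c) >= size]
    if not chroms:
        raise InvalidParameterError(f"window size {size} exceeds every chromosome")
    valid = np.array([layout.length(c) - size + 1 for c in chroms], dtype=np.float64)
    probs = valid / valid.sum()

    excl_by_chrom: dict[str, pd.DataFrame] = {}
    if exclusion is not None and len(exclusion):
        excl_by_chrom = {c: g for c, g in exclusion.groupby("chrom", sort=False)}

    if not excl_by_chrom:
        ci = rng.choice(len(chroms), size=n, p=probs)
        offs = (rng.random(n) * valid[ci]).astype(np.int64)
        return pd.DataFrame(
            {
                "chrom": np.array(chroms, dtype=object)[ci],
                "start": offs,
                "end": offs + size,
            }
        )

    chosen_chrom = np.empty(n, dtype=object)
    chosen_start = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    for _ in range(max_tries):
        if len(pending) == 0:
            break
        ci = rng.choice(len(chroms), size=len(pending), p=probs)
        offs = (rng.random(len(pending)) * valid[ci]).astype(np.int64)
        ok = np.ones(len(pending), dtype=bool)
        for k, (c_idx, off) in enumerate(zip(ci, offs)):
            chrom = chroms[c_idx]
            excl = excl_by_chrom.get(chrom)
            if excl is not None:
                hit = overlap_any(
                    np.array([off]),
                    np.array([off + size]),
                    excl["start"].to_numpy(),
                    excl["end"].to_numpy(),
                )
                if hit[0]:
                    ok[k] = False
                    continue
            chosen_chrom[pending[k]] = chrom
            chosen_start[pending[k]] = off
        pending = pending[~ok]
    if len(pending):
        raise InvalidParameterError(
            "could not place sampled windows outside the exclusion set"
        )
    df = pd.DataFrame(
        {"chrom": chosen_chrom, "start": chosen_start, "end": chosen_start + size}
    )
    return df


def _stranded_counts(read_set: StrandedReadSet, windows: pd.DataFrame):
    plus = np.zeros(len(windows), dtype=np.int64)
    minus = np.zeros(len(windows), dtype=np.int64)
    pos = windows.reset_index(drop=True)
    for chrom, grp in pos.groupby("chrom", sort=False):
        p, m = read_set.count_in(
            chrom, grp["start"].to_numpy(), grp["end"].to_numpy()
        )
        plus[grp.index.to_numpy()] = p
        minus[grp.index.to_numpy()] = m
    return plus, minus


def asymmetry_by_size(
    read_set: StrandedReadSet,
    layout: GenomeLayout,
    sizes: Sequence[int],
    n: int = 10_000,
    seed: int | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    exclusion: pd.DataFrame | None = None,
) -> dict:
    """Coefficient distribution over random windows, per window size.

    Returns {"summary": DataFrame(size, n_evaluated, median, q1, q3),
    "coefficients": {size: ndarray}}.
    """
    rng = np.random.default_rng(seed)
    summaries = []
    coefs: dict[int, np.ndarray] = {}
    for size in sizes:
        win = sample_windows(layout, size, n=n, rng=rng, exclusion=exclusion)
        plus, minus = _stranded_counts(read_set, win)
        coef, ok = coefficient_array(plus, minus, min_reads=min_reads)
        vals = coef[ok]
        coefs[size] = vals
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        summaries.append(
            {"size": size, "n_evaluated": int(len(vals)), "median": med, "q1": q1, "q3": q3}
        )
    return {"summary": pd.DataFrame(summaries), "coefficients": coefs}


# ---------------------------------------------------------------------------
# Asymmetric-region size estimation (adjacent-pair concordance)
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceCurve:
    table: pd.DataFrame  # size, n_adjacent, adjacent_frac, n_random, random_frac


def _majority_sign(plus, minus, min_reads):
    total = plus + minus
    sign = np.sign(plus - minus)
    valid = (total >= min_reads) & (sign != 0)  # ties have no majority
    return sign, valid


def concordance_curve(
    read_set: StrandedReadSet,
    layout: GenomeLayout,
    sizes: Sequence[int],
    n: int = 10_000,
    seed: int | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    exclusion: pd.DataFrame | None = None,
) -> ConcordanceCurve:
    """Majority-strand concordance of adjacent same-size window pairs.

    Per size: windows are sampled at random; each is paired with its
    immediately downstream neighbour (skipped when out of bounds) and, as a
    control, with an independently sampled random window.  Windows below
    ``min_reads`` or with a plus/minus tie are excluded.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        win = sample_windows(layout, size, n=n, rng=rng, exclusion=exclusion)
        rand = sample_windows(layout, size, n=n, rng=rng, exclusion=exclusion)
        nb = win.copy()
        nb["start"] = nb["end"]
        nb["end"] = nb["start"] + size
        in_bounds = np.array(
            [e <= layout.length(c) for c, e in zip(nb["chrom"], nb["end"])]
        )
        p_w, m_w = _stranded_counts(read_set, win)
        p_r, m_r = _stranded_counts(read_set, rand)
        nb_valid = nb[in_bounds]
        p_n = np.zeros(len(win), dtype=np.int64)
        m_n = np.zeros(len(win), dtype=np.int64)
        if len(nb_valid):
            p_nv, m_nv = _stranded_counts(read_set, nb_valid)
            p_n[in_bounds] = p_nv
            m_n[in_bounds] = m_nv

        s_w, v_w = _majority_sign(p_w, m_w, min_reads)
        s_n, v_n = _majority_sign(p_n, m_n, min_reads)
        s_r, v_r = _majority_sign(p_r, m_r, min_reads)
        v_n &= in_bounds

        adj_mask = v_w & v_n
        rnd_mask = v_w & v_r
        adj_frac = float((s_w[adj_mask] == s_n[adj_mask]).mean()) if adj_mask.any() else np.nan
        rnd_frac = float((s_w[rnd_mask] == s_r[rnd_mask]).mean()) if rnd_mask.any() else np.nan
        rows.append(
            {
                "size": size,
                "n_adjacent": int(adj_mask.sum()),
                "adjacent_frac": adj_frac,
                "n_random": int(rnd_mask.sum()),
                "random_frac": rnd_frac,
            }
        )
    return ConcordanceCurve(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Gene template ratios
# ---------------------------------------------------------------------------


def gene_template_ratio(
    read_set: StrandedReadSet, gene: GeneModel, min_reads: int = DEFAULT_MIN_READS
) -> float | None:
    """template / (template + coding) over the gene body, or None if excluded."""
    iv = gene.interval
    plus, minus = read_set.count_in(
        iv.chrom, np.array([iv.start]), np.array([iv.end])
    )
    p, m = int(plus[0]), int(minus[0])
    total = p + m
    if total < min_reads:
        return None
    template = m if gene.strand == "+" else p
    return template / total


def gene_template_ratios(
    read_set: StrandedReadSet,
    genes: Sequence[GeneModel],
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Vectorized per-gene template ratios; one row per gene."""
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.interval.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    )
    plus, minus = _stranded_counts(read_set, df)
    total = plus + minus
    template = np.where(df["strand"] == "+", minus, plus)
    ratio = np.full(len(df), np.nan)
    nz = total > 0
    ratio[nz] = template[nz] / total[nz]
    df["plus"] = plus
    df["minus"] = minus
    df["total"] = total
    df["template_ratio"] = ratio
    df["pass_filter"] = total >= min_reads
    return df


def asymmetry_by_expression(
    gene_ratios: pd.DataFrame, strata: pd.Series
) -> pd.DataFrame:
    """Template-ratio distribution per expression stratum.

    ``strata`` maps gene_id -> stratum label (from expression stratification).
    Only genes passing the read filter contribute.
    """
    df = gene_ratios[gene_ratios["pass_filter"]].copy()
    df["stratum"] = df["gene_id"].map(strata)
    df = df.dropna(subset=["stratum"])
    rows = []
    for stratum, grp in df.groupby("stratum", sort=True):
        q1, med, q3 = np.percentile(grp["template_ratio"], [25, 50, 75])
        rows.append(
            {
                "stratum": stratum,
                "n_genes": len(grp),
                "median": med,
                "q1": q1,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeat-family asymmetry
# ---------------------------------------------------------------------------


def repeat_family_asymmetry(
    read_set: StrandedReadSet,
    repeats: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    known_families: Sequence[str] | None = None,
) -> dict:
    """Per-element coefficients and orientation-relative ratios, by family.

    ``repeats`` is a BED6-style frame whose name field carries the family.
    Elements are oriented by their annotated strand: ``oriented_ratio`` is
    the fraction of reads on the strand opposite the element (template-style),
    so families can show directional bias; the unsigned coefficient is
    reported alongside.  Unknown families group under "other".
    """
    df = repeats.copy()
    df["family"] = df["name"].astype(str)
    if known_families is not None:
        df.loc[~df["family"].isin(known_families), "family"] = "other"
    plus, minus = _stranded_counts(read_set, df)
    total = plus + minus
    coef, ok = coefficient_array(plus, minus, min_reads=min_reads)
    anti = np.where(df["strand"] == "+", minus, plus)
    oriented = np.full(len(df), np.nan)
    nz = total > 0
    oriented[nz] = anti[nz] / total[nz]
    df["plus"] = plus
    df["minus"] = minus
    df["coefficient"] = coef
    df["oriented_ratio"] = oriented
    df["pass_filter"] = ok
    passed = df[df["pass_filter"]]
    rows = []
    for family, grp in passed.groupby("family", sort=True):
        rows.append(
            {
                "family": family,
                "n_elements": len(grp),
                "median_coefficient": float(np.median(grp["coefficient"])),
                "median_oriented_ratio": float(np.median(grp["oriented_ratio"])),
            }
        )
    return {"elements": df, "summary": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# CH-content asymmetry from sequence
# ---------------------------------------------------------------------------

_CH_BYTES = {b: i for i, b in enumerate(b"ACGT")}


def ch_counts(sequence: str) -> tuple[int, int]:
    """Count CH dinucleotide starts on each strand of a sequence.

    CH+ counts positions i < L-1 with s[i] = C and s[i+1] in {A, C, T};
    CH- counts positions i > 0 with s[i] = G and s[i-1] in {A, G, T}
    (i.e. a C on the reverse strand followed 3' by a non-G).  Positions
    whose relevant neighbour is N (or any non-ACGT code) are not counted.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    if len(arr) < 2:
        return 0, 0
    a = arr[:-1]
    b = arr[1:]
    C, G = ord("C"), ord("G")
    acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    valid_pair = acgt[:-1] & acgt[1:]
    ch_plus = int(((a == C) & (b != G) & valid_pair).sum())
    ch_minus = int(((b == G) & (a != C) & valid_pair).sum())
    return ch_plus, ch_minus


def ch_asymmetry(sequence: str) -> float | None:
    """|CH+ - CH-| / (CH+ + CH-); None when the denominator is zero."""
    ch_plus, ch_minus = ch_counts(sequence)
    total = ch_plus + ch_minus
    if total == 0:
        return None
    return abs(ch_plus - ch_minus) / total


def ch_template_ratio(sequence: str, gene_strand: str) -> float | None:
    """Fraction of CH starts on the template strand of a gene's sequence."""
    ch_plus, ch_minus = ch_counts(sequence)
    total = ch_plus + ch_minus
    if total == 0:
        return None
    template = ch_minus if gene_strand == "+" else ch_plus
    return template / total


def ch_asymmetry_regions(
    sequences: Mapping[str, str], regions: pd.DataFrame
) -> pd.DataFrame:
    """CH coefficients for BED-style regions against a FASTA-derived genome."""
    rows = []
    for row in regions.itertuples(index=False):
        seq = sequences[row.chrom][row.start : row.end]
        cp, cm = ch_counts(seq)
        total = cp + cm
        rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "ch_plus": cp,
                "ch_minus": cm,
                "coefficient": abs(cp - cm) / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-assay / cross-cell-type correlations
# ---------------------------------------------------------------------------


def asymmetry_correlations(
    record_sets: Mapping[str, pd.DataFrame], value_col: str = "template_ratio"
) -> pd.DataFrame:
    """Pairwise Spearman correlations of per-region ratios across record sets.

    Each record set is a frame with ``gene_id`` (or ``region_id``),
    ``pass_filter`` and the value column.  Pairs sharing fewer than 3
    passing regions are reported as NaN.
    """
    names = list(record_sets)
    keyed = {}
    for name, df in record_sets.items():
        key = "gene_id" if "gene_id" in df.columns else "region_id"
        sel = df[df["pass_filter"]] if "pass_filter" in df.columns else df
        keyed[name] = sel.set_index(key)[value_col]
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        mat.loc[a, a] = 1.0
        for b in names[i + 1 :]:
            joined = pd.concat([keyed[a], keyed[b]], axis=1, join="inner").dropna()
            if len(joined) < 3:
                continue
            rho = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
            mat.loc[a, b] = rho
            mat.loc[b, a] = rho
    return mat
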