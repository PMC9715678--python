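"""TFBS overlap with significant windows and permutation z-scores.

Observed statistic: number of significant windows overlapping at least one
binding site (each window counted once).  The null is built by relocating
every site uniformly among all genome positions where it fits, ``n_shuffles``
times; z = (observed - null_mean) / null_sd.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, InvalidParameterError, overlap_any


@dataclass
class EnrichmentResult:
    tf: str
    observed: int
    null_mean: float
    null_sd: float
    z: float | None
    pct_windows: float


def _windows_by_chrom(sig_windows: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in sig_windows.groupby("chrom", sort=False):
        out[chrom] = (grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64))
    return out


def overlap_count(sig_windows: pd.DataFrame, sites: pd.DataFrame) -> int:
    """Number of significant windows overlapping >= 1 site by >= 1 bp."""
    total = 0
    site_by_chrom = {c: g for c, g in sites.groupby("chrom", sort=False)}
    for chrom, grp in sig_windows.groupby("chrom", sort=False):
        s = site_by_chrom.get(chrom)
        if s is None:
            continue
        hit = overlap_any(
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            s["start"].to_numpy(),
            s["end"].to_numpy(),
        )
        total += int(hit.sum())
    return total


def shuffle_intervals(
    sites: pd.DataFrame,
    layout: GenomeLayout,
    rng: np.random.Generator | int | None = None,
    exclusion: pd.DataFrame | None = None,
    max_tries: int = 100,
) -> pd.DataFrame:
    """Relocate each interval uniformly among all positions where it fits.

    Chromosomes are chosen proportional to their number of valid placements
    for that interval's length; lengths are preserved.  Placements
    overlapping the exclusion set are redrawn (bounded retries).
    """
    rng = np.random.default_rng(rng)
    lengths = (sites["end"] - sites["start"]).to_numpy(np.int64)
    chroms = layout.chroms
    clens = np.array([layout.length(c) for c in chroms], dtype=np.int64)
    if lengths.max(initial=0) > clens.max(initial=0):
        raise InvalidParameterError("an interval is longer than every chromosome")

    # valid placements per (site, chromosome)
    valid = np.maximum(clens[None, :] - lengths[:, None] + 1, 0).astype(float)
    row_tot = valid.sum(axis=1)
    if (row_tot == 0).any():
        raise InvalidParameterError("an interval fits no chromosome")
    cum = np.cumsum(valid, axis=1)

    excl_by_chrom: dict[str, pd.DataFrame] = {}
    if exclusion is not None and len(exclusion):
        excl_by_chrom = {c: g for c, g in exclusion.groupby("chrom", sort=False)}

    n = len(sites)
    out_chrom = np.empty(n, dtype=object)
    out_start = np.zeros(n, dtype=np.int64)
    pending = np.arange(n)
    for _ in range(max_tries):
        if len(pending) == 0:
            break
        u = rng.random(len(pending)) * row_tot[pending]
        ci = (u[:, None] >= cum[pending]).sum(axis=1)
        offs = (rng.random(len(pending)) * valid[pending, ci]).astype(np.int64)
        if not excl_by_chrom:
            out_chrom[pending] = np.array(chroms, dtype=object)[ci]
            out_start[pending] = offs
            pending = pending[:0]
            break
        keep = np.ones(len(pending), dtype=bool)
        for k, (idx, c_idx, off) in enumerate(zip(pending, ci, offs)):
            chrom = chroms[c_idx]
            excl = excl_by_chrom.get(chrom)
            if excl is not None:
                hit = overlap_any(
                    np.array([off]),
                    np.array([off + lengths[idx]]),
                    excl["start"].to_numpy(),
                    excl["end"].to_numpy(),
                )
                if hit[0]:
                    keep[k] = False
                    continue
            out_chrom[idx] = chrom
            out_start[idx] = off
        pending = pending[~keep]
    if len(pending):
        raise InvalidParameterError(
            "could not place shuffled intervals outside the exclusion set"
        )
    shuffled = sites.copy()
    shuffled["chrom"] = out_chrom
    shuffled["start"] = out_start
    shuffled["end"] = out_start + lengths
    return shuffled


def tfbs_zscore(
    sig_windows: pd.DataFrame,
    tfbs_sets: Mapping[str, pd.DataFrame],
    layout: GenomeLayout,
    n_shuffles: int = 100,
    seed: int | None = None,
    exclusion: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation enrichment per TF, ranked by z (descending).

    Columns: tf, n_sites, observed, null_mean, null_sd, z, pct_windows.
    z is NaN when the null sd is zero.
    """
    if n_shuffles < 2:
        raise InvalidParameterError("n_shuffles must be >= 2")
    rng = np.random.default_rng(seed)
    n_windows = len(sig_windows)
    rows = []
    for tf in sorted(tfbs_sets):
        sites = tfbs_sets[tf]
        if not len(sites):
            raise InvalidParameterError(f"TF {tf!r} has no binding sites")
        observed = overlap_count(sig_windows, sites)
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            shuffled = shuffle_intervals(sites, layout, rng=rng, exclusion=exclusion)
            null[i] = overlap_count(sig_windows, shuffled)
        null_mean = float(null.mean())
        null_sd = float(null.std(ddof=1))
        z = (observed - null_mean) / null_sd if null_sd > 0 else np.nan
        rows.append(
            {
                "tf": tf,
                "n_sites": len(sites),
                "observed": observed,
                "null_mean": null_mean,
                "null_sd": null_sd,
                "z": z,
                "pct_windows": observed / n_windows if n_windows else np.nan,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["z", "tf"], ascending=[False, True], kind="mergesort", na_position="last"
    )
    return out.reset_index(drop=True)
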