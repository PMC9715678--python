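"""Build differentially modified regions from significant tiled windows.

Two-stage rule: significant same-direction windows less than ``gap_bp``
apart are grouped into seeds; seeds then greedily absorb the nearest
same-direction significant window on either side as long as the density of
significant windows over the merged span stays strictly above
``density_threshold``.  Clusters need at least ``min_sig`` significant
windows to be emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .genome import GenomicInterval, overlap_any_df


@dataclass
class ModCluster:
    interval: GenomicInterval
    direction: str
    member_ids: tuple[str, ...]
    n_sig: int
    n_total: int

    @property
    def density(self) -> float:
        return self.n_sig / self.n_total

    @property
    def span(self) -> int:
        return len(self.interval)


def _span_windows(span_bp: int, window_size: int) -> int:
    return math.ceil(span_bp / window_size)


class _Group:
    __slots__ = ("rows", "start", "end")

    def __init__(self, rows: list[int], start: int, end: int) -> None:
        self.rows = rows
        self.start = start
        self.end = end

    @property
    def n_sig(self) -> int:
        return len(self.rows)


def _prepare(sig_windows: pd.DataFrame) -> pd.DataFrame:
    df = sig_windows.copy()
    required = {"chrom", "start", "end", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sig_windows missing columns: {sorted(missing)}")
    if "unit_id" not in df.columns:
        df["unit_id"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def seed_clusters(sig_windows: pd.DataFrame, gap_bp: int = 5000) -> list[list[str]]:
    """Group consecutive same-direction significant windows with gaps < gap_bp.

    The gap is the bp between the end of one window and the start of the next
    same-direction window; opposite-direction windows never join a group (and
    do not bridge one).  Returns lists of unit_ids.
    """
    df = _prepare(sig_windows)
    groups: list[list[str]] = []
    for (_, _), grp in df.groupby(["chrom", "direction"], sort=True):
        current: list[str] = []
        prev_end = None
        for row in grp.itertuples(index=False):
            if prev_end is not None and row.start - prev_end < gap_bp:
                current.append(row.unit_id)
            else:
                if current:
                    groups.append(current)
                current = [row.unit_id]
            prev_end = row.end
        if current:
            groups.append(current)
    return groups


def extend_clusters(
    sig_windows: pd.DataFrame,
    gap_bp: int = 5000,
    density_threshold: float = 1 / 8,
    window_size: int = 1000,
    min_sig: int = 2,
) -> list[ModCluster]:
    """Seed by the gap rule, then greedily extend until no merge passes.

    Extension runs per chromosome and direction to a fixpoint: each group
    repeatedly tries to absorb the nearest neighbouring group's closest
    window (left candidate first on distance ties); a merge is accepted iff
    significant-window density over the merged span, with denominator
    ceil(span / window_size), exceeds ``density_threshold`` strictly.
    """
    df = _prepare(sig_windows)
    clusters: list[ModCluster] = []
    for (chrom, direction), grp in df.groupby(["chrom", "direction"], sort=True):
        grp = grp.reset_index(drop=True)
        # seeds via the gap rule, expressed as row-index groups
        groups: list[_Group] = []
        current: list[int] = []
        prev_end = None
        for i, row in enumerate(grp.itertuples(index=False)):
            if prev_end is not None and row.start - prev_end < gap_bp:
                current.append(i)
            else:
                if current:
                    groups.append(_make_group(grp, current))
                current = [i]
            prev_end = row.end
        if current:
            groups.append(_make_group(grp, current))

        groups = _extend_to_fixpoint(grp, groups, density_threshold, window_size)

        for g in sorted(groups, key=lambda g: g.start):
            n_total = _span_windows(g.end - g.start, window_size)
            if g.n_sig >= min_sig and g.n_sig / n_total > density_threshold:
                clusters.append(
                    ModCluster(
                        interval=GenomicInterval(chrom, g.start, g.end),
                        direction=direction,
                        member_ids=tuple(grp.loc[g.rows, "unit_id"]),
                        n_sig=g.n_sig,
                        n_total=n_total,
                    )
                )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return clusters


def _make_group(grp: pd.DataFrame, rows: list[int]) -> _Group:
    return _Group(
        rows=list(rows),
        start=int(grp.loc[rows, "start"].min()),
        end=int(grp.loc[rows, "end"].max()),
    )


def _extend_to_fixpoint(
    grp: pd.DataFrame,
    groups: list[_Group],
    density_threshold: float,
    window_size: int,
) -> list[_Group]:
    changed = True
    while changed:
        changed = False
        groups.sort(key=lambda g: g.start)
        i = 0
        while i < len(groups):
            g = groups[i]
            left_open, right_open = True, True
            while left_open or right_open:
                left = groups[i - 1] if i > 0 else None
                right = groups[i + 1] if i + 1 < len(groups) else None
                dist_left = g.start - left.end if (left_open and left) else None
                dist_right = right.start - g.end if (right_open and right) else None
                # nearest candidate; left first on ties
                if dist_left is not None and (
                    dist_right is None or dist_left <= dist_right
                ):
                    side, cand = "left", left
                elif dist_right is not None:
                    side, cand = "right", right
                else:
                    break
                new_start = min(g.start, cand.start)
                new_end = max(g.end, cand.end)
                n_sig = g.n_sig + cand.n_sig
                n_total = _span_windows(new_end - new_start, window_size)
                if n_sig / n_total > density_threshold:
                    g.rows = sorted(g.rows + cand.rows)
                    g.start, g.end = new_start, new_end
                    if side == "left":
                        groups.pop(i - 1)
                        i -= 1
                    else:
                        groups.pop(i + 1)
                    changed = True
                elif side == "left":
                    left_open = False
                else:
                    right_open = False
            i += 1
    return groups


def clusters_to_frame(clusters: list[ModCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in clusters],
            "start": [c.interval.start for c in clusters],
            "end": [c.interval.end for c in clusters],
            "direction": [c.direction for c in clusters],
            "n_sig": [c.n_sig for c in clusters],
            "n_total": [c.n_total for c in clusters],
            "density": [c.density for c in clusters],
            "span": [c.span for c in clusters],
        }
    )


def summarize_clusters(
    clusters: list[ModCluster],
    genes=None,
    other_clusters: list[ModCluster] | None = None,
    other_sig_windows: pd.DataFrame | None = None,
    n_sig_windows_total: int | None = None,
    large_span_bp: int = 100_000,
) -> dict:
    """Per-cluster report plus headline aggregates.

    Returns a dict with a ``table`` DataFrame (span, overlapping genes,
    large-cluster and cross-assay flags) and scalar summaries including the
    fraction of significant windows that were grouped into clusters.
    """
    table = clusters_to_frame(clusters)
    table["large"] = table["span"] > large_span_bp if len(table) else pd.Series(dtype=bool)

    if genes:
        gene_df = pd.DataFrame(
            {
                "chrom": [g.interval.chrom for g in genes],
                "start": [g.interval.start for g in genes],
                "end": [g.interval.end for g in genes],
                "gene_id": [g.gene_id for g in genes],
            }
        )
        overlaps = []
        for c in clusters:
            sel = gene_df[
                (gene_df["chrom"] == c.interval.chrom)
                & (gene_df["start"] < c.interval.end)
                & (gene_df["end"] > c.interval.start)
            ]
            overlaps.append(",".join(sel["gene_id"]))
        table["genes"] = overlaps

    if other_clusters is not None and len(table):
        other = clusters_to_frame(other_clusters)
        table["overlaps_other_cluster"] = overlap_any_df(table, other)
    if other_sig_windows is not None and len(table):
        table["overlaps_other_window"] = overlap_any_df(
            table, other_sig_windows[["chrom", "start", "end"]]
        )

    n_grouped = int(sum(c.n_sig for c in clusters))
    summary = {
        "table": table,
        "n_clusters": len(clusters),
        "n_large": int(table["large"].sum()) if len(table) else 0,
        "n_sig_windows_grouped": n_grouped,
    }
    if n_sig_windows_total:
        summary["fraction_grouped"] = n_grouped / n_sig_windows_total
    return summary
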