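"""Genomic coordinate model, window tiling, read counting and feature assignment.

All coordinates are 0-based half-open (BED-native).  The only place 1-based
coordinates may appear is in human-readable report text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

FEATURE_PRECEDENCE = ("TSS", "exon", "intron", "TTS", "lncRNA", "intergenic")


class InvalidParameterError(ValueError):
    """A parameter violates an operation's preconditions."""


class UnknownChromosomeError(KeyError):
    """A record refers to a chromosome absent from the genome layout."""


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome-name -> length (bp) map."""

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        sizes = dict(self.chrom_sizes)
        if len(sizes) != len(self.chrom_sizes):
            raise InvalidParameterError("duplicate chromosome names in layout")
        for name, length in sizes.items():
            if int(length) <= 0:
                raise InvalidParameterError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
        object.__setattr__(self, "chrom_sizes", sizes)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def __len__(self) -> int:
        return len(self.chrom_sizes)

    def length(self, chrom: str) -> int:
        try:
            return int(self.chrom_sizes[chrom])
        except KeyError:
            raise UnknownChromosomeError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_sizes.values()))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise InvalidParameterError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure, biotype and optional family tag.

    ``tss``/``tts`` follow the annotated strand: for a plus-strand gene the
    TSS is ``interval.start``, for a minus-strand gene it is ``interval.end``.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "coding"
    family: str | None = None
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in (PLUS, MINUS):
            raise InvalidParameterError(f"gene {self.gene_id} must be stranded")
        if not self.exons:
            object.__setattr__(
                self, "exons", ((self.interval.start, self.interval.end),)
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == PLUS else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand == PLUS else self.interval.start

    @property
    def template_strand(self) -> str:
        """Strand complementary to the mRNA (the non-coding strand)."""
        return MINUS if self.strand == PLUS else PLUS


# ---------------------------------------------------------------------------
# Stranded read sets
# ---------------------------------------------------------------------------

_STRAND_CODE = {PLUS: 1, MINUS: -1}


class StrandedReadSet:
    """Per-sample stranded fragment intervals, stored as per-chromosome arrays.

    ``reads[chrom]`` is a dict with int64 arrays ``starts``, ``ends`` and an
    int8 ``strands`` array coded +1 / -1.
    """

    def __init__(
        self,
        sample_id: str,
        cell_type: str,
        assay: str,
        replicate: int,
        reads: Mapping[str, dict[str, np.ndarray]],
        layout: GenomeLayout | None = None,
    ) -> None:
        self.sample_id = sample_id
        self.cell_type = cell_type
        self.assay = assay
        self.replicate = int(replicate)
        self.reads = {c: dict(a) for c, a in reads.items()}
        self._midpoint_cache: dict[tuple[str, int], np.ndarray] = {}
        if layout is not None:
            self.validate_bounds(layout)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_intervals(
        cls,
        sample_id: str,
        cell_type: str,
        assay: str,
        replicate: int,
        intervals: Iterable[GenomicInterval],
        layout: GenomeLayout | None = None,
    ) -> "StrandedReadSet":
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for iv in intervals:
            if iv.strand not in _STRAND_CODE:
                raise InvalidParameterError(
                    f"read {iv.chrom}:{iv.start}-{iv.end} must be stranded"
                )
            by_chrom.setdefault(iv.chrom, []).append(
                (iv.start, iv.end, _STRAND_CODE[iv.strand])
            )
        reads = {}
        for chrom, rows in by_chrom.items():
            arr = np.asarray(rows, dtype=np.int64)
            reads[chrom] = {
                "starts": arr[:, 0],
                "ends": arr[:, 1],
                "strands": arr[:, 2].astype(np.int8),
            }
        return cls(sample_id, cell_type, assay, replicate, reads, layout=layout)

    # -- basic properties ----------------------------------------------------

    @property
    def library_size(self) -> int:
        return int(sum(len(a["starts"]) for a in self.reads.values()))

    def chroms(self) -> list[str]:
        return list(self.reads)

    def validate_bounds(self, layout: GenomeLayout) -> None:
        for chrom, arrs in self.reads.items():
            clen = layout.length(chrom)  # raises on unknown chromosome
            if len(arrs["starts"]) and (
                arrs["starts"].min() < 0 or arrs["ends"].max() > clen
            ):
                raise InvalidParameterError(
                    f"sample {self.sample_id}: read out of bounds on {chrom}"
                )

    def iter_intervals(self) -> Iterator[GenomicInterval]:
        for chrom, arrs in self.reads.items():
            strands = np.where(arrs["strands"] > 0, PLUS, MINUS)
            for s, e, st in zip(arrs["starts"], arrs["ends"], strands):
                yield GenomicInterval(chrom, int(s), int(e), str(st))

    # -- counting support ----------------------------------------------------

    def sorted_midpoints(self, chrom: str, strand_code: int) -> np.ndarray:
        """Sorted fragment midpoints for one chromosome and strand (+1/-1)."""
        key = (chrom, strand_code)
        cached = self._midpoint_cache.get(key)
        if cached is None:
            arrs = self.reads.get(chrom)
            if arrs is None:
                cached = np.empty(0, dtype=np.int64)
            else:
                sel = arrs["strands"] == strand_code
                mids = (arrs["starts"][sel] + arrs["ends"][sel]) // 2
                cached = np.sort(mids)
            self._midpoint_cache[key] = cached
        return cached

    def count_in(self, chrom: str, starts: np.ndarray, ends: np.ndarray):
        """Stranded midpoint counts for arbitrary (possibly overlapping) regions.

        Returns ``(plus, minus)`` int64 arrays aligned with the inputs.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = []
        for code in (1, -1):
            mids = self.sorted_midpoints(chrom, code)
            out.append(
                np.searchsorted(mids, ends, side="left")
                - np.searchsorted(mids, starts, side="left")
            )
        return out[0], out[1]


def pool_read_sets(read_sets: Sequence[StrandedReadSet]) -> StrandedReadSet:
    """Merge replicate read sets into one pooled set (shared cell type/assay)."""
    if not read_sets:
        raise InvalidParameterError("cannot pool an empty list of read sets")
    cell_types = {r.cell_type for r in read_sets}
    assays = {r.assay for r in read_sets}
    merged: dict[str, dict[str, list[np.ndarray]]] = {}
    for rs in read_sets:
        for chrom, arrs in rs.reads.items():
            bucket = merged.setdefault(chrom, {"starts": [], "ends": [], "strands": []})
            for k in bucket:
                bucket[k].append(arrs[k])
    reads = {
        chrom: {k: np.concatenate(v) for k, v in bucket.items()}
        for chrom, bucket in merged.items()
    }
    return StrandedReadSet(
        sample_id="+".join(r.sample_id for r in read_sets),
        cell_type=cell_types.pop() if len(cell_types) == 1 else "mixed",
        assay=assays.pop() if len(assays) == 1 else "mixed",
        replicate=0,
        reads=reads,
    )


# ---------------------------------------------------------------------------
# Window tiling and counting
# ---------------------------------------------------------------------------


def tile_genome(layout: GenomeLayout, window_size: int) -> pd.DataFrame:
    """Tile every chromosome with adjacent windows of ``window_size`` bp.

    Returns a DataFrame with columns chrom/start/end/partial in (chrom, start)
    order.  A trailing window shorter than ``window_size`` is emitted and
    flagged ``partial``.
    """
    if window_size < 1:
        raise InvalidParameterError(f"window_size must be >= 1, got {window_size}")
    frames = []
    for chrom in layout.chroms:
        clen = layout.length(chrom)
        starts = np.arange(0, clen, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, clen)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "partial": (ends - starts) < window_size,
                }
            )
        )
    windows = pd.concat(frames, ignore_index=True)
    windows.index.name = "window_idx"
    return windows


@dataclass
class WindowCounts:
    """Tiled-window x sample x strand count matrix with sample metadata.

    ``counts`` has shape (n_windows, n_samples, 2) with strand axis (+, -).
    """

    window_size: int
    windows: pd.DataFrame
    counts: np.ndarray
    sample_table: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_table["sample_id"])

    def sample_index(self, sample_id: str) -> int:
        ids = self.sample_ids
        try:
            return ids.index(sample_id)
        except ValueError:
            raise InvalidParameterError(f"unknown sample {sample_id!r}") from None

    def library_sizes(self, sample_ids: Sequence[str]) -> np.ndarray:
        tbl = self.sample_table.set_index("sample_id")
        return tbl.loc[list(sample_ids), "library_size"].to_numpy(dtype=np.int64)


def count_reads_in_windows(
    read_sets: Sequence[StrandedReadSet] | StrandedReadSet,
    windows: pd.DataFrame,
    layout: GenomeLayout,
    window_size: int,
) -> WindowCounts:
    """Assign every read to the window containing its fragment midpoint.

    Totals are conserved: per sample, window counts plus the dropped-read
    count (reads on chromosomes absent from the tiling never occur because
    unknown chromosomes raise) equal the library size.
    """
    if isinstance(read_sets, StrandedReadSet):
        read_sets = [read_sets]
    chrom_offsets: dict[str, int] = {}
    chrom_nwin: dict[str, int] = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        chrom_offsets[chrom] = int(grp.index[0])
        chrom_nwin[chrom] = len(grp)

    n_windows = len(windows)
    counts = np.zeros((n_windows, len(read_sets), 2), dtype=np.int64)
    rows = []
    dropped: dict[str, int] = {}
    for j, rs in enumerate(read_sets):
        rs.validate_bounds(layout)
        n_dropped = 0
        for chrom, arrs in rs.reads.items():
            if chrom not in chrom_offsets:
                raise UnknownChromosomeError(
                    f"sample {rs.sample_id}: reads on chromosome {chrom!r} "
                    "which is not tiled"
                )
            mids = (arrs["starts"] + arrs["ends"]) // 2
            widx = mids // window_size
            ok = widx < chrom_nwin[chrom]
            n_dropped += int((~ok).sum())
            widx = widx[ok] + chrom_offsets[chrom]
            strand_idx = (arrs["strands"][ok] < 0).astype(np.int64)  # 0=+, 1=-
            np.add.at(counts[:, j, :], (widx, strand_idx), 1)
        dropped[rs.sample_id] = n_dropped
        rows.append(
            {
                "sample_id": rs.sample_id,
                "cell_type": rs.cell_type,
                "assay": rs.assay,
                "replicate": rs.replicate,
                "library_size": rs.library_size,
                "dropped": n_dropped,
            }
        )
    return WindowCounts(
        window_size=window_size,
        windows=windows,
        counts=counts,
        sample_table=pd.DataFrame(rows),
        dropped=dropped,
    )


def count_reads_in_regions(
    read_set: StrandedReadSet, regions: Sequence[GenomicInterval] | pd.DataFrame
) -> pd.DataFrame:
    """Stranded midpoint counts per region; overlapping regions each count.

    Regions extending past chromosome bounds are clipped before counting.
    Returns a DataFrame with chrom/start/end/plus/minus aligned with input
    order (empty input gives an empty frame).
    """
    if isinstance(regions, pd.DataFrame):
        reg = regions[["chrom", "start", "end"]].reset_index(drop=True)
    else:
        reg = pd.DataFrame(
            [(r.chrom, r.start, r.end) for r in regions],
            columns=["chrom", "start", "end"],
        )
    reg = reg.copy()
    reg["plus"] = 0
    reg["minus"] = 0
    for chrom, grp in reg.groupby("chrom", sort=False):
        starts = np.maximum(grp["start"].to_numpy(np.int64), 0)
        ends = grp["end"].to_numpy(np.int64)
        plus, minus = read_set.count_in(chrom, starts, ends)
        reg.loc[grp.index, "plus"] = plus
        reg.loc[grp.index, "minus"] = minus
    return reg


# ---------------------------------------------------------------------------
# Interval overlap utilities
# ---------------------------------------------------------------------------


def overlap_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    r_starts: np.ndarray,
    r_ends: np.ndarray,
) -> np.ndarray:
    """Boolean mask: does query i overlap any reference interval by >= 1 bp?

    Single-chromosome arrays.  Uses the sorted-starts / prefix-max-ends trick,
    O((n+m) log m).
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if len(r_starts) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    order = np.argsort(r_starts, kind="mergesort")
    rs = np.asarray(r_starts, dtype=np.int64)[order]
    re_ = np.asarray(r_ends, dtype=np.int64)[order]
    max_end = np.maximum.accumulate(re_)
    # candidates: reference intervals with start < q_end
    idx = np.searchsorted(rs, q_ends, side="left")
    hit = np.zeros(len(q_starts), dtype=bool)
    nz = idx > 0
    hit[nz] = max_end[idx[nz] - 1] > q_starts[nz]
    return hit


def overlap_any_df(queries: pd.DataFrame, refs: pd.DataFrame) -> np.ndarray:
    """Per-chromosome :func:`overlap_any` over chrom/start/end DataFrames."""
    out = np.zeros(len(queries), dtype=bool)
    ref_by_chrom = {c: g for c, g in refs.groupby("chrom", sort=False)}
    pos = queries.reset_index(drop=True)
    for chrom, grp in pos.groupby("chrom", sort=False):
        ref = ref_by_chrom.get(chrom)
        if ref is None:
            continue
        out[grp.index.to_numpy()] = overlap_any(
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            ref["start"].to_numpy(),
            ref["end"].to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# Feature assignment
# ---------------------------------------------------------------------------


def build_feature_index(
    genes: Sequence[GeneModel], layout: GenomeLayout, flank: int = 2000
) -> dict[str, pd.DataFrame]:
    """Interval sets per feature label, derived from gene models.

    Labels follow :data:`FEATURE_PRECEDENCE`: TSS+/-flank, exon, intron,
    TTS+/-flank, lncRNA gene span.  Intergenic is the fallback and has no
    interval set.
    """
    buckets: dict[str, list[tuple[str, int, int]]] = {
        k: [] for k in FEATURE_PRECEDENCE[:-1]
    }
    for g in genes:
        clen = layout.length(g.interval.chrom)
        chrom = g.interval.chrom
        buckets["TSS"].append(
            (chrom, max(0, g.tss - flank), min(clen, g.tss + flank))
        )
        buckets["TTS"].append(
            (chrom, max(0, g.tts - flank), min(clen, g.tts + flank))
        )
        if g.biotype == "lncRNA":
            buckets["lncRNA"].append((chrom, g.interval.start, g.interval.end))
            continue
        exons = sorted(g.exons)
        for s, e in exons:
            buckets["exon"].append((chrom, s, e))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1:
                buckets["intron"].append((chrom, e1, s2))
    return {
        label: pd.DataFrame(rows, columns=["chrom", "start", "end"])
        for label, rows in buckets.items()
    }


def assign_features(
    windows: pd.DataFrame,
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    flank: int = 2000,
) -> pd.Series:
    """Label each window by the highest-precedence feature it overlaps.

    Precedence: TSS > exon > intron > TTS > lncRNA > intergenic; overlap by
    >= 1 bp suffices.  Total function — every window receives a label.
    """
    index = build_feature_index(genes, layout, flank=flank)
    labels = pd.Series("intergenic", index=windows.index, dtype=object)
    unassigned = np.ones(len(windows), dtype=bool)
    pos = windows.reset_index(drop=True)
    for label in FEATURE_PRECEDENCE[:-1]:
        refs = index[label]
        if refs.empty or not unassigned.any():
            continue
        hit = overlap_any_df(pos, refs)
        take = hit & unassigned
        labels.iloc[np.flatnonzero(take)] = label
        unassigned &= ~take
    return labels


def assign_feature(
    window: GenomicInterval,
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    flank: int = 2000,
) -> str:
    """Single-window convenience wrapper around :func:`assign_features`."""
    df = pd.DataFrame(
        {"chrom": [window.chrom], "start": [window.start], "end": [window.end]}
    )
    return str(assign_features(df, genes, layout, flank=flank).iloc[0])


def apply_exclusion(
    read_set: StrandedReadSet, exclusion: pd.DataFrame
) -> StrandedReadSet:
    """Drop reads overlapping any exclusion interval (chrom/start/end frame)."""
    if exclusion is None or exclusion.empty:
        return read_set
    excl_by_chrom = {c: g for c, g in exclusion.groupby("chrom", sort=False)}
    reads = {}
    for chrom, arrs in read_set.reads.items():
        excl = excl_by_chrom.get(chrom)
        if excl is None:
            reads[chrom] = arrs
            continue
        hit = overlap_any(
            arrs["starts"], arrs["ends"], excl["start"].to_numpy(), excl["end"].to_numpy()
        )
        keep = ~hit
        reads[chrom] = {k: v[keep] for k, v in arrs.items()}
    return StrandedReadSet(
        read_set.sample_id,
        read_set.cell_type,
        read_set.assay,
        read_set.replicate,
        reads,
    )
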