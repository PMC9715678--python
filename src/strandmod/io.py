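"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is consumed and produced 0-based half-open; TSV tables are tab-delimited
with a header row, UTF-8.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    InvalidParameterError,
    StrandedReadSet,
)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path: str | os.PathLike) -> GenomeLayout:
    """Two-column chromosome-sizes TSV (name, length), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return GenomeLayout(dict(zip(df["chrom"].astype(str), df["size"].astype(int))))


def write_chrom_sizes(layout: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, size in layout.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    """BED6 (or BED3/4) into a chrom/start/end/name/score/strand frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed6(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(
    path: str | os.PathLike,
    sample_id: str,
    cell_type: str,
    assay: str,
    replicate: int,
    layout: GenomeLayout | None = None,
) -> StrandedReadSet:
    """Load one sample's stranded fragment intervals from BED6."""
    df = read_bed6(path)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise InvalidParameterError(
            f"{path}: {int(bad.sum())} records without +/- strand"
        )
    reads = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        reads[chrom] = {
            "starts": grp["start"].to_numpy(np.int64),
            "ends": grp["end"].to_numpy(np.int64),
            "strands": np.where(grp["strand"] == "+", 1, -1).astype(np.int8),
        }
    return StrandedReadSet(sample_id, cell_type, assay, replicate, reads, layout=layout)


def write_reads_bed(read_set: StrandedReadSet, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in sorted(read_set.reads):
            arrs = read_set.reads[chrom]
            order = np.argsort(arrs["starts"], kind="mergesort")
            strands = np.where(arrs["strands"][order] > 0, "+", "-")
            for s, e, st in zip(arrs["starts"][order], arrs["ends"][order], strands):
                fh.write(f"{chrom}\t{s}\t{e}\t{read_set.sample_id}\t0\t{st}\n")


# ---------------------------------------------------------------------------
# Gene models: BED12 + metadata TSV
# ---------------------------------------------------------------------------


def read_bed12(path: str | os.PathLike) -> pd.DataFrame:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
        "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed12(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            iv = g.interval
            exons = sorted(g.exons)
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            starts = ",".join(str(s - iv.start) for s, _ in exons) + ","
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def read_gene_models(
    bed12_path: str | os.PathLike, metadata_path: str | os.PathLike | None = None
) -> list[GeneModel]:
    """Gene models from BED12 blocks plus optional gene metadata TSV.

    The metadata table is keyed by gene_id and may carry ``biotype`` and
    ``family`` columns; genes absent from it default to coding / no family.
    """
    df = read_bed12(bed12_path)
    meta = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep="\t")
        meta = mdf.set_index("gene_id").to_dict("index")
    genes = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).strip(",").split(",")]
        offsets = [int(x) for x in str(row.blockStarts).strip(",").split(",")]
        exons = tuple(
            (row.start + off, row.start + off + size)
            for off, size in zip(offsets, sizes)
        )
        info = meta.get(row.name, {})
        family = info.get("family")
        if isinstance(family, float) and np.isnan(family):
            family = None
        genes.append(
            GeneModel(
                gene_id=str(row.name),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                biotype=str(info.get("biotype", "coding")),
                family=family,
                exons=exons,
            )
        )
    return genes


def write_gene_metadata(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "biotype": [g.biotype for g in genes],
            "family": [g.family if g.family is not None else "" for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph (strand-split browser tracks)
# ---------------------------------------------------------------------------


def write_strand_bedgraphs(
    window_counts, sample_id: str, prefix: str | os.PathLike
) -> list[str]:
    """One bedGraph per strand for a sample's window counts; returns paths."""
    j = window_counts.sample_index(sample_id)
    paths = []
    for strand_idx, tag in ((0, "plus"), (1, "minus")):
        path = f"{prefix}.{tag}.bedGraph"
        vals = window_counts.counts[:, j, strand_idx]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f'track type=bedGraph name="{sample_id}_{tag}"\n'
            )
            for (_, w), v in zip(window_counts.windows.iterrows(), vals):
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{int(v)}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Generic TSV helpers (deterministic formatting for byte-identical reruns)
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
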