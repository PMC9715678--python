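"""End-to-end orchestration: simulate -> count -> differential -> clusters ->
genes -> asymmetry -> TFBS -> report, with a manifest and structured logs.

All stage outputs are plain TSV/BED/JSON under a run directory; the report
is recomputed from the stage tables, never cached independently.  Given the
same config (and its seeds) a rerun reproduces every table byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import asymmetry as asym
from . import clusters as clu
from . import differential as diff
from . import genes as gn
from . import io as sio
from . import simulate as sim
from . import tfbs as tf
from .genome import GenomeLayout, InvalidParameterError, count_reads_in_windows, tile_genome

log = logging.getLogger("strandmod")

MOD_ASSAYS = ("5mC", "5hmC")


@dataclass
class AnalysisParams:
    window_sizes: tuple = (100, 500, 1000, 2000, 8000, 20000, 50000)
    cluster_window_size: int = 1000
    alpha: float = 0.05
    gap_bp: int = 5000
    density: float = 1 / 8
    min_sig: int = 2
    large_span_bp: int = 100_000
    min_reads: int = 20
    min_total: int = 10
    tss_flank: int = 2000
    expressed_cpm: float = 1.0
    silent_cpm: float = 0.2
    n_strata: int = 10
    body_bins: int = 100
    flank_bin_bp: int = 50
    n_sample_windows: int = 10_000
    asymmetry_sizes: tuple = (100, 1000, 10_000, 100_000, 1_000_000)
    n_shuffles: int = 100
    seed: int = 0
    exclusion_bed: str | None = None
    assays: tuple = MOD_ASSAYS

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must be in (0, 1)")
        for name in ("gap_bp", "min_reads", "min_total", "tss_flank", "min_sig"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        d = dict(d)
        for key in ("window_sizes", "asymmetry_sizes", "assays"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | os.PathLike) -> tuple[sim.SimulationConfig, AnalysisParams]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if "simulation" not in raw:
        raise InvalidParameterError("config missing 'simulation' section")
    sim_cfg = sim.SimulationConfig.from_dict(raw["simulation"])
    params = AnalysisParams.from_dict(raw.get("analysis", {}))
    return sim_cfg, params


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def record(self, stage: str, paths: dict, seconds: float) -> None:
        self.outputs.update(paths)
        self.stages.append({"stage": stage, "outputs": sorted(paths), "wall_s": round(seconds, 2)})
        log.info("stage %s done in %.1fs (%d outputs)", stage, seconds, len(paths))

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "outputs": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in self.outputs.items()},
            "stages": self.stages,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _write(df: pd.DataFrame, path: Path) -> str:
    sio.write_tsv(df, path)
    return str(path)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


def cluster_recovery(
    called: pd.DataFrame, truth: pd.DataFrame, min_jaccard: float = 0.8
) -> dict:
    """Recall/precision of called clusters against planted truth intervals."""
    matches = []
    for t in truth.itertuples(index=False):
        best = 0.0
        for c in called[called["chrom"] == t.chrom].itertuples(index=False):
            best = max(best, jaccard((t.start, t.end), (c.start, c.end)))
        matches.append(best)
    recovered = sum(1 for j in matches if j >= min_jaccard)
    called_matched = 0
    for c in called.itertuples(index=False):
        for t in truth[truth["chrom"] == c.chrom].itertuples(index=False):
            if jaccard((t.start, t.end), (c.start, c.end)) >= min_jaccard:
                called_matched += 1
                break
    return {
        "n_truth": len(truth),
        "n_called": len(called),
        "n_recovered": recovered,
        "recall": recovered / len(truth) if len(truth) else np.nan,
        "precision": called_matched / len(called) if len(called) else np.nan,
        "jaccards": matches,
    }


def sample_correlation_matrix(counts_by_assay: dict) -> pd.DataFrame:
    """Pearson correlations of per-window totals between all samples."""
    cols = {}
    for wc in counts_by_assay.values():
        totals = wc.counts.sum(axis=2)  # strands summed
        for j, sid in enumerate(wc.sample_ids):
            cols[sid] = totals[:, j]
    mat = pd.DataFrame(cols)
    return mat.corr(method="pearson")


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------


def run_pipeline(
    config_path: str | os.PathLike | None,
    outdir: str | os.PathLike,
    sim_cfg: sim.SimulationConfig | None = None,
    params: AnalysisParams | None = None,
    write_inputs: bool = False,
    make_plots: bool = False,
) -> RunManifest:
    """Execute every stage on a synthetic experiment and write the report."""
    if config_path is not None:
        sim_cfg, params = load_config(config_path)
    if sim_cfg is None or params is None:
        raise InvalidParameterError("need a config path or explicit config objects")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={"simulation": sim_cfg.to_dict(), "analysis": asdict(params)},
        version=__version__,
    )

    exclusion = (
        sio.read_bed6(params.exclusion_bed) if params.exclusion_bed else None
    )

    t0 = time.perf_counter()
    exp = sim.simulate_experiment(sim_cfg)
    layout = exp.genome.layout
    paths = {}
    paths["truth_clusters"] = _write(exp.truth.clusters, out / "truth_clusters.tsv")
    paths["truth_genes"] = _write(
        exp.truth.gene_truth.reset_index(), out / "truth_genes.tsv"
    )
    paths["expression_counts"] = _write(
        exp.expression_counts.reset_index(), out / "expression_counts.tsv"
    )
    if write_inputs:
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        sio.write_fasta(exp.genome.sequences, inputs / "genome.fa")
        sio.write_chrom_sizes(layout, inputs / "genome.chrom.sizes")
        sio.write_bed12(exp.genome.genes, inputs / "genes.bed12")
        sio.write_gene_metadata(exp.genome.genes, inputs / "genes.meta.tsv")
        sio.write_bed6(exp.genome.repeats, inputs / "repeats.bed")
        for sid, rs in exp.samples.items():
            sio.write_reads_bed(rs, inputs / f"{sid}.bed")
        for tf_name, sites in exp.tfbs.items():
            sio.write_bed6(sites, inputs / f"tfbs_{tf_name}.bed")
        paths["inputs_dir"] = str(inputs / "genome.chrom.sizes")
    manifest.record("simulate", paths, time.perf_counter() - t0)

    # ---- window counting + differential per assay ------------------------
    windows_1kb = tile_genome(layout, params.cluster_window_size)
    counts_by_assay = {}
    sig_windows = {}
    diff_results = {}
    cluster_sets = {}
    for assay in params.assays:
        t0 = time.perf_counter()
        paths = {}
        samples = [s for s in exp.samples.values() if s.assay == assay]
        if exclusion is not None:
            from .genome import apply_exclusion

            samples = [apply_exclusion(s, exclusion) for s in samples]
        group_a = sorted(s.sample_id for s in samples if s.cell_type == "D1")
        group_b = sorted(s.sample_id for s in samples if s.cell_type == "D2")
        ordered = [exp.samples[sid] for sid in group_a + group_b]
        for wsize in params.window_sizes:
            win = (
                windows_1kb
                if wsize == params.cluster_window_size
                else tile_genome(layout, wsize)
            )
            wc = count_reads_in_windows(ordered, win, layout, wsize)
            res = diff.differential_windows(
                wc, group_a, group_b, min_total=params.min_total, alpha=params.alpha
            )
            paths[f"diff_{assay}_w{wsize}"] = _write(
                res, out / f"diff_windows_{assay}_{wsize}bp.tsv"
            )
            if wsize == params.cluster_window_size:
                counts_by_assay[assay] = wc
                diff_results[assay] = res
                sig_windows[assay] = res[res["significant"]].reset_index(drop=True)
        manifest.record(f"differential_{assay}", paths, time.perf_counter() - t0)

        t0 = time.perf_counter()
        built = clu.extend_clusters(
            sig_windows[assay],
            gap_bp=params.gap_bp,
            density_threshold=params.density,
            window_size=params.cluster_window_size,
            min_sig=params.min_sig,
        )
        cluster_sets[assay] = built
        paths = {
            f"clusters_{assay}": _write(
                clu.clusters_to_frame(built), out / f"clusters_{assay}.tsv"
            )
        }
        manifest.record(f"clusters_{assay}", paths, time.perf_counter() - t0)

    # cross-assay cluster summaries
    t0 = time.perf_counter()
    paths = {}
    for assay in params.assays:
        other = [a for a in params.assays if a != assay]
        summary = clu.summarize_clusters(
            cluster_sets[assay],
            genes=exp.genome.genes,
            other_clusters=cluster_sets[other[0]] if other else None,
            other_sig_windows=sig_windows[other[0]] if other else None,
            n_sig_windows_total=len(sig_windows[assay]) or None,
            large_span_bp=params.large_span_bp,
        )
        paths[f"cluster_summary_{assay}"] = _write(
            summary["table"], out / f"cluster_summary_{assay}.tsv"
        )
    manifest.record("cluster_summary", paths, time.perf_counter() - t0)

    # ---- expression + gene-level -----------------------------------------
    t0 = time.perf_counter()
    paths = {}
    rna_cols = exp.expression_counts.columns
    cell_of = {c: ("D1" if c.startswith("D1") else "D2") for c in rna_cols}
    expr = gn.expression_summary(
        exp.expression_counts,
        cell_of,
        n_strata=params.n_strata,
        expressed_cpm=params.expressed_cpm,
        silent_cpm=params.silent_cpm,
    )
    paths["expression_strata"] = _write(expr.reset_index(), out / "expression_strata.tsv")

    # DE via the same exact engine on pooled rna counts
    a_cols = sorted(c for c in rna_cols if cell_of[c] == "D1")
    b_cols = sorted(c for c in rna_cols if cell_of[c] == "D2")
    c1 = exp.expression_counts[a_cols].sum(axis=1).to_numpy(np.int64)
    c2 = exp.expression_counts[b_cols].sum(axis=1).to_numpy(np.int64)
    N1 = int(c1.sum())
    N2 = int(c2.sum())
    gene_iv = pd.DataFrame(
        {
            "chrom": [g.interval.chrom for g in exp.genome.genes],
            "start": [g.interval.start for g in exp.genome.genes],
            "end": [g.interval.end for g in exp.genome.genes],
        }
    )
    de_res = diff.differential_table(
        list(exp.expression_counts.index),
        gene_iv,
        c1,
        c2,
        N1,
        N2,
        min_total=params.min_total,
        alpha=params.alpha,
    )
    paths["diff_expression"] = _write(de_res, out / "diff_expression.tsv")
    de_table = de_res.set_index("unit_id")[["log2fc", "significant"]].rename(
        columns={"significant": "de"}
    )

    gene_results = {}
    for assay in params.assays:
        samples = [s for s in exp.samples.values() if s.assay == assay]
        group_a = sorted(s.sample_id for s in samples if s.cell_type == "D1")
        group_b = sorted(s.sample_id for s in samples if s.cell_type == "D2")
        lib = {s.sample_id: s.library_size for s in samples}
        from .genome import count_reads_in_regions

        tss_regions = pd.DataFrame(
            {
                "chrom": [g.interval.chrom for g in exp.genome.genes],
                "start": [max(0, g.tss - params.tss_flank) for g in exp.genome.genes],
                "end": [
                    min(layout.length(g.interval.chrom), g.tss + params.tss_flank)
                    for g in exp.genome.genes
                ],
            }
        )
        body_regions = gene_iv
        ids = [g.gene_id for g in exp.genome.genes]
        tss_counts = {
            s.sample_id: count_reads_in_regions(s, tss_regions) for s in samples
        }
        body_counts = {
            s.sample_id: count_reads_in_regions(s, body_regions) for s in samples
        }
        tss_res = diff.differential_regions(
            tss_counts, ids, group_a, group_b, lib,
            min_total=params.min_total, alpha=params.alpha,
        )
        body_res = diff.differential_regions(
            body_counts, ids, group_a, group_b, lib,
            min_total=params.min_total, alpha=params.alpha,
        )
        paths[f"diff_tss_{assay}"] = _write(tss_res, out / f"diff_tss_{assay}.tsv")
        paths[f"diff_body_{assay}"] = _write(body_res, out / f"diff_body_{assay}.tsv")
        merged = gn.merge_gene_calls(
            tss_res, body_res, diff_results[assay], exp.genome.genes,
            flank=params.tss_flank,
        )
        paths[f"gene_calls_{assay}"] = _write(
            merged["calls"], out / f"gene_calls_{assay}.tsv"
        )
        gene_results[assay] = {"tss": tss_res, "body": body_res, "venn": merged["venn"]}

    # metagene profiles (quintiles, 5hmC combined + strand-split)
    strata5 = gn.stratify_expression(
        expr["mean_cpm"], n_strata=5,
        expressed_cpm=params.expressed_cpm, silent_cpm=params.silent_cpm,
    )
    metagene_tables = {}
    for assay in params.assays:
        pooled = [s for s in exp.samples.values() if s.assay == assay]
        prof = gn.metagene_profile(
            pooled,
            exp.genome.genes,
            layout,
            flank_bp=params.tss_flank,
            body_bins=params.body_bins,
            flank_bin_bp=params.flank_bin_bp,
            strata=strata5,
            strand_mode="combined",
        )
        tbl = prof["profiles"]["combined"].reset_index()
        paths[f"metagene_{assay}"] = _write(tbl, out / f"metagene_{assay}.tsv")
        metagene_tables[assay] = prof
    if "5hmC" in params.assays:
        pooled = [s for s in exp.samples.values() if s.assay == "5hmC"]
        prof = gn.metagene_profile(
            pooled, exp.genome.genes, layout,
            flank_bp=params.tss_flank, body_bins=params.body_bins,
            flank_bin_bp=params.flank_bin_bp, strata=strata5,
            strand_mode="template-vs-coding",
        )
        for key, mat in prof["profiles"].items():
            paths[f"metagene_5hmC_{key}"] = _write(
                mat.reset_index(), out / f"metagene_5hmC_{key}.tsv"
            )

    # modification fold change vs expression fold change
    corr_rows = []
    for assay in params.assays:
        body = gene_results[assay]["body"]
        sig_body = body[body["significant"]]
        if len(sig_body) >= 3:
            mod_fc = sig_body.set_index("unit_id")["log2fc"]
            mrna_fc = de_table["log2fc"]
            try:
                summary = gn.correlate_mod_expression(mod_fc, mrna_fc)
                corr_rows.append({"assay": assay, **summary})
            except InvalidParameterError:
                pass
    if corr_rows:
        paths["mod_expression_correlation"] = _write(
            pd.DataFrame(corr_rows), out / "mod_expression_correlation.tsv"
        )

    if "5hmC" in params.assays:
        mc_sig_genes = (
            set(gene_results["5mC"]["body"].loc[
                gene_results["5mC"]["body"]["significant"], "unit_id"
            ])
            if "5mC" in params.assays
            else set()
        )
        classified = gn.classify_hmc_expression_direction(
            diff_results["5hmC"], exp.genome.genes, de_table,
            flank=params.tss_flank, exclude_gene_ids=mc_sig_genes,
        )
        if len(classified["table"]):
            paths["hmc_expression_direction"] = _write(
                classified["table"], out / "hmc_expression_direction.tsv"
            )
        hmc_fractions = classified["fractions"]
    else:
        hmc_fractions = {}
    manifest.record("gene_level", paths, time.perf_counter() - t0)

    # ---- strand asymmetry -------------------------------------------------
    t0 = time.perf_counter()
    paths = {}
    from .genome import pool_read_sets

    max_size = max(layout.chrom_sizes.values())
    sizes = tuple(s for s in params.asymmetry_sizes if s <= max_size)
    asym_tables = {}
    ratio_sets = {}
    for assay in [a for a in params.assays if a in MOD_ASSAYS]:
        for ct in ("D1", "D2"):
            pooled = pool_read_sets(exp.read_sets(ct, assay))
            tag = f"{assay}_{ct}"
            by_size = asym.asymmetry_by_size(
                pooled, layout, sizes,
                n=params.n_sample_windows, seed=params.seed,
                min_reads=params.min_reads, exclusion=exclusion,
            )
            paths[f"asym_size_{tag}"] = _write(
                by_size["summary"], out / f"asymmetry_by_size_{tag}.tsv"
            )
            curve = asym.concordance_curve(
                pooled, layout, sizes,
                n=params.n_sample_windows, seed=params.seed,
                min_reads=params.min_reads, exclusion=exclusion,
            )
            paths[f"concordance_{tag}"] = _write(
                curve.table, out / f"concordance_{tag}.tsv"
            )
            ratios = asym.gene_template_ratios(
                pooled, exp.genome.genes, min_reads=params.min_reads
            )
            paths[f"gene_ratios_{tag}"] = _write(
                ratios, out / f"gene_template_ratios_{tag}.tsv"
            )
            ratio_sets[tag] = ratios
            by_expr = asym.asymmetry_by_expression(
                ratios, expr["stratum"]
            )
            paths[f"asym_expr_{tag}"] = _write(
                by_expr, out / f"asymmetry_by_expression_{tag}.tsv"
            )
            reps = asym.repeat_family_asymmetry(
                pooled, exp.genome.repeats, min_reads=params.min_reads
            )
            paths[f"repeat_asym_{tag}"] = _write(
                reps["summary"], out / f"repeat_asymmetry_{tag}.tsv"
            )
            asym_tables[tag] = by_expr

    # CH template ratios per gene + correlation with modification ratios
    ch_rows = []
    for g in exp.genome.genes:
        seq = exp.genome.sequences[g.interval.chrom][g.interval.start : g.interval.end]
        ratio = asym.ch_template_ratio(seq, g.strand)
        ch_rows.append(
            {"gene_id": g.gene_id, "template_ratio": ratio, "pass_filter": ratio is not None}
        )
    ch_ratios = pd.DataFrame(ch_rows)
    paths["ch_gene_ratios"] = _write(ch_ratios, out / "ch_gene_template_ratios.tsv")
    corr_in = dict(ratio_sets)
    corr_in["CH"] = ch_ratios
    corr = asym.asymmetry_correlations(corr_in)
    paths["asymmetry_correlations"] = _write(
        corr.reset_index().rename(columns={"index": "set"}),
        out / "asymmetry_correlations.tsv",
    )
    manifest.record("asymmetry", paths, time.perf_counter() - t0)

    # ---- TFBS enrichment --------------------------------------------------
    t0 = time.perf_counter()
    paths = {}
    tf_assay = "5mC" if "5mC" in params.assays else params.assays[0]
    enr = tf.tfbs_zscore(
        sig_windows[tf_assay][["chrom", "start", "end"]],
        exp.tfbs,
        layout,
        n_shuffles=params.n_shuffles,
        seed=params.seed,
        exclusion=exclusion,
    )
    paths["tfbs_enrichment"] = _write(enr, out / "tfbs_enrichment.tsv")
    manifest.record("tfbs", paths, time.perf_counter() - t0)

    # ---- truth vs called + report ----------------------------------------
    t0 = time.perf_counter()
    paths = {}
    recovery = {}
    for assay in [a for a in params.assays if a in MOD_ASSAYS]:
        rec = cluster_recovery(
            clu.clusters_to_frame(cluster_sets[assay]), exp.truth.clusters
        )
        recovery[assay] = {k: v for k, v in rec.items() if k != "jaccards"}
    corr_mat = sample_correlation_matrix(counts_by_assay)
    paths["sample_correlation"] = _write(
        corr_mat.reset_index().rename(columns={"index": "sample"}),
        out / "sample_correlation.tsv",
    )

    report = {
        "n_significant_windows": {a: int(len(sig_windows[a])) for a in params.assays},
        "window_concordance": _window_concordance(sig_windows),
        "clusters": {
            a: {
                "n_clusters": len(cluster_sets[a]),
                "n_large": int(
                    sum(c.span > params.large_span_bp for c in cluster_sets[a])
                ),
                "fraction_windows_grouped": (
                    sum(c.n_sig for c in cluster_sets[a]) / len(sig_windows[a])
                    if len(sig_windows[a])
                    else None
                ),
            }
            for a in params.assays
        },
        "gene_evidence_venn": {a: gene_results[a]["venn"] for a in params.assays},
        "hmc_expression_fractions": hmc_fractions,
        "asymmetry_by_expression": {
            tag: tbl.to_dict("records") for tag, tbl in asym_tables.items()
        },
        "top_tfs": enr.head(10).to_dict("records"),
        "truth_recovery": recovery,
        "n_de_genes": int(de_res["significant"].sum()),
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    paths["report"] = str(out / "report.json")
    if make_plots:
        paths.update(_make_plots(out, asym_tables, cluster_sets))
    manifest.record("report", paths, time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    return manifest


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _window_concordance(sig_windows: dict) -> dict:
    """Venn-style overlap of significant windows between assays."""
    if len(sig_windows) < 2:
        return {}
    assays = list(sig_windows)
    a, b = assays[0], assays[1]
    keys_a = {
        (r.chrom, r.start, r.direction) for r in sig_windows[a].itertuples(index=False)
    }
    keys_b = {
        (r.chrom, r.start, r.direction) for r in sig_windows[b].itertuples(index=False)
    }
    both_same_dir = len(keys_a & keys_b)
    pos_a = {(k[0], k[1]) for k in keys_a}
    pos_b = {(k[0], k[1]) for k in keys_b}
    return {
        "shared_windows": len(pos_a & pos_b),
        "shared_same_direction": both_same_dir,
        f"only_{a}": len(pos_a - pos_b),
        f"only_{b}": len(pos_b - pos_a),
    }


def _make_plots(out: Path, asym_tables: dict, cluster_sets: dict) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    fig, ax = plt.subplots(figsize=(6, 4))
    for tag, tbl in asym_tables.items():
        ax.plot(tbl["stratum"], tbl["median"], marker="o", label=tag)
    ax.set_xlabel("expression stratum")
    ax.set_ylabel("median template ratio")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = out / "asymmetry_by_expression.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["plot_asym"] = str(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    for assay, built in cluster_sets.items():
        spans = sorted((c.span for c in built), reverse=True)
        ax.plot(range(1, len(spans) + 1), spans, marker=".", label=assay)
    ax.set_yscale("log")
    ax.set_xlabel("cluster rank")
    ax.set_ylabel("span (bp)")
    ax.legend()
    fig.tight_layout()
    p = out / "cluster_sizes.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["plot_clusters"] = str(p)
    return paths


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


def validate_inputs(
    chrom_sizes_path: str,
    read_beds: dict | None = None,
    sample_grid: tuple | None = None,
) -> list[str]:
    """Check BED sortedness/bounds/strands and sample-grid completeness.

    ``read_beds`` maps sample_id -> (path, cell_type, assay, replicate).
    Returns a list of violation/warning strings (empty = clean).
    """
    problems: list[str] = []
    layout = sio.read_chrom_sizes(chrom_sizes_path)
    seen = set()
    for sample_id, (path, cell_type, assay, replicate) in (read_beds or {}).items():
        df = sio.read_bed6(path)
        if not df["strand"].isin(["+", "-"]).all():
            problems.append(f"{sample_id}: records without +/- strand")
        for chrom, grp in df.groupby("chrom", sort=False):
            if chrom not in layout.chrom_sizes:
                problems.append(f"{sample_id}: unknown chromosome {chrom}")
                continue
            if (grp["end"] > layout.length(chrom)).any() or (grp["start"] < 0).any():
                problems.append(f"{sample_id}: read beyond bounds on {chrom}")
            if not grp["start"].is_monotonic_increasing:
                problems.append(f"{sample_id}: {chrom} not coordinate-sorted")
        seen.add((cell_type, assay, int(replicate)))
    if sample_grid:
        cell_types, assays, n_reps = sample_grid
        for ct in cell_types:
            for assay in assays:
                for rep in range(1, n_reps + 1):
                    if (ct, assay, rep) not in seen:
                        problems.append(
                            f"missing sample in grid: {ct} x {assay} x r{rep}"
                        )
    return problems
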