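"""End-to-end orchestration: simulate/load -> filter -> scan -> call -> annotate.

A single :class:`PipelineConfig` (TOML-loadable) drives every stage; one
seed propagates to each stochastic step.  All tabular outputs are written
deterministically, and a manifest records every output file with its SHA-256
hash so a re-run with the same config can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

from . import ed as ed_mod
from . import snpindex as si_mod
from .annotate import (Variant, classify_variant, annotations_to_frame,
                       read_gene_models_bed12, read_gene_models_gff3,
                       summarize_region_variants)
from .records import LocusTable
from .regions import (CandidateRegion, FittedTrack, attach_genes, call_regions,
                      fit_scan, intersect_methods, regions_to_frame,
                      write_regions_bed, write_regions_tsv)
from .simulate import SimConfig, TruthRecord, simulate_f2_experiment
from .snpindex import ThresholdSpec
from .variant_table import (filter_ed_path, filter_snp_index_path,
                            read_locus_table, select_pool_divergent,
                            write_tsv, write_vcf)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; see docs/methods.md for rationale."""

    out_dir: str = "bsascan_out"
    seed: int = 0
    # input: either a locus-table file or a simulation
    input_path: str | None = None
    input_format: str = "auto"
    sample_roles: dict = field(default_factory=dict)
    simulate: SimConfig | None = None
    # filtering
    min_bulk_depth: int = 4
    # SNP-index scan
    snp_threshold_rule: str = "theoretical"  # "theoretical" | "simulated"
    snp_percentile: float = 0.95
    snp_n_rep: int = 10_000
    # ED scan; het band calibrated so the pool-divergent fraction matches the
    # ~40% observed for F2 extreme bulks at ~50x depth (see docs/methods.md)
    ed_power: float = 5.0
    ed_het_band: tuple = (0.40, 0.60)
    # fitting / regions
    window_bp: int = 1_000_000
    step_bp: int = 10_000
    merge_gap_bp: int = 0
    # annotation
    genes_path: str | None = None
    genes_format: str = "gff3"  # "gff3" | "bed12"
    flank_bp: int = 1_000
    splice_bp: int = 2
    make_plots: bool = False

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("config needs exactly one of input_path or [simulate]")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(f"input_path {self.input_path} does not exist")
        if self.genes_path is not None and not Path(self.genes_path).exists():
            raise FileNotFoundError(f"genes_path {self.genes_path} does not exist")
        if self.snp_threshold_rule not in ("theoretical", "simulated"):
            raise ValueError("snp_threshold_rule must be theoretical or simulated")

    @staticmethod
    def from_toml(path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = raw.pop("simulate", None)
        cfg = PipelineConfig(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg


@dataclass
class PipelineResult:
    table: LocusTable
    truth: TruthRecord | None
    snp_scan: pd.DataFrame
    ed_scan: pd.DataFrame
    snp_tracks: list[FittedTrack]
    ed_tracks: list[FittedTrack]
    snp_threshold: ThresholdSpec
    ed_threshold: ThresholdSpec
    snp_regions: list[CandidateRegion]
    ed_regions: list[CandidateRegion]
    intersected: list[CandidateRegion]
    reports: pd.DataFrame
    manifest_path: Path | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Run every stage and (optionally) write the result bundle.

    Any stage failure propagates with the stage name prepended so the
    offending step is identifiable from the traceback message.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        truth: TruthRecord | None = None
        if cfg.simulate is not None:
            sim_cfg = cfg.simulate
            table, truth = simulate_f2_experiment(sim_cfg)
        else:
            table = read_locus_table(cfg.input_path, cfg.input_format,
                                     cfg.sample_roles or None)
        log.info("input: %d loci on %d chromosomes", len(table),
                 table.df["chrom"].nunique())

        stage = "filter"
        snp_table, snp_report = filter_snp_index_path(table, cfg.min_bulk_depth)
        ed_table, ed_report = filter_ed_path(table, cfg.min_bulk_depth)
        ed_table = select_pool_divergent(ed_table, tuple(cfg.ed_het_band))

        stage = "scan-snpindex"
        snp_scan = si_mod.snp_index_scan(snp_table)
        snp_tracks = fit_scan(snp_scan, "delta", cfg.window_bp, cfg.step_bp,
                              statistic="delta_snp_index")
        if cfg.snp_threshold_rule == "theoretical":
            snp_thr = si_mod.theoretical_threshold_f2()
        else:
            depths = snp_scan[["depth_mut", "depth_wt"]].to_numpy()
            bulk_size = cfg.simulate.bulk_size if cfg.simulate else 30
            snp_thr = si_mod.simulated_threshold(
                depths, bulk_size, cfg.snp_percentile, cfg.snp_n_rep, cfg.seed
            )
        snp_regions = call_regions(snp_tracks, snp_thr, cfg.merge_gap_bp,
                                   method="snp_index", use_abs=True)

        stage = "scan-ed"
        ed_scan_df = ed_mod.ed_scan(ed_table, cfg.ed_power)
        ed_tracks = fit_scan(ed_scan_df, "ed_powered", cfg.window_bp, cfg.step_bp,
                             statistic="ed")
        ed_thr = ed_mod.ed_threshold(
            np.concatenate([t.values for t in ed_tracks]) if ed_tracks else np.array([])
        )
        ed_regions = call_regions(ed_tracks, ed_thr, cfg.merge_gap_bp)

        stage = "intersect"
        intersected = intersect_methods(snp_regions, ed_regions)

        stage = "annotate"
        genes = []
        if cfg.genes_path is not None:
            reader = (read_gene_models_gff3 if cfg.genes_format == "gff3"
                      else read_gene_models_bed12)
            genes = reader(cfg.genes_path)
            intersected = attach_genes(intersected, genes)

        reports = pd.concat([snp_report.to_frame(), ed_report.to_frame()],
                            ignore_index=True)

        result = PipelineResult(
            table=table, truth=truth, snp_scan=snp_scan, ed_scan=ed_scan_df,
            snp_tracks=snp_tracks, ed_tracks=ed_tracks,
            snp_threshold=snp_thr, ed_threshold=ed_thr,
            snp_regions=snp_regions, ed_regions=ed_regions,
            intersected=intersected, reports=reports,
        )

        if write_outputs:
            stage = "write"
            _write_bundle(cfg, result, genes, out)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _tracks_frame(tracks: list[FittedTrack]) -> pd.DataFrame:
    return pd.concat(
        [pd.DataFrame({"chrom": t.chrom, "pos": t.positions, "fitted": t.values})
         for t in tracks],
        ignore_index=True,
    ) if tracks else pd.DataFrame(columns=["chrom", "pos", "fitted"])


def _write_bundle(cfg: PipelineConfig, res: PipelineResult, genes, out: Path) -> None:
    files: dict[str, Path] = {}

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        files[name] = path

    save("locus_table.tsv", lambda p: write_tsv(res.table, p))
    save("locus_table.vcf", lambda p: write_vcf(res.table, p))
    if res.truth is not None:
        save("truth.tsv", lambda p: res.truth.to_tsv(str(p)))
    save("snpindex_scan.tsv",
         lambda p: res.snp_scan.to_csv(p, sep="\t", index=False, float_format="%.6g"))
    save("snpindex_fitted.tsv",
         lambda p: _tracks_frame(res.snp_tracks).to_csv(p, sep="\t", index=False,
                                                        float_format="%.6g"))
    save("ed_scan.tsv",
         lambda p: res.ed_scan.to_csv(p, sep="\t", index=False, float_format="%.6g"))
    save("ed_fitted.tsv",
         lambda p: _tracks_frame(res.ed_tracks).to_csv(p, sep="\t", index=False,
                                                       float_format="%.6g"))
    save("filter_reports.tsv",
         lambda p: res.reports.to_csv(p, sep="\t", index=False))
    save("regions_snpindex.tsv", lambda p: write_regions_tsv(res.snp_regions, p))
    save("regions_ed.tsv", lambda p: write_regions_tsv(res.ed_regions, p))
    save("regions_intersected.tsv", lambda p: write_regions_tsv(res.intersected, p))
    save("regions_intersected.bed", lambda p: write_regions_bed(res.intersected, p))

    if genes:
        chroms = set(res.table.genome) | {g.chrom for g in genes}
        variants = [
            Variant(r.chrom, int(r.pos), r.allele_wt, r.allele_mut)
            for r in res.table.df.itertuples(index=False)
            if any(reg.chrom == r.chrom and reg.start <= r.pos <= reg.end
                   for reg in res.intersected)
        ]
        annotated = [
            (v, classify_variant(v, genes, cfg.flank_bp, cfg.splice_bp, chroms=chroms))
            for v in variants
        ]
        save("variant_annotations.tsv",
             lambda p: annotations_to_frame(annotated).to_csv(p, sep="\t", index=False))
        save("variant_summary.tsv",
             lambda p: summarize_region_variants(annotated, res.intersected)
             .to_csv(p, sep="\t"))

    if cfg.make_plots:
        files.update(plot_scans(res, out))

    thresholds = {
        "snp_index": {"value": res.snp_threshold.value,
                      "rule": res.snp_threshold.rule,
                      "display": res.snp_threshold.display_value},
        "ed": {"value": res.ed_threshold.value, "rule": res.ed_threshold.rule},
    }
    manifest = {
        "config": {k: (asdict(v) if isinstance(v, SimConfig) else v)
                   for k, v in asdict(cfg).items()},
        "thresholds": thresholds,
        "outputs": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    res.manifest_path = manifest_path


def scan_figure(scan: pd.DataFrame, value_col: str, tracks: list[FittedTrack],
                thr: ThresholdSpec, regions: list[CandidateRegion], label: str):
    """Build one genome-scan figure: per-chromosome panels of raw points,
    fitted line, threshold line and shaded called regions."""
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [t.chrom for t in tracks] or list(scan["chrom"].unique())
    fig, axes = plt.subplots(max(len(chroms), 1), 1,
                             figsize=(10, 2.2 * max(len(chroms), 1)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = scan[scan["chrom"] == chrom]
        ax.plot(sub["pos"] / 1e6, sub[value_col], ".", ms=2, alpha=0.4,
                color="tab:blue")
        for t in tracks:
            if t.chrom == chrom:
                ax.plot(t.positions / 1e6, t.values, "-", color="black", lw=1.2)
        ax.axhline(thr.value, color="magenta", ls="--", lw=1)
        for r in regions:
            if r.chrom == chrom:
                ax.axvspan(r.start / 1e6, r.end / 1e6, color="orange", alpha=0.3)
        ax.set_ylabel(label)
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    return fig


def plot_scans(res: PipelineResult, out_dir: Path) -> dict[str, Path]:
    """Write the two genome-scan figures; returns {filename: path}."""
    import matplotlib.pyplot as plt

    out: dict[str, Path] = {}
    jobs = [
        ("snpindex_scan.png", res.snp_scan, "delta", res.snp_tracks,
         res.snp_threshold, res.snp_regions, r"$\Delta$SNP-index"),
        ("ed_scan.png", res.ed_scan, "ed_powered", res.ed_tracks,
         res.ed_threshold, res.ed_regions, "ED (powered)"),
    ]
    for fname, scan, col, tracks, thr, regions, label in jobs:
        if not len(scan):
            continue
        fig = scan_figure(scan, col, tracks, thr, regions, label)
        path = Path(out_dir) / fname
        fig.savefig(path, dpi=110)
        plt.close(fig)
        out[fname] = path
    return out
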