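"""End-to-end scan: filter → windows → HDR → annotate → GO → CDS π.

Outputs are plain TSV/BED/JSON with stable schemas; the manifest records
the realized percentile thresholds and per-stage counts so a run is
auditable ("FST < x, π1 > y, π2 > z").
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allsites import FilterConfig, filter_stream, read_allsites_vcf, read_population_map
from .annotate import (
    genes_overlapping_regions,
    parse_repeatmasker_out,
    read_gff_genes,
    welch_t_test,
    window_repeat_proportion,
)
from .clusters import cds_pi, read_aligned_fasta
from .goenrich import build_gene2go, parse_obo, read_gene2go_tsv, results_to_dataframe, run_enrichment
from .hdr import call_hdrs, regions_to_bed, regions_to_dataframe
from .windows import (
    WindowSpec,
    make_windows,
    pearson_correlation,
    read_recombination_track,
    window_summaries,
    windows_to_dataframe,
)

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "PipelineError", "run_scan"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


@dataclass(slots=True)
class ScanConfig:
    vcf: str = ""
    popmap: str = ""
    gff: str | None = None
    repeats: str | None = None
    obo: str | None = None
    gene2go: str | None = None
    recomb: str | None = None
    cds_fasta: str | None = None
    window_size: int = 5_000
    filters: FilterConfig = field(default_factory=FilterConfig)
    q_fst: float = 0.05
    q_pi: float = 0.95
    max_gap: int = 0
    go_namespace: str = "BP"
    go_algorithm: str = "elim"
    go_min_genes: int = 10
    go_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filters = FilterConfig(**raw.pop("filters", {}))
        cfg = cls(filters=filters, **raw)
        for required in ("vcf", "popmap"):
            if not getattr(cfg, required):
                raise ValueError(f"config missing required field {required!r}")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return inner

    return wrap


@_stage("windows")
def _stage_windows(cfg: ScanConfig, outdir: Path, manifest: dict):
    pops = read_population_map(cfg.popmap)
    sample_order, sites = read_allsites_vcf(cfg.vcf, samples=pops.samples)
    from cyvcf2 import VCF

    header = VCF(cfg.vcf)
    contig_lengths = dict(zip(header.seqnames, header.seqlens))
    header.close()
    windows = make_windows(contig_lengths, cfg.window_size)
    stats = window_summaries(
        filter_stream(sites, cfg.filters), windows, pops, sample_order
    )
    df = windows_to_dataframe(stats, pops)
    df.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    manifest["counts"]["windows_total"] = len(df)
    manifest["counts"]["sites_excluded_nonbiallelic"] = int(
        sum(s.n_excluded for s in stats)
    )
    return df, pops


@_stage("hdr")
def _stage_hdr(cfg: ScanConfig, df: pd.DataFrame, outdir: Path, manifest: dict):
    flagged, thresholds, regions = call_hdrs(
        df, q_fst=cfg.q_fst, q_pi=cfg.q_pi, max_gap=cfg.max_gap
    )
    (outdir / "hdr_regions.bed").write_text(regions_to_bed(regions))
    regions_to_dataframe(regions).to_csv(outdir / "hdr_summary.tsv", sep="\t", index=False)
    manifest["thresholds"] = {
        "fst_cut": thresholds.fst_cut,
        "pi_cuts": thresholds.pi_cuts,
        "q_fst": thresholds.q_fst,
        "q_pi": thresholds.q_pi,
    }
    manifest["counts"]["windows_retained"] = len(flagged)
    manifest["counts"]["windows_selected"] = int(flagged["selected"].sum())
    manifest["counts"]["hdr_regions"] = len(regions)
    return flagged, regions


@_stage("annotate")
def _stage_annotate(cfg: ScanConfig, flagged, regions, outdir: Path, manifest: dict):
    genes_df = None
    if cfg.repeats:
        repeats = parse_repeatmasker_out(cfg.repeats)
        windows = [
            WindowSpec(str(r["chrom"]), int(r["start"]) - 1, int(r["end"]))
            for _, r in flagged.iterrows()
        ]
        props = window_repeat_proportion(repeats, windows)
        props["selected"] = flagged["selected"].to_numpy()
        props.to_csv(outdir / "repeat_windows.tsv", sep="\t", index=False)
        rows = []
        sel = props[props["selected"]]
        bg = props[~props["selected"]]
        for col in props.columns:
            if col in ("chrom", "start", "end", "selected"):
                continue
            try:
                t, dof, p = welch_t_test(sel[col], bg[col])
            except ValueError:
                t, dof, p = float("nan"), float("nan"), float("nan")
            rows.append(
                {
                    "superclass": col,
                    "mean_hdr": float(sel[col].mean()),
                    "mean_background": float(bg[col].mean()),
                    "t": t,
                    "df": dof,
                    "p": p,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "repeat_contrast.tsv", sep="\t", index=False)
    if cfg.gff:
        genes = read_gff_genes(cfg.gff)
        genes_df = genes_overlapping_regions(genes, regions)
        genes_df.to_csv(outdir / "hdr_genes.tsv", sep="\t", index=False)
        manifest["counts"]["genes_total"] = len(genes_df)
        manifest["counts"]["genes_in_hdr"] = int(genes_df["in_region"].sum())
    return genes_df


@_stage("go")
def _stage_go(cfg: ScanConfig, genes_df, outdir: Path, manifest: dict):
    dag = parse_obo(cfg.obo)
    g2g = build_gene2go([read_gene2go_tsv(cfg.gene2go)], dag)
    annotated = g2g.genes()
    universe = annotated & set(genes_df["gene_id"])
    study = set(genes_df.loc[genes_df["in_region"], "gene_id"]) & universe
    if not study or not universe:
        logger.warning("GO stage skipped: empty study or universe")
        pd.DataFrame(
            columns=["term", "name", "annotated", "significant", "expected",
                     "p_raw", "p_bonferroni", "algorithm", "significant_bonferroni"]
        ).to_csv(outdir / f"go_{cfg.go_namespace}.tsv", sep="\t", index=False)
        manifest["counts"].update(
            {"go_terms_tested": 0, "go_universe": len(universe), "go_study": len(study)}
        )
        return
    results = run_enrichment(
        study,
        universe,
        g2g,
        dag,
        namespace=cfg.go_namespace,
        algorithm=cfg.go_algorithm,
        min_genes=cfg.go_min_genes,
    )
    out = results_to_dataframe(results)
    out["significant_bonferroni"] = out["p_bonferroni"] <= cfg.go_alpha
    out.to_csv(outdir / f"go_{cfg.go_namespace}.tsv", sep="\t", index=False)
    manifest["counts"]["go_terms_tested"] = len(out)
    manifest["counts"]["go_universe"] = len(universe)
    manifest["counts"]["go_study"] = len(study)
    manifest["counts"]["go_significant"] = int(out["significant_bonferroni"].sum())


@_stage("cds_pi")
def _stage_cds(cfg: ScanConfig, outdir: Path, manifest: dict):
    groups = read_aligned_fasta(cfg.cds_fasta)
    rows = []
    for gene, copies in sorted(groups.items()):
        seqs = [c.sequence for c in copies if c.status == "complete"]
        value = cds_pi(seqs) if len(seqs) >= 2 else float("nan")
        rows.append({"gene": gene, "n_sequences": len(seqs), "pi": value})
    pd.DataFrame(rows).to_csv(outdir / "cds_pi.tsv", sep="\t", index=False)
    manifest["counts"]["cds_genes"] = len(rows)


@_stage("recomb")
def _stage_recomb(cfg: ScanConfig, flagged, manifest: dict):
    track = read_recombination_track(cfg.recomb)
    merged = flagged.merge(track, on=["chrom", "start"], how="inner", suffixes=("", "_r"))
    if len(merged) >= 3:
        r, p = pearson_correlation(merged["fst"], merged["rate"])
        manifest["correlations"] = {"fst_vs_recomb_r": r, "fst_vs_recomb_p": p}


def run_scan(cfg: ScanConfig, outdir) -> Path:
    """Run all configured stages; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "divscan_version": __version__,
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "counts": {},
    }
    df, pops = _stage_windows(cfg, outdir, manifest)
    flagged, regions = _stage_hdr(cfg, df, outdir, manifest)
    genes_df = _stage_annotate(cfg, flagged, regions, outdir, manifest)
    if cfg.obo and cfg.gene2go:
        if genes_df is None:
            raise PipelineError("stage 'go': GO enrichment requires a GFF gene annotation")
        _stage_go(cfg, genes_df, outdir, manifest)
    if cfg.cds_fasta:
        _stage_cds(cfg, outdir, manifest)
    if cfg.recomb:
        _stage_recomb(cfg, flagged, manifest)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
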