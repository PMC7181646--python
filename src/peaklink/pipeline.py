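"""End-to-end orchestration of the co-occupancy / enhancer-linking analysis.

Stages, in order: co-occupancy of the two factor peak sets through
midpoint windows -> common-region extraction -> chromatin-state
enrichment against the IgG background -> enhancer-state subset ->
regulatory-domain construction -> region-to-gene linking -> intersection
with differential-expression gene sets (all direction variants).  Each
stage's output is persisted, record counts in and out are logged, and a
rerun on identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from peaklink.genomic import (
    PeakSet,
    midpoint,
    read_bed,
    read_gene_table,
    read_genome_table,
    write_bed,
)
from peaklink.cooccupancy import cooccurring_peaks, median_peak_distance
from peaklink.annotation import state_enrichment
from peaklink.linking import (
    build_regulatory_domains,
    gene_set_intersection,
    link_regions_to_genes,
)
from peaklink.quantstats import de_filter, read_de_table

logger = logging.getLogger(__name__)


def _package_version() -> str:
    import peaklink

    return peaklink.__version__


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run.

    Defaults follow the analysis this pipeline reproduces: 100-bp
    midpoint windows, basal domains of 5 kb upstream / 1 kb downstream,
    1 Mb maximum extension, padj < 0.05.
    """

    chrom_sizes: str
    peaks_a: str
    peaks_b: str
    peaks_igg: str
    segmentation: str
    genes: str
    de_tables: dict[str, str] = field(default_factory=dict)
    outdir: str = "pipeline_out"
    window: int = 100
    basal_up: int = 5_000
    basal_down: int = 1_000
    max_ext: int = 1_000_000
    alpha: float = 0.05
    enhancer_state_names: list[str] = field(default_factory=lambda: ["Enhancer"])
    pairing: str = "nearest"
    pseudocount: float = 1e-4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash over every parameter; changes iff any parameter does."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Machine-readable summary of a full run."""

    config: dict
    config_hash: str
    version: str
    cooccupancy: dict
    distance: dict
    state_enrichment: list[dict]
    n_common_regions: int
    n_enhancer_regions: int
    n_links: int
    n_linked_genes: int
    de_intersections: dict
    stage_counts: dict

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json_dict(cls, data: dict) -> "PipelineReport":
        return cls(**data)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute every stage and persist intermediates under cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, dict] = {}

    def _stage(name: str):
        logger.info("stage %s", name)
        return name

    stage = _stage("load_inputs")
    try:
        genome = read_genome_table(cfg.chrom_sizes)
        A = read_bed(cfg.peaks_a, genome, kind="peaks")
        B = read_bed(cfg.peaks_b, genome, kind="peaks")
        igg = read_bed(cfg.peaks_igg, genome, kind="peaks")
        seg = read_bed(cfg.segmentation, genome, kind="segmentation")
        genes = read_gene_table(cfg.genes)
        de_frames = {name: read_de_table(path) for name, path in cfg.de_tables.items()}
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc
    for label, ps in (("peaks_a", A), ("peaks_b", B), ("peaks_igg", igg)):
        if len(ps) == 0:
            raise PipelineError(stage, f"{label} is empty: co-occupancy needs peaks in both sets")
    stage_counts[stage] = {
        "peaks_a": len(A),
        "peaks_b": len(B),
        "peaks_igg": len(igg),
        "genes": len(genes),
    }

    stage = _stage("cooccupancy")
    cooc = cooccurring_peaks(A, B, window=cfg.window)
    dist = median_peak_distance(A, B, window=cfg.window, pairing=cfg.pairing)
    common = PeakSet(label="common_regions", intervals=cooc.common_regions, genome=genome)
    write_bed(common, outdir / "common_regions.bed")
    stage_counts[stage] = {"pairs": cooc.n_pairs, "common_regions": len(common)}

    stage = _stage("state_enrichment")
    enr = state_enrichment(common, igg, seg, pseudocount=cfg.pseudocount)
    enr_frame = enr.to_frame()
    enr_frame.to_csv(outdir / "state_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    stage_counts[stage] = {"states": len(enr.states)}

    stage = _stage("enhancer_subset")
    enh = PeakSet(
        label="enhancer_regions",
        intervals=[
            iv
            for iv in common
            if seg.state_at(iv.chrom, midpoint(iv)) in cfg.enhancer_state_names
        ],
        genome=genome,
    )
    write_bed(enh, outdir / "enhancer_regions.bed")
    stage_counts[stage] = {"in": len(common), "out": len(enh)}

    stage = _stage("gene_linking")
    domains = build_regulatory_domains(
        genes, genome=genome, basal_up=cfg.basal_up, basal_down=cfg.basal_down, max_ext=cfg.max_ext
    )
    with open(outdir / "domains.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tbasal_start\tbasal_end\text_start\text_end\n")
        for d in domains:
            fh.write(
                f"{d.gene_id}\t{d.chrom}\t{d.strand}\t{d.tss}\t{d.basal[0]}\t{d.basal[1]}"
                f"\t{d.extended[0]}\t{d.extended[1]}\n"
            )
    links = link_regions_to_genes(enh, domains)
    with open(outdir / "links.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\tdistance_to_tss\n")
        for l in links:
            fh.write(
                f"{l.region.chrom}\t{l.region.start}\t{l.region.end}\t{l.gene_id}\t{l.distance_to_tss}\n"
            )
    linked_genes = {l.gene_id for l in links}
    stage_counts[stage] = {"domains": len(domains), "links": len(links), "linked_genes": len(linked_genes)}

    stage = _stage("de_intersection")
    de_intersections: dict[str, dict] = {}
    for name, frame in de_frames.items():
        per_dir = {}
        for direction in ("all", "up", "down"):
            query = de_filter(frame, mode="replicates", alpha=cfg.alpha, direction=direction)
            inter = gene_set_intersection(links, query)
            per_dir[direction] = {"n_de": len(query), "n_overlap": inter.n_overlap}
        de_intersections[name] = per_dir
    stage_counts[stage] = {name: v["all"]["n_overlap"] for name, v in de_intersections.items()}

    report = PipelineReport(
        config=cfg.to_dict(),
        config_hash=cfg.config_hash(),
        version=_package_version(),
        cooccupancy=cooc.to_dict(),
        distance=dist.to_dict(),
        state_enrichment=enr_frame.to_dict(orient="records"),
        n_common_regions=len(common),
        n_enhancer_regions=len(enh),
        n_links=len(links),
        n_linked_genes=len(linked_genes),
        de_intersections=de_intersections,
        stage_counts=stage_counts,
    )
    return report


def write_report(report: PipelineReport, outdir: str | Path, figures: bool = False) -> dict[str, Path]:
    """Write JSON, TSV and Markdown forms of the report (and figures).

    The JSON form round-trips to an equal report object; the TSV/MD
    forms are views of the same data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": outdir / "report.json",
        "state_tsv": outdir / "state_enrichment.tsv",
        "markdown": outdir / "report.md",
    }
    with open(paths["json"], "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    pd.DataFrame(report.state_enrichment).to_csv(
        paths["state_tsv"], sep="\t", index=False, float_format="%.6g"
    )
    lines = [
        "# Pipeline report",
        "",
        f"- version: {report.version}",
        f"- config hash: {report.config_hash}",
        f"- window: {report.config['window']} bp; basal {report.config['basal_up']}/"
        f"{report.config['basal_down']} bp; max extension {report.config['max_ext']} bp; "
        f"alpha {report.config['alpha']}",
        "",
        "## Co-occupancy",
        "",
        f"- peaks A/B: {report.cooccupancy['n_A']} / {report.cooccupancy['n_B']}",
        f"- co-occurring pairs: {report.cooccupancy['n_pairs']}",
        f"- fraction A / B / union: {report.cooccupancy['frac_A']:.4f} / "
        f"{report.cooccupancy['frac_B']:.4f} / {report.cooccupancy['frac_union']:.4f}",
        f"- median peak-peak distance: {report.distance['median_bp']} bp "
        f"({report.distance['n_pairs']} pairs)",
        "",
        "## State enrichment (log2 sample / IgG)",
        "",
    ]
    for row in report.state_enrichment:
        lines.append(f"- {row['state']}: {row['log2fc']:.3f}")
    lines += [
        "",
        "## Enhancer linking",
        "",
        f"- common regions: {report.n_common_regions}; enhancer regions: {report.n_enhancer_regions}",
        f"- links: {report.n_links}; linked genes: {report.n_linked_genes}",
        "",
        "## DE intersections",
        "",
    ]
    for name, per_dir in report.de_intersections.items():
        entries = ", ".join(
            f"{d}: {v['n_overlap']}/{v['n_de']}" for d, v in per_dir.items()
        )
        lines.append(f"- {name}: {entries}")
    with open(paths["markdown"], "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = pd.DataFrame(report.state_enrichment)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.bar(frame["state"], frame["log2fc"], color="steelblue")
        ax.axhline(0, color="black", lw=0.8)
        ax.set_ylabel("log2(sample / IgG)")
        ax.set_title("Chromatin-state enrichment of co-occurring peaks")
        plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
        fig.tight_layout()
        fig_path = outdir / "state_enrichment.png"
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
        paths["figure"] = fig_path
    return paths
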