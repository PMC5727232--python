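"""End-to-end orchestration: simulate a dataset, or run the full
enrichment analysis from genome + peaks + TSS to a report bundle.

The JSON report is the machine-readable contract (deterministic bytes for
a given config and seed); the TSVs are the human-readable one. The run log
records every parameter, the seed, and a checksum of every input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .enrichment import (
    UndefinedEnrichmentError,
    cluster_distribution,
    cooccurrence_fraction,
    fold_enrichment,
    profile_regions,
)
from .io import (
    genome_sizes,
    open_genome,
    read_bed,
    read_tss,
    sha256_of,
    write_bed,
    write_fasta,
    write_narrowpeak,
)
from .motifs import builtin_panels, load_panels
from .regions import (
    center_windows,
    exclude_overlapping,
    extract_sequences,
    promoter_filter,
    sample_baseline,
)
from .synthetic import SyntheticSpec, TruthTable, emit_annotation, generate_genome

logger = logging.getLogger("fivegc")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_simulate(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate a synthetic dataset and write the full bundle.

    Emits genome.fa (+ .fai), chrom.sizes, peaks.bed, peaks.narrowPeak,
    tss.bed, truth_regions.tsv, truth_motifs.tsv and spec.yaml (the spec
    echoed back for provenance). Returns the paths written.
    """
    spec.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(spec)
    peaks, tss = emit_annotation(spec, truth)

    paths = {
        "genome": out / "genome.fa",
        "chrom_sizes": out / "chrom.sizes",
        "peaks": out / "peaks.bed",
        "narrowpeak": out / "peaks.narrowPeak",
        "tss": out / "tss.bed",
        "truth_regions": out / "truth_regions.tsv",
        "truth_motifs": out / "truth_motifs.tsv",
        "spec": out / "spec.yaml",
    }
    write_fasta(genome, paths["genome"])
    import pyfaidx

    pyfaidx.Faidx(str(paths["genome"]))  # build the .fai alongside
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in sorted(spec.chrom_lengths):
            fh.write(f"{chrom}\t{spec.chrom_lengths[chrom]}\n")
    write_bed(peaks, paths["peaks"])
    write_narrowpeak(peaks, paths["narrowpeak"])
    with open(paths["tss"], "w") as fh:
        for t in tss:
            fh.write(
                f"{t.chrom}\t{t.position}\t{t.position + 1}\t"
                f"{t.gene_id}\t0\t{t.strand}\n"
            )
    truth.regions.to_csv(paths["truth_regions"], sep="\t", index=False)
    truth.motifs.to_csv(paths["truth_motifs"], sep="\t", index=False)
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=True)
    logger.info("simulated dataset written to %s", out)
    return paths


def load_truth(outdir: str | Path) -> TruthTable:
    """Read back the truth tables written by :func:`run_simulate`."""
    out = Path(outdir)
    return TruthTable(
        regions=pd.read_csv(out / "truth_regions.tsv", sep="\t"),
        motifs=pd.read_csv(out / "truth_motifs.tsv", sep="\t"),
    )


def run_enrich(config: RunConfig) -> dict:
    """Execute the full enrichment analysis and write the report bundle.

    Stages: read peaks -> center 200-bp windows -> promoter filter against
    the TSS annotation -> optional exclusion of regions overlapped by other
    peak sets -> sequence extraction -> motif profiling -> random baseline
    sampling + profiling -> fold enrichment, cluster distributions and
    5GC/CAGAC co-occurrence. Returns the report dict (also written as
    report.json).
    """
    config.validate_inputs()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineError(name, str(exc)) from exc

    genome = stage("open_genome", open_genome, config.genome)
    sizes = genome_sizes(genome)
    peaks = stage("read_peaks", read_bed, config.peaks)
    logger.info("read %d peaks", len(peaks))
    windows = stage(
        "center_windows", center_windows, peaks, sizes,
        width=config.width, use_summit=config.use_summit,
    )
    tss = stage("read_tss", read_tss, config.tss)
    windows = stage(
        "promoter_filter", promoter_filter, windows, tss,
        max_upstream=config.max_upstream, mode=config.promoter_mode,
    )
    n_excluded = 0
    for path in config.exclude:
        other = stage("read_exclude", read_bed, path)
        before = len(windows)
        windows = stage("exclude_overlapping", exclude_overlapping, windows, other)
        n_excluded += before - len(windows)
    logger.info("%d promoter-proximal windows (%d excluded)", len(windows), n_excluded)
    if len(windows) == 0:
        raise PipelineError(
            "promoter_filter", "no regions survive windowing/filtering"
        )

    panels = (
        load_panels(config.panels) if config.panels else builtin_panels()
    )
    panel_list = list(panels.values())

    chip_seqs = stage("extract_sequences", extract_sequences, genome, windows)
    chip_profile = stage(
        "profile_regions", profile_regions, chip_seqs, panel_list,
        strands=config.strands, mask=config.mask,
    )
    baseline = stage(
        "sample_baseline", sample_baseline, sizes,
        n=config.baseline_n, width=config.width, seed=config.seed,
        genome=genome, max_n_fraction=config.max_n_fraction,
    )
    base_seqs = stage("extract_sequences", extract_sequences, genome, baseline)
    base_profile = stage(
        "profile_regions", profile_regions, base_seqs, panel_list,
        strands=config.strands, mask=config.mask,
    )

    enrichments, clusters = {}, {}
    for name in panels:
        try:
            enrichments[name] = fold_enrichment(
                chip_profile, base_profile, name
            ).as_dict()
        except UndefinedEnrichmentError as exc:
            enrichments[name] = {"motif_set": name, "error": str(exc)}
        clusters[name] = {
            "chip": cluster_distribution(
                chip_profile, name, config.cluster_threshold
            ).as_dict(),
            "baseline": cluster_distribution(
                base_profile, name, config.cluster_threshold
            ).as_dict(),
        }
    cooc = cooccurrence_fraction(
        chip_profile, "FIVE_GC", config.cluster_threshold, "CAGAC", 1
    ) if "FIVE_GC" in panels and "CAGAC" in panels else None

    # the report must be byte-identical for identical config + seed; the
    # output directory is where the report lives, not an analysis parameter
    params = {k: v for k, v in asdict(config).items() if k != "outdir"}
    report = {
        "fivegc_version": __version__,
        "parameters": params,
        "panels": {
            name: {
                "patterns": [p.iupac for p in ms.patterns],
                "excluded_5prime": sorted(ms.excluded_5prime)
                if ms.excluded_5prime else None,
            }
            for name, ms in panels.items()
        },
        "n_peaks": len(peaks),
        "n_regions_chip": len(windows),
        "n_regions_excluded_by_overlap": n_excluded,
        "n_regions_baseline": len(baseline),
        "enrichment": enrichments,
        "cluster_distribution": clusters,
        "cooccurrence_5gc_ge_threshold_with_cagac": cooc,
    }

    # outputs
    write_bed(windows, out / "windows.bed")
    write_bed(baseline, out / "baseline.bed")
    chip_profile.to_csv(out / "profile_chip.tsv", sep="\t", index=False)
    base_profile.to_csv(out / "profile_baseline.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_summary_tsv(report, out / "summary.tsv")
    _write_run_log(config, out / "run_log.txt")
    logger.info("report written to %s", out / "report.json")
    return report


def _write_summary_tsv(report: dict, path: Path) -> None:
    rows = []
    for name, e in report["enrichment"].items():
        rows.append(
            {
                "motif_set": name,
                "mean_chip": e.get("mean_per_region_chip"),
                "mean_baseline": e.get("mean_per_region_baseline"),
                "fold_enrichment": e.get("fold_enrichment"),
                "chip_ge_threshold_fraction": report["cluster_distribution"][
                    name
                ]["chip"]["fractions"][
                    f"{report['parameters']['cluster_threshold']}+"
                ],
                "baseline_ge_threshold_fraction": report[
                    "cluster_distribution"
                ][name]["baseline"]["fractions"][
                    f"{report['parameters']['cluster_threshold']}+"
                ],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_run_log(config: RunConfig, path: Path) -> None:
    lines = [f"fivegc {__version__}", "parameters:"]
    for k, v in sorted(asdict(config).items()):
        lines.append(f"  {k} = {v!r}")
    lines.append("input checksums (sha256):")
    inputs = [config.genome, config.peaks, config.tss, *config.exclude]
    if config.panels:
        inputs.append(config.panels)
    for p in inputs:
        lines.append(f"  {p} = {sha256_of(p)}")
    path.write_text("\n".join(lines) + "\n")
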