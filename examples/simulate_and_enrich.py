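"""Simulate a small bound-region dataset and run the full enrichment
analysis on it.

Generates a 600-kb two-chromosome genome (GC fraction 0.5) with 100 bound
regions, each planted with three 5GC-panel motifs and placed within
1000 bp upstream of a generated TSS; then runs the complete pipeline:
peak-centered 200-bp windows, promoter filtering, motif profiling, a
500-region random baseline, fold enrichment and cluster statistics.
"""

import tempfile
from pathlib import Path

from fivegc import RunConfig, SyntheticSpec, run_enrich, run_simulate

with tempfile.TemporaryDirectory() as tmp:
    ds = Path(tmp) / "dataset"
    run_simulate(
        SyntheticSpec(
            chrom_lengths={"c1": 400_000, "c2": 200_000},
            gc_fraction=0.5,
            n_bound_regions=100,
            plant_rate=3,
            promoter_fraction=1.0,
            peak_jitter_sd=0.0,
            seed=11,
        ),
        ds,
    )
    report = run_enrich(
        RunConfig(
            genome=str(ds / "genome.fa"),
            peaks=str(ds / "peaks.bed"),
            tss=str(ds / "tss.bed"),
            outdir=str(Path(tmp) / "run"),
            baseline_n=500,
            seed=23,
        )
    )

e = report["enrichment"]["FIVE_GC"]
cd = report["cluster_distribution"]["FIVE_GC"]
print(f"promoter-proximal regions analysed: {report['n_regions_chip']}")
print(
    f"5GC motifs per 200-bp region: {e['mean_per_region_chip']:.2f} bound "
    f"vs {e['mean_per_region_baseline']:.2f} baseline "
    f"-> fold enrichment {e['fold_enrichment']:.2f}"
)
print(
    "fraction of regions with >=3 5GC motifs: "
    f"{cd['chip']['fractions']['3+']:.0%} bound vs "
    f"{cd['baseline']['fractions']['3+']:.0%} baseline"
)
print(
    "\nEvery bound region was planted with three motifs, so the bound"
    "\n>=3 fraction is 100% by construction; the baseline fraction is the"
    "\nchance rate for GC-rich 5-mers in random 50%-GC sequence (~20%),"
    "\nand the fold is (3 + background)/background ~ 3."
)
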