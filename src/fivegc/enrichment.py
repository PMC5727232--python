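"""Per-region motif statistics.

The core quantities are simple by design, mirroring how the underlying
observation is usually reported: the mean number of motif occurrences per
fixed-width region ("motifs per 200 bp"), the ratio of that mean between
ChIP-bound and random baseline regions (fold enrichment), and the fraction
of regions carrying 0, 1, 2 or >=3 panel motifs (cluster distribution).
Two structural-model utilities live here too: the footprint-capacity
calculation — how many MH1 domains can occupy a motif cluster at once given
a ~6-bp footprint per domain — and the EMSA probe tiler used to walk a
GC-rich segment with overlapping duplex probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .motifs import MotifHit, MotifSet, count_hits_in_region, scan_sequence

REGION_COLUMNS = ["region", "chrom", "start", "end"]


class UndefinedEnrichmentError(ValueError):
    """Raised when the baseline mean is zero and a fold ratio is undefined."""


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold enrichment of one panel: ratio of per-region means."""

    motif_set: str
    mean_per_region_chip: float
    mean_per_region_baseline: float
    fold_enrichment: float
    n_chip_regions: int
    n_baseline_regions: int

    def as_dict(self) -> dict:
        return {
            "motif_set": self.motif_set,
            "mean_per_region_chip": self.mean_per_region_chip,
            "mean_per_region_baseline": self.mean_per_region_baseline,
            "fold_enrichment": self.fold_enrichment,
            "n_chip_regions": self.n_chip_regions,
            "n_baseline_regions": self.n_baseline_regions,
        }


@dataclass(frozen=True)
class ClusterDistribution:
    """Fractions of regions with exactly 0..t-1 and >= t panel motifs.

    ``tallies`` maps each bin label ("0", "1", "2", "3+") to its integer
    count; fractions always reproduce as tally / total.
    """

    motif_set: str
    threshold: int
    tallies: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.tallies}
        return {k: v / self.total for k, v in self.tallies.items()}

    @property
    def ge_threshold_fraction(self) -> float:
        return self.fractions[f"{self.threshold}+"]

    def as_dict(self) -> dict:
        return {
            "motif_set": self.motif_set,
            "threshold": self.threshold,
            "tallies": dict(self.tallies),
            "fractions": self.fractions,
            "total": self.total,
        }


def profile_regions(
    region_seqs: list[tuple[GenomicInterval, str]],
    panels: list[MotifSet],
    strands: str = "both",
    mask: str = "include",
) -> pd.DataFrame:
    """Count panel motifs in each region.

    Returns one row per region with a column per panel (total count) and,
    for multi-pattern panels, a ``panel:pattern`` column per member so the
    pooled total remains auditable. All sequences must share one length —
    counts are densities over equal-width regions.
    """
    if not region_seqs:
        raise ValueError("no regions to profile")
    widths = {len(s) for _, s in region_seqs}
    if len(widths) != 1:
        raise ValueError(f"ragged region sequence lengths: {sorted(widths)}")

    rows = []
    for i, (region, seq) in enumerate(region_seqs):
        row: dict = {
            "region": region.name or f"region_{i}",
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
        }
        for panel in panels:
            hits = scan_sequence(
                seq, panel, strands=strands, mask=mask,
                chrom=region.chrom, offset=region.start,
            )
            row[panel.name] = count_hits_in_region(hits, region)
            if len(panel.patterns) > 1:
                for pat in panel.patterns:
                    sub = [h for h in hits if h.pattern_name == pat.name]
                    row[f"{panel.name}:{pat.name}"] = count_hits_in_region(
                        sub, region
                    )
        rows.append(row)
    return pd.DataFrame(rows)


def fold_enrichment(
    chip: pd.DataFrame, baseline: pd.DataFrame, panel: str
) -> EnrichmentResult:
    """Ratio of per-region mean counts, ChIP over baseline.

    Raises
    ------
    UndefinedEnrichmentError
        If the baseline mean is zero — the ratio is reported as an explicit
        error, never as infinity.
    """
    for name, prof in (("chip", chip), ("baseline", baseline)):
        if panel not in prof.columns:
            raise KeyError(f"panel {panel!r} not in {name} profile")
        if len(prof) == 0:
            raise ValueError(f"{name} profile is empty")
    mean_chip = float(chip[panel].mean())
    mean_base = float(baseline[panel].mean())
    if mean_base == 0.0:
        raise UndefinedEnrichmentError(
            f"baseline mean for panel {panel!r} is zero; "
            "fold enrichment is undefined"
        )
    return EnrichmentResult(
        motif_set=panel,
        mean_per_region_chip=mean_chip,
        mean_per_region_baseline=mean_base,
        fold_enrichment=mean_chip / mean_base,
        n_chip_regions=len(chip),
        n_baseline_regions=len(baseline),
    )


def cluster_distribution(
    profile: pd.DataFrame, panel: str, threshold: int = 3
) -> ClusterDistribution:
    """Fractions of regions with exactly 0 .. threshold-1 and >= threshold
    panel motifs."""
    if panel not in profile.columns:
        raise KeyError(f"panel {panel!r} not in profile")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = profile[panel].to_numpy()
    tallies = {str(k): int((counts == k).sum()) for k in range(threshold)}
    tallies[f"{threshold}+"] = int((counts >= threshold).sum())
    return ClusterDistribution(
        motif_set=panel,
        threshold=threshold,
        tallies=tallies,
        total=len(counts),
    )


def cooccurrence_fraction(
    profile: pd.DataFrame,
    panel_a: str,
    min_a: int = 3,
    panel_b: str = "CAGAC",
    min_b: int = 1,
) -> float:
    """Fraction of regions with >= min_a of panel_a AND >= min_b of panel_b.

    Quantifies how often GC-motif clusters are accompanied by classical
    CAGAC elements in the same region.
    """
    for panel in (panel_a, panel_b):
        if panel not in profile.columns:
            raise KeyError(f"panel {panel!r} not in profile")
    if len(profile) == 0:
        return 0.0
    both = (profile[panel_a] >= min_a) & (profile[panel_b] >= min_b)
    return float(both.mean())


def site_capacity(hits: list[MotifHit], footprint: int = 6) -> int:
    """Maximum number of MH1 domains that can occupy ``hits`` at once.

    Each bound domain covers ``footprint`` bp anchored at its motif start
    (the contact area extends ~1 bp 3' of the 5-bp motif via backbone
    hydrogen bonds). The answer is the maximum number of mutually
    non-overlapping footprints — unit-weight interval scheduling, solved
    exactly by the earliest-end greedy rule.
    """
    if hits and footprint < max(len(h.interval) for h in hits):
        raise ValueError(
            f"footprint {footprint} shorter than the longest motif hit"
        )
    spans = sorted(
        (h.interval.start + footprint, h.interval.start) for h in hits
    )
    chosen = 0
    cursor = -(10**18)
    for end, start in spans:
        if start >= cursor:
            chosen += 1
            cursor = end
    return chosen


def design_tiling_probes(
    segment: str, probe_len: int = 20, step: int = 2
) -> list[tuple[int, str]]:
    """Tile a segment with overlapping fixed-length duplex probes.

    Probes start at offsets 0, step, 2*step, ... up to
    ``len(segment) - probe_len`` inclusive; each is the forward-strand
    substring (the duplex is implied). This is the sliding-window design
    used to narrow a binding site down within a GC-rich segment by EMSA.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(segment) < probe_len:
        raise ValueError(
            f"segment ({len(segment)} bp) shorter than probe length {probe_len}"
        )
    return [
        (off, segment[off : off + probe_len])
        for off in range(0, len(segment) - probe_len + 1, step)
    ]


def bootstrap_fold_ci(
    chip_counts: np.ndarray | pd.Series,
    baseline_counts: np.ndarray | pd.Series,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the fold enrichment, resampling regions.

    An optional extra beyond the point-estimate ratio: useful for judging
    whether an observed fold could be sampling noise at small region
    counts. Resamples with zero-baseline draws are discarded.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(chip_counts, dtype=float)
    b = np.asarray(baseline_counts, dtype=float)
    folds = []
    for _ in range(n_boot):
        mb = b[rng.integers(0, len(b), len(b))].mean()
        if mb == 0:
            continue
        folds.append(c[rng.integers(0, len(c), len(c))].mean() / mb)
    if not folds:
        raise UndefinedEnrichmentError("all bootstrap baseline means were zero")
    lo, hi = np.quantile(folds, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
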