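"""Self-contained synthetic datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: an
i.i.d. background genome with a configurable GC fraction, "bound" regions
carrying a known number of planted 5GC-panel motifs, ChIP-Seq-like peak
records centered (with Gaussian jitter) on those regions, and a TSS
annotation placing a configurable fraction of bound regions within 1000 bp
upstream of a transcription start site. Because the background is i.i.d.,
the expected motif count per baseline region has an exact closed form
(:func:`expected_background_count`), which serves as the analytic oracle
for the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, TSSRecord
from .motifs import MotifPattern, MotifSet, builtin_panels, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_chrom_lengths() -> dict[str, int]:
    return {"chrS1": 2_000_000, "chrS2": 1_000_000}


def _default_motif_weights() -> dict[str, float]:
    return {"GGCGC": 0.25, "GGCGG": 0.25, "GGCCG": 0.25, "GGCTG": 0.25}


@dataclass
class SyntheticSpec:
    """All parameters of the synthetic dataset generator.

    Parameters
    ----------
    chrom_lengths
        Chromosome name -> length in bp.
    gc_fraction
        Background GC content g; bases are i.i.d. with
        P(G) = P(C) = g/2 and P(A) = P(T) = (1-g)/2.
    n_bound_regions
        Number of non-overlapping bound regions to place.
    region_width
        Width of each bound region in bp.
    plant_rate
        Planted 5GC-panel motifs per bound region: a fixed integer k, or
        the mean of a Poisson draw when ``plant_poisson`` is set.
    motif_weights
        Probability of each panel pattern when planting; must sum to 1.
    plant_strand_prob
        Probability a planted motif goes on the minus strand.
    peak_jitter_sd
        SD (bp) of the Gaussian displacement of peak centers from bound
        region centers.
    promoter_fraction
        Fraction of bound regions given a TSS placed so the region center
        is uniformly 0-1000 bp upstream of it.
    n_decoy_tss
        TSS records placed far (> 1000 bp + margin) from every bound
        region, so the annotation exists independently of binding.
    min_region_spacing
        Minimum edge-to-edge gap between bound regions (bp). Kept large
        enough that a TSS belonging to one region can never make another
        region promoter-proximal.
    seed
        Seed for all randomness; identical specs give byte-identical
        datasets.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    gc_fraction: float = 0.41
    n_bound_regions: int = 500
    region_width: int = 200
    plant_rate: float = 3
    plant_poisson: bool = False
    motif_weights: dict[str, float] = field(default_factory=_default_motif_weights)
    plant_strand_prob: float = 0.5
    peak_jitter_sd: float = 20.0
    promoter_fraction: float = 1.0
    n_decoy_tss: int = 50
    min_region_spacing: int = 2000
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if not self.chrom_lengths:
            errors.append("chrom_lengths: at least one chromosome required")
        if not 0.0 <= self.gc_fraction <= 1.0:
            errors.append("gc_fraction: must be in [0, 1]")
        if self.n_bound_regions < 0:
            errors.append("n_bound_regions: must be >= 0")
        if self.region_width < 5:
            errors.append("region_width: must be >= motif length (5)")
        if self.plant_rate < 0:
            errors.append("plant_rate: must be >= 0")
        if abs(sum(self.motif_weights.values()) - 1.0) > 1e-9:
            errors.append("motif_weights: must sum to 1")
        if not 0.0 <= self.plant_strand_prob <= 1.0:
            errors.append("plant_strand_prob: must be in [0, 1]")
        if not 0.0 <= self.promoter_fraction <= 1.0:
            errors.append("promoter_fraction: must be in [0, 1]")
        if self.peak_jitter_sd < 0:
            errors.append("peak_jitter_sd: must be >= 0")
        if not self.plant_poisson:
            k = int(self.plant_rate)
            # non-overlapping 5-mers must fit with room to redraw
            if k * 5 > self.region_width:
                errors.append(
                    f"region_width {self.region_width} too small for "
                    f"{k} non-overlapping planted motifs"
                )
        if errors:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(errors))


@dataclass
class TruthTable:
    """Ground truth of a synthetic dataset.

    ``regions``: one row per bound region (region_id, chrom, start, end,
    n_planted). ``motifs``: one row per planted motif (region_id, chrom,
    start, end, pattern, strand, forward_seq); every planted motif is
    recoverable by the scanner at its recorded footprint and strand.
    """

    regions: pd.DataFrame
    motifs: pd.DataFrame

    def region_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.region_id)
            for r in self.regions.itertuples()
        ]


def _place_regions(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Uniform non-overlapping placement with a minimum gap.

    Per chromosome, n starts are drawn by the classic slack trick: choose n
    sorted offsets in the leftover space, then shift each by the cumulative
    width+gap of its predecessors.
    """
    w, gap = spec.region_width, spec.min_region_spacing
    chroms = sorted(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    n = spec.n_bound_regions
    if n == 0:
        return []
    # allocate proportionally to length, largest remainder
    quota = lengths / lengths.sum() * n
    alloc = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - alloc)):
        if alloc.sum() >= n:
            break
        alloc[i] += 1
    placements: list[tuple[str, int]] = []
    for c, n_c in zip(chroms, alloc):
        if n_c == 0:
            continue
        L = spec.chrom_lengths[c]
        slack = L - n_c * w - (n_c - 1) * gap
        if slack < 0:
            raise ValueError(
                f"cannot place {n_c} regions of {w} bp with {gap} bp spacing "
                f"on {c} ({L} bp)"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=n_c))
        for i, off in enumerate(offsets):
            placements.append((c, int(off + i * (w + gap))))
    return placements


def _hits_overlapping(seq: str, lo: int, hi: int, panel: MotifSet) -> int:
    """Panel hits (both strands) in ``seq`` whose footprint intersects
    [lo, hi)."""
    from .motifs import scan_sequence

    return sum(
        1
        for h in scan_sequence(seq, panel, strands="both")
        if h.interval.start < hi and lo < h.interval.end
    )


def generate_genome(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], TruthTable]:
    """Draw the background genome and plant motifs in bound regions.

    Returns the chromosome sequences and the :class:`TruthTable`. Planting
    is *clean insertion*: each planted motif must add exactly one panel
    occurrence to the region. An offset is redrawn when the written bases
    would overlap an earlier plant, destroy a pre-existing panel hit, or
    create an extra panel hit at the junction with flanking sequence.
    Consequently a bound region's total panel count equals its background
    count plus the number of plants — the truth count is exact, and the
    expected bound-region count is ``expected_background_count(...) + k``.
    A minus-strand plant writes the reverse complement of the pattern on
    the forward strand.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    g = spec.gc_fraction
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])

    arrays: dict[str, np.ndarray] = {}
    for chrom in sorted(spec.chrom_lengths):
        L = spec.chrom_lengths[chrom]
        arrays[chrom] = rng.choice(_BASES, size=L, p=probs)

    placements = _place_regions(spec, rng)
    patterns = list(spec.motif_weights)
    weights = np.array([spec.motif_weights[p] for p in patterns])
    plant_panel = MotifSet(
        "plant", tuple(MotifPattern(p, p) for p in patterns)
    )
    w = spec.region_width

    region_rows, motif_rows = [], []
    for idx, (chrom, start) in enumerate(placements):
        region_id = f"bound_{idx:05d}"
        if spec.plant_poisson:
            k = int(rng.poisson(spec.plant_rate))
            while k * 5 > w:  # cannot exceed what the region can hold
                k = int(rng.poisson(spec.plant_rate))
        else:
            k = int(spec.plant_rate)
        # clean-insertion planting: redraw until the plant adds exactly
        # one panel occurrence (no junction hits, nothing destroyed)
        local = arrays[chrom][start : start + w]  # numpy view, writes through
        taken: list[tuple[int, int]] = []
        attempts = 0
        while len(taken) < k:
            attempts += 1
            if attempts > 500 * max(k, 1):
                raise ValueError(
                    f"could not cleanly place {k} motifs in a {w} bp region "
                    f"after {attempts} attempts"
                )
            off = int(rng.integers(0, w - 5 + 1))
            if any(off < e and s < off + 5 for s, e in taken):
                continue
            pat = patterns[int(rng.choice(len(patterns), p=weights))]
            strand = "-" if rng.random() < spec.plant_strand_prob else "+"
            forward = pat if strand == "+" else reverse_complement(pat)
            # any hit created/destroyed by the write touches a written base,
            # so the clamped +/-4 bp window sees every change
            lo, hi = max(0, off - 4), min(w, off + 5 + 4)
            before = local[lo:hi].tobytes().decode("ascii")
            if _hits_overlapping(before, off - lo, off - lo + 5, plant_panel):
                continue  # would destroy an existing panel hit
            after = (
                before[: off - lo] + forward + before[off - lo + 5 :]
            )
            if _hits_overlapping(after, off - lo, off - lo + 5, plant_panel) != 1:
                continue  # junction would create an extra panel hit
            taken.append((off, off + 5))
            local[off : off + 5] = np.frombuffer(
                forward.encode(), dtype=np.uint8
            )
            motif_rows.append(
                {
                    "region_id": region_id,
                    "chrom": chrom,
                    "start": start + off,
                    "end": start + off + 5,
                    "pattern": pat,
                    "strand": strand,
                    "forward_seq": forward,
                }
            )
        region_rows.append(
            {
                "region_id": region_id,
                "chrom": chrom,
                "start": start,
                "end": start + w,
                "n_planted": k,
            }
        )

    genome = {c: a.tobytes().decode("ascii") for c, a in arrays.items()}
    truth = TruthTable(
        regions=pd.DataFrame(
            region_rows,
            columns=["region_id", "chrom", "start", "end", "n_planted"],
        ),
        motifs=pd.DataFrame(
            motif_rows,
            columns=[
                "region_id", "chrom", "start", "end",
                "pattern", "strand", "forward_seq",
            ],
        ),
    )
    return genome, truth


def emit_annotation(
    spec: SyntheticSpec,
    truth: TruthTable,
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomicInterval], list[TSSRecord]]:
    """Derive peak and TSS records from the truth table.

    One peak per bound region, its center displaced by N(0, peak_jitter_sd)
    rounded to integer and clipped so the peak stays within the
    chromosome; the summit column records the true (jittered) center. For
    the promoter fraction of regions a TSS is placed so the region center
    is uniformly 0-1000 bp upstream of it on a random strand. Decoy TSS are
    kept > 1000 bp (+ margin) from every bound-region center.
    """
    if rng is None:
        # independent stream from the genome draw, still seed-determined
        rng = np.random.default_rng((spec.seed + 1) % 2**31)
    w = spec.region_width
    half = w // 2

    peaks: list[GenomicInterval] = []
    centers_by_chrom: dict[str, list[int]] = {}
    for r in truth.regions.itertuples():
        L = spec.chrom_lengths[r.chrom]
        center = (int(r.start) + int(r.end)) // 2
        jit = int(round(rng.normal(0.0, spec.peak_jitter_sd)))
        cj = min(max(center + jit, half), L - (w - half))
        peaks.append(
            GenomicInterval(
                r.chrom, cj - half, cj - half + w,
                name=f"peak_{r.region_id}", summit_offset=half,
            )
        )
        centers_by_chrom.setdefault(r.chrom, []).append(center)

    tss: list[TSSRecord] = []
    n = len(truth.regions)
    n_prom = int(round(spec.promoter_fraction * n))
    chosen = set(
        rng.choice(n, size=n_prom, replace=False).tolist()
    ) if n_prom else set()
    for i, r in enumerate(truth.regions.itertuples()):
        if i not in chosen:
            continue
        L = spec.chrom_lengths[r.chrom]
        center = (int(r.start) + int(r.end)) // 2
        u = int(rng.integers(0, 1001))
        strand = "+" if rng.random() < 0.5 else "-"
        # region center must sit 0..1000 bp upstream of the TSS
        if strand == "+" and center + u >= L:
            strand = "-"
        if strand == "-" and center - u < 0:
            strand = "+"
        pos = center + u if strand == "+" else center - u
        tss.append(TSSRecord(r.chrom, pos, strand, f"gene_{r.region_id}"))

    # decoys: never promoter-proximal to any bound region center
    margin = 1000 + w + int(8 * spec.peak_jitter_sd)
    chroms = sorted(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    cw = lengths / lengths.sum()
    sorted_centers = {
        c: np.array(sorted(v)) for c, v in centers_by_chrom.items()
    }
    placed, attempts = 0, 0
    while placed < spec.n_decoy_tss and attempts < 200 * max(spec.n_decoy_tss, 1):
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=cw))]
        pos = int(rng.integers(0, spec.chrom_lengths[chrom]))
        centers = sorted_centers.get(chrom)
        if centers is not None and len(centers):
            j = int(np.searchsorted(centers, pos))
            near = [
                centers[k] for k in (j - 1, j) if 0 <= k < len(centers)
            ]
            if any(abs(pos - c) <= margin for c in near):
                continue
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TSSRecord(chrom, pos, strand, f"decoy_{placed:04d}"))
        placed += 1
    if placed < spec.n_decoy_tss:
        raise RuntimeError(
            f"could only place {placed}/{spec.n_decoy_tss} decoy TSS; "
            "genome too crowded with bound regions"
        )
    return peaks, tss


def expected_background_count(
    panel: MotifSet | str,
    region_width: int = 200,
    gc_fraction: float = 0.5,
    strands: str = "both",
) -> float:
    """Exact first-order expected panel count per i.i.d. background region.

    Sum over patterns and strands of ``(W - k + 1) * prod(P(base))`` with
    P(G) = P(C) = g/2 and P(A) = P(T) = (1-g)/2. Overlap between potential
    occurrences is ignored — this is the expectation of the occurrence
    count, which is exact by linearity, not a Poisson claim about its
    distribution.
    """
    if isinstance(panel, str):
        panel = builtin_panels()[panel]
    if strands not in ("+", "-", "both"):
        raise ValueError(f"invalid strand selector {strands!r}")
    g = gc_fraction
    p_base = {"A": (1 - g) / 2, "T": (1 - g) / 2, "C": g / 2, "G": g / 2}
    total = 0.0
    for pat in panel.patterns:
        if any(c not in "ACGT" for c in pat.iupac):
            raise ValueError(
                f"expected_background_count needs literal patterns, got "
                f"{pat.iupac!r}"
            )
        positions = region_width - pat.length + 1
        if positions <= 0:
            continue
        fwd = math.prod(p_base[c] for c in pat.iupac)
        rev = math.prod(p_base[c] for c in reverse_complement(pat.iupac))
        if strands == "both":
            total += positions * (fwd + rev)
        elif strands == "+":
            total += positions * fwd
        else:
            total += positions * rev
    return total
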