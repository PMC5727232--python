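"""Region-set construction: peak-centered windows, promoter filtering,
peak-vs-peak exclusion, random baseline sampling and sequence extraction.

The analysis unit is a fixed-width window (200 bp by default) centered on
each ChIP-Seq peak; the enrichment denominator is a set of equally sized
regions drawn at random genomic coordinates. Keeping every region the same
width makes per-region motif counts directly comparable densities.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, RegionSet, TSSRecord, deduplicate


def center_windows(
    peaks: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    width: int = 200,
    use_summit: bool = False,
) -> RegionSet:
    """Cut a fixed-width window centered on each peak.

    The center is the interval midpoint ``floor((start + end) / 2)``, or
    ``start + summit_offset`` when ``use_summit`` is set and the peak
    carries a summit. Windows extending past a chromosome edge are dropped
    (not clipped) so every output region has the same width; exact
    duplicate windows are removed keeping first-occurrence order.

    Raises
    ------
    KeyError
        If a peak's chromosome has no entry in ``chrom_sizes``.
    """
    if width <= 0 or width % 2:
        raise ValueError(f"width must be even and positive, got {width}")
    half = width // 2
    out: list[GenomicInterval] = []
    for p in peaks:
        if p.chrom not in chrom_sizes:
            raise KeyError(
                f"no chromosome size for {p.chrom!r} "
                f"(peak {p.chrom}:{p.start}-{p.end})"
            )
        if use_summit and p.summit_offset != -1:
            center = p.start + p.summit_offset
        else:
            center = p.center
        start, end = center - half, center + half
        if start < 0 or end > chrom_sizes[p.chrom]:
            continue
        out.append(GenomicInterval(p.chrom, start, end, name=p.name))
    return RegionSet(deduplicate(out), provenance="chip", width=width)


def promoter_filter(
    regions: RegionSet,
    tss: Sequence[TSSRecord],
    max_upstream: int = 1000,
    mode: str = "upstream_only",
) -> RegionSet:
    """Keep regions whose center is promoter-proximal to at least one TSS.

    ``upstream_only`` (default) keeps a region iff its center lies in the
    strand-aware window ``[position - max_upstream, position]`` of a
    plus-strand TSS (mirrored for minus strand). ``symmetric`` uses
    ``position ± max_upstream`` regardless of strand, so its output is a
    superset of the upstream-only one.

    An empty TSS list is rejected: "no annotation" must not silently read
    as "no promoters".
    """
    if not tss:
        raise ValueError("empty TSS list: provide a TSS annotation")
    if mode not in ("upstream_only", "symmetric"):
        raise ValueError(f"invalid promoter filter mode {mode!r}")

    # per-chrom sorted arrays of candidate windows for fast center lookup
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in tss:
        if mode == "symmetric":
            lo, hi = t.position - max_upstream, t.position + max_upstream
        elif t.strand == "+":
            lo, hi = t.position - max_upstream, t.position
        else:
            lo, hi = t.position, t.position + max_upstream
        by_chrom.setdefault(t.chrom, []).append((lo, hi))

    kept = [
        r
        for r in regions
        if any(
            lo <= r.center <= hi for lo, hi in by_chrom.get(r.chrom, ())
        )
    ]
    return RegionSet(kept, provenance=regions.provenance, width=regions.width)


def exclude_overlapping(
    regions: RegionSet, other_peaks: Sequence[GenomicInterval]
) -> RegionSet:
    """Remove regions sharing >= 1 bp with any interval in ``other_peaks``.

    Used for the control that discards Smad peaks co-occupied by other
    GC-binding factors (SP1, CTCF). Half-open abutment is not overlap.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for o in other_peaks:
        by_chrom.setdefault(o.chrom, []).append((o.start, o.end))
    for ivs in by_chrom.values():
        ivs.sort()

    def hits_any(r: GenomicInterval) -> bool:
        ivs = by_chrom.get(r.chrom)
        if not ivs:
            return False
        # linear scan is fine at the list sizes this pipeline sees
        return any(s < r.end and r.start < e for s, e in ivs)

    kept = [r for r in regions if not hits_any(r)]
    return RegionSet(kept, provenance=regions.provenance, width=regions.width)


def sample_baseline(
    chrom_sizes: Mapping[str, int],
    n: int = 500,
    width: int = 200,
    seed: int | None = None,
    genome=None,
    max_n_fraction: float = 0.1,
    max_redraw_factor: int = 50,
) -> RegionSet:
    """Draw ``n`` fixed-width regions at random genomic coordinates.

    Starts are uniform over all valid (chrom, start) pairs — chromosomes
    are weighted by their number of valid start positions — so no region
    ever crosses a chromosome boundary. When a ``genome`` (pyfaidx Fasta or
    dict of sequences) is supplied, draws whose sequence exceeds
    ``max_n_fraction`` ambiguous bases are rejected and redrawn, keeping
    assembly gaps from deflating baseline motif rates. Same seed, same
    output.
    """
    if seed is None:
        raise ValueError("sample_baseline requires an explicit seed")
    chroms = [c for c, L in chrom_sizes.items() if L >= width]
    if not chroms:
        raise ValueError(f"no chromosome is at least {width} bp long")
    valid = np.array([chrom_sizes[c] - width + 1 for c in chroms], dtype=float)
    weights = valid / valid.sum()
    rng = np.random.default_rng(seed)

    out: list[GenomicInterval] = []
    attempts = 0
    budget = max_redraw_factor * n
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} baseline regions after {attempts} draws "
                f"(placed {len(out)}); genome too gappy or too small"
            )
        attempts += 1
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        start = int(rng.integers(0, chrom_sizes[chrom] - width + 1))
        if genome is not None:
            seq = str(genome[chrom][start : start + width]).upper()
            if seq.count("N") > max_n_fraction * width:
                continue
        out.append(
            GenomicInterval(chrom, start, start + width, name=f"baseline_{len(out)}")
        )
    return RegionSet(out, provenance="baseline", width=width)


def extract_sequences(
    genome, regions: RegionSet | Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, str]]:
    """Fetch the uppercase forward-strand sequence of each region.

    ``genome`` may be a pyfaidx Fasta or a plain dict of chromosome
    sequences. Order is preserved; an out-of-bounds region or unknown
    chromosome is rejected naming the offending region.
    """
    out: list[tuple[GenomicInterval, str]] = []
    for r in regions:
        try:
            record = genome[r.chrom]
        except KeyError:
            raise KeyError(
                f"chromosome {r.chrom!r} not in genome "
                f"(region {r.chrom}:{r.start}-{r.end})"
            ) from None
        if r.end > len(record):
            raise ValueError(
                f"region {r.chrom}:{r.start}-{r.end} extends past chromosome "
                f"end ({len(record)} bp)"
            )
        out.append((r, str(record[r.start : r.end]).upper()))
    return out
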