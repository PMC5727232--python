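"""Coordinate primitives shared by every stage of the pipeline.

All coordinates are 0-based, half-open (BED convention). Conversion to and
from 1-based display coordinates happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GenomicInterval:
    """A chrom/start/end/strand span.

    The universal coordinate unit for ChIP-Seq peaks, analysis windows,
    baseline regions and motif hit footprints.

    Parameters
    ----------
    chrom
        Chromosome name. May be empty for hits on bare sequences.
    start, end
        0-based half-open span; ``0 <= start < end``.
    strand
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    name
        Optional label (peak id, region id, ...).
    summit_offset
        narrowPeak column-10 summit, relative to ``start``; ``-1`` means
        absent.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside interval of "
                f"length {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Integer midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share at least one base on the same chrom."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site with the strand needed to orient
    "upstream"."""

    chrom: str
    position: int  # 0-based coordinate of the TSS base
    strand: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"TSS {self.gene_id or self.chrom}:{self.position} needs an "
                f"explicit +/- strand, got {self.strand!r}"
            )
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")


@dataclass
class RegionSet:
    """An ordered, deduplicated list of same-width regions.

    ``width is None`` for raw (un-windowed) peak lists; once windows are cut
    every region must share the common width so that per-region motif counts
    are densities over equal sequence.
    """

    regions: list[GenomicInterval] = field(default_factory=list)
    provenance: str = ""  # chip | baseline | synthetic
    width: int | None = None

    def __post_init__(self) -> None:
        if self.width is not None:
            bad = [r for r in self.regions if len(r) != self.width]
            if bad:
                r = bad[0]
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} has width {len(r)}, "
                    f"expected {self.width}"
                )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.regions[i]


def deduplicate(regions: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Drop exact (chrom, start, end) duplicates, keeping first occurrence
    order."""
    seen: set[tuple[str, int, int]] = set()
    out: list[GenomicInterval] = []
    for r in regions:
        key = (r.chrom, r.start, r.end)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out
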