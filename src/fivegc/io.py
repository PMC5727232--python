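"""Readers and writers for the standard interval/annotation formats.

Peaks come in as BED3, BED6 or ENCODE narrowPeak; TSS annotations as BED6
(one record per TSS) or GFF3/GTF transcript records, where the 5' end of
the transcript on its strand becomes the TSS. Genome access goes through
pyfaidx; GFF/GTF parsing through gffutils.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pyfaidx

from .intervals import GenomicInterval, RegionSet, TSSRecord

_GFF_SUFFIXES = {".gff", ".gff3", ".gtf"}
_TRANSCRIPT_TYPES = {"transcript", "mRNA", "mrna"}


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-style two-column ``chrom.sizes`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak intervals.

    narrowPeak (10 columns) summits are stored in ``summit_offset``;
    a ``-1`` summit column means absent, as in the format spec.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            summit = int(f[9]) if len(f) == 10 else -1
            out.append(
                GenomicInterval(chrom, start, end, strand, name, summit)
            )
    return out


def write_bed(regions: RegionSet | list[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = r.name or f"region_{i}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand if r.strand != '.' else '.'}\n")


def write_narrowpeak(regions: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = r.name or f"peak_{i}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t"
                f"{r.strand if r.strand != '.' else '.'}\t0\t-1\t-1\t{r.summit_offset}\n"
            )


def read_tss(path: str | Path) -> list[TSSRecord]:
    """Read TSS records from BED6 or GFF3/GTF.

    BED6: each record is a single TSS; the TSS base is ``start`` for ``+``
    records and ``end - 1`` for ``-`` records (so 1-bp records work either
    way). GFF3/GTF: transcript-type features are reduced to their 5' end on
    the record's strand.
    """
    p = Path(path)
    if p.suffix.lower() in _GFF_SUFFIXES:
        return _read_tss_gff(p)
    out: list[TSSRecord] = []
    with open(p) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(
                    f"{p}:{ln}: TSS BED needs 6 columns (strand required)"
                )
            chrom, start, end, name, _, strand = f[:6]
            pos = int(start) if strand == "+" else int(end) - 1
            out.append(TSSRecord(chrom, pos, strand, name))
    return out


def _read_tss_gff(path: Path) -> list[TSSRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    out: list[TSSRecord] = []
    for ft in db.all_features(order_by=("seqid", "start")):
        if ft.featuretype not in _TRANSCRIPT_TYPES:
            continue
        # GFF is 1-based inclusive
        pos = ft.start - 1 if ft.strand == "+" else ft.end - 1
        gid = (
            ft.attributes.get("transcript_id", [None])[0]
            or ft.attributes.get("ID", [None])[0]
            or ft.id
        )
        out.append(TSSRecord(ft.seqid, pos, ft.strand, gid))
    return out


def open_genome(path: str | Path) -> pyfaidx.Fasta:
    """Open an (indexed) FASTA; the .fai index is created if missing."""
    return pyfaidx.Fasta(str(path))


def genome_sizes(genome: pyfaidx.Fasta) -> dict[str, int]:
    return {name: len(rec) for name, rec in genome.items()}


def write_fasta(sequences: dict[str, str], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
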