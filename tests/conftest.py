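"""Shared fixtures: brute-force scanner oracle and small on-disk datasets."""

from __future__ import annotations

import numpy as np
import pytest

from fivegc.intervals import GenomicInterval
from fivegc.motifs import IUPAC_CODES, MotifSet, reverse_complement


def brute_force_scan(
    seq: str, motif_set: MotifSet, strands: str = "both"
) -> list[tuple[int, int, str, str]]:
    """Independent oracle: test every offset, strand and pattern separately.

    Returns (start, end, strand, pattern_name) tuples sorted the same way
    the native scanner sorts its hits.
    """
    s = seq.upper()
    out = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def matches(sub: str, pat: str) -> bool:
        return len(sub) == len(pat) and all(
            b in IUPAC_CODES[p] for b, p in zip(sub, pat)
        )

    for pat in motif_set.patterns:
        k = pat.length
        for i in range(len(s) - k + 1):
            sub = s[i : i + k]
            if strands in ("+", "both") and matches(sub, pat.iupac):
                prev = s[i - 1] if i > 0 else None
                if motif_set.excluded_5prime and prev in motif_set.excluded_5prime:
                    pass
                else:
                    out.append((i, i + k, "+", pat.name))
            if strands in ("-", "both") and matches(
                reverse_complement(sub), pat.iupac
            ):
                # 5' neighbour on the minus strand = complement of base at i+k
                nxt = comp[s[i + k]] if i + k < len(s) else None
                if motif_set.excluded_5prime and nxt in motif_set.excluded_5prime:
                    pass
                else:
                    out.append((i, i + k, "-", pat.name))
    return sorted(out)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome() -> dict[str, str]:
    """A tiny fixed two-chromosome genome used for I/O round trips."""
    rs = np.random.default_rng(7)
    return {
        "chrA": random_dna(rs, 5000),
        "chrB": random_dna(rs, 3000),
    }


@pytest.fixture
def toy_genome_fasta(toy_genome, tmp_path):
    from fivegc.io import write_fasta

    path = tmp_path / "toy.fa"
    write_fasta(toy_genome, path)
    return path


def region(chrom: str, start: int, end: int, **kw) -> GenomicInterval:
    return GenomicInterval(chrom, start, end, **kw)
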