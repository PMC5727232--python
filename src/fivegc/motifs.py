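"""Motif panels and exact, strand-aware IUPAC scanning.

The Smad MH1 domain recognises short exact elements rather than degenerate
position-weight matrices: the classical CAGAC/GTCT Smad binding element
(SBE) and a family of 5-bp GC-rich elements (5GC SBEs) summarised by the
consensus GGC(GC)|(CG) and operationally scanned as the panel
{GGCGC, GGCGG, GGCCG, GGCTG}. Because the protein contacts bases on both
DNA strands, scanning is double-stranded by default: a hit on the minus
strand is reported on forward coordinates with its footprint interval and
the forward-strand sequence it covers.

The scanner reports *every* occurrence: overlapping matches are all
returned, matching the behaviour of a classical pattern scanner.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path

import yaml

from .intervals import GenomicInterval

# IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain nucleotide sequence.

    Case-insensitive input; uppercase output. Applying the function twice
    returns the (uppercased) input.

    Raises
    ------
    ValueError
        If ``seq`` contains a character outside ``{A, C, G, T, N}``.
    """
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"non-nucleotide character(s) in sequence: {bad}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (R<->Y, K<->M, B<->V, D<->H)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A fixed-length exact/IUPAC DNA pattern."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty motif pattern")
        bad = [c for c in self.iupac.upper() if c not in IUPAC_CODES]
        if bad:
            raise ValueError(
                f"pattern {self.name!r}: invalid IUPAC code(s) {bad}"
            )
        object.__setattr__(self, "iupac", self.iupac.upper())

    @property
    def length(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class MotifSet:
    """A named panel of patterns, optionally with a 5'-context rule.

    ``excluded_5prime`` lists bases that must NOT appear immediately 5' of a
    match *on the match's strand*; a sequence edge (no preceding base)
    satisfies the rule. This implements DAGAC — AGAC occurrences not part of
    a CAGAC — as one AGAC scan plus a context filter rather than three
    separate 5-mers.
    """

    name: str
    patterns: tuple[MotifPattern, ...]
    excluded_5prime: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"motif set {self.name!r} has no patterns")

    @property
    def pattern_names(self) -> list[str]:
        return [p.name for p in self.patterns]

    @property
    def uniform_length(self) -> int | None:
        lengths = {p.length for p in self.patterns}
        return lengths.pop() if len(lengths) == 1 else None


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on forward coordinates.

    ``interval`` is the footprint (0-based half-open) on the forward
    coordinate system; ``matched_forward_seq`` is the forward-strand
    substring of that footprint. For a minus-strand hit the reverse
    complement of ``matched_forward_seq`` matches the pattern.
    """

    interval: GenomicInterval
    strand: str
    pattern_name: str
    matched_forward_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"hit strand must be + or -, got {self.strand!r}")
        if len(self.interval) != len(self.matched_forward_seq):
            raise ValueError("hit footprint length != matched sequence length")


def expand_consensus(notation: str) -> set[MotifPattern]:
    """Expand a consensus string into its concrete patterns.

    The notation is literal bases (IUPAC codes allowed, expanded) plus
    alternation groups; both ``GGC(GC|CG)`` and the equivalent published
    style ``GGC(GC)|(CG)`` are accepted.

    Examples
    --------
    >>> sorted(p.iupac for p in expand_consensus("GGC(GC|CG)"))
    ['GGCCG', 'GGCGC']
    >>> sorted(p.iupac for p in expand_consensus("DAGAC"))
    ['AAGAC', 'GAGAC', 'TAGAC']
    """
    text = notation.replace(")|(", "|").upper()
    # tokenize into per-position alternatives
    choices: list[list[str]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "(":
            j = text.find(")", i)
            if j < 0:
                raise ValueError(f"unclosed alternation in {notation!r}")
            branches = text[i + 1 : j].split("|")
            if not all(branches) or len(branches) < 1:
                raise ValueError(f"malformed alternation in {notation!r}")
            for b in branches:
                if any(ch not in IUPAC_CODES for ch in b):
                    raise ValueError(
                        f"invalid character in alternation branch {b!r}"
                    )
            choices.append(branches)
            i = j + 1
        elif c in IUPAC_CODES:
            choices.append(list(IUPAC_CODES[c]))
            i += 1
        else:
            raise ValueError(f"invalid character {c!r} in consensus {notation!r}")
    if not choices:
        raise ValueError("empty consensus notation")
    return {
        MotifPattern(name="".join(parts), iupac="".join(parts))
        for parts in itertools.product(*choices)
    }


# --- built-in panels -------------------------------------------------------

def builtin_panels() -> dict[str, MotifSet]:
    """The default motif panels.

    FIVE_GC pools the four 5-bp GC-rich Smad binding elements
    {GGCGC, GGCGG, GGCCG, GGCTG}; CAGAC and GTCT are the two reads of the
    classical SBE; AGAC is its 4-bp core; DAGAC restricts AGAC to
    occurrences whose 5' neighbour is not C (i.e. AGAC sites that are not
    CAGAC); CONSENSUS_5GC is the two-member expansion of the structural
    consensus GGC(GC)|(CG).
    """
    mk = lambda *seqs: tuple(MotifPattern(s, s) for s in seqs)  # noqa: E731
    return {
        "FIVE_GC": MotifSet("FIVE_GC", mk("GGCGC", "GGCGG", "GGCCG", "GGCTG")),
        "CAGAC": MotifSet("CAGAC", mk("CAGAC")),
        "AGAC": MotifSet("AGAC", mk("AGAC")),
        "DAGAC": MotifSet("DAGAC", mk("AGAC"), excluded_5prime=frozenset("C")),
        "GTCT": MotifSet("GTCT", mk("GTCT")),
        "CONSENSUS_5GC": MotifSet(
            "CONSENSUS_5GC",
            tuple(sorted(expand_consensus("GGC(GC|CG)"), key=lambda p: p.iupac)),
        ),
    }


def load_panels(path: str | Path) -> dict[str, MotifSet]:
    """Load motif panels from a YAML file.

    Format::

        FIVE_GC:
          patterns: [GGCGC, GGCGG, GGCCG, GGCTG]
        DAGAC:
          patterns: [AGAC]
          excluded_5prime: [C]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"panel config {path}: expected a mapping")
    panels: dict[str, MotifSet] = {}
    for name, entry in raw.items():
        pats = entry.get("patterns")
        if not pats:
            raise ValueError(f"panel {name!r}: no patterns")
        excl = entry.get("excluded_5prime")
        panels[name] = MotifSet(
            name=name,
            patterns=tuple(MotifPattern(p, p) for p in pats),
            excluded_5prime=frozenset(excl) if excl else None,
        )
    return panels


# --- scanning --------------------------------------------------------------

def _pattern_regex(iupac: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all found
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
        for c in iupac
    )
    return re.compile(f"(?=({body}))")


def scan_sequence(
    seq: str,
    motif_set: MotifSet,
    strands: str = "both",
    mask: str = "include",
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Find every occurrence of every panel pattern in ``seq``.

    Parameters
    ----------
    seq
        DNA over ``{A, C, G, T, N}``, case-insensitive. ``N`` never matches
        a literal pattern base.
    motif_set
        The panel to scan with.
    strands
        ``"+"`` (forward only), ``"-"`` (reverse only) or ``"both"``.
    mask
        ``"include"`` (default) treats soft-masked lowercase sequence as
        ordinary bases; ``"exclude"`` makes lowercase bases unmatchable.
    chrom, offset
        When scanning a genomic slice, set these so hit footprints are in
        genome coordinates.

    Returns
    -------
    list of MotifHit sorted by footprint start, then strand (+ before -),
    then pattern name.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"invalid strand selector {strands!r}")
    if mask not in ("include", "exclude"):
        raise ValueError(f"invalid mask policy {mask!r}")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"non-nucleotide character(s) in sequence: {bad}")

    if mask == "exclude":
        search = "".join(c if c.isupper() else "!" for c in seq)
    else:
        search = seq.upper()
    upper = seq.upper()

    excl = motif_set.excluded_5prime
    # Forward-strand disallowed preceding base(s) are excl themselves;
    # for a minus-strand hit the base 5' of the match sits at forward
    # position `end` and is the complement of the match-strand base.
    excl_after = (
        {b.translate(_COMPLEMENT) for b in excl} if excl is not None else None
    )

    hits: list[MotifHit] = []
    L = len(seq)
    for pat in motif_set.patterns:
        if strands in ("+", "both"):
            rx = _pattern_regex(pat.iupac)
            for m in rx.finditer(search):
                s = m.start()
                if excl is not None and s > 0 and search[s - 1] in excl:
                    continue
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(
                            chrom, offset + s, offset + s + pat.length, "+"
                        ),
                        strand="+",
                        pattern_name=pat.name,
                        matched_forward_seq=upper[s : s + pat.length],
                    )
                )
        if strands in ("-", "both"):
            rx = _pattern_regex(_revcomp_iupac(pat.iupac))
            for m in rx.finditer(search):
                s = m.start()
                e = s + pat.length
                if excl_after is not None and e < L and search[e] in excl_after:
                    continue
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(chrom, offset + s, offset + e, "-"),
                        strand="-",
                        pattern_name=pat.name,
                        matched_forward_seq=upper[s:e],
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.strand, h.pattern_name))
    return hits


def count_hits_in_region(hits: list[MotifHit], region: GenomicInterval) -> int:
    """Number of hits whose footprint lies entirely within ``region``.

    A hit straddling the region edge is not counted. Chromosomes are
    compared only when both the hit and the region carry one.
    """
    n = 0
    for h in hits:
        iv = h.interval
        if iv.chrom and region.chrom and iv.chrom != region.chrom:
            continue
        if region.start <= iv.start and iv.end <= region.end:
            n += 1
    return n
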