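"""Scan three short promoter sequences for Smad binding elements.

The sequences are classics of the Smad-DNA literature: the 10-bp GC-rich
goosecoid promoter segment whose deletion abolishes the nodal response,
the palindromic GTCTAGAC duplex used to discover the CAGAC box, and the
palindromic GC-rich BRE GGCGCC. Because the MH1 domain contacts bases on
both strands, the scanner reports minus-strand occurrences on forward
coordinates.
"""

from fivegc import builtin_panels, scan_sequence

panels = builtin_panels()

for label, seq, panel in [
    ("Gsc GC-rich deletion segment", "GCGCCGGGGC", "FIVE_GC"),
    ("palindromic SBE duplex", "GTCTAGAC", "CAGAC"),
    ("palindromic SBE duplex", "GTCTAGAC", "AGAC"),
    ("palindromic GC BRE", "GGCGCC", "FIVE_GC"),
]:
    hits = scan_sequence(seq, panels[panel], strands="both")
    print(f"{label} ({seq}), panel {panel}: {len(hits)} hit(s)")
    for h in hits:
        print(
            f"  {h.pattern_name} on {h.strand} strand, footprint "
            f"[{h.interval.start},{h.interval.end}), forward bases "
            f"{h.matched_forward_seq}"
        )

print(
    "\nThe GC segment carries exactly one 5GC element (GGCGC, read on the"
    "\nminus strand); GTCTAGAC contains no CAGAC but two AGAC cores (one"
    "\nper strand); the 6-bp BRE presents GGCGC twice, once per strand,"
    "\nwhich is how a palindrome offers a site to two MH1 domains."
)
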