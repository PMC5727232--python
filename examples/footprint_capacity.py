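"""How many MH1 domains can bind a motif cluster at once?

One Smad MH1 domain covers about six base pairs of duplex DNA (five bases
contacted directly plus backbone hydrogen bonds one base 3' of the
motif). When 5GC elements overlap, not every occurrence can be occupied
simultaneously: the footprint capacity is the maximum number of mutually
non-overlapping 6-bp footprints anchored at motif starts.
"""

from fivegc import builtin_panels, scan_sequence, site_capacity

panel = builtin_panels()["FIVE_GC"]

# a synthetic GC-rich promoter-like segment with overlapping elements
segment = "TTGGCGGCGCAAGGCCGCCGGCTGTT"

hits = scan_sequence(segment, panel, strands="both")
print(f"segment: {segment}")
print(f"{len(hits)} 5GC motif occurrence(s):")
for h in hits:
    print(
        f"  {h.pattern_name} [{h.interval.start},{h.interval.end}) "
        f"strand {h.strand}"
    )

cap = site_capacity(hits, footprint=6)
print(f"\nfootprint capacity (6-bp footprints): {cap}")
print(
    "\nAlthough the scanner reports every occurrence, overlapping motifs"
    "\nshare base pairs, so only "
    f"{cap} MH1 domain(s) can be bound at once - the geometric basis for"
    "\ncounting usable sites in a cluster rather than raw motif matches."
)
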