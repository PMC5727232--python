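# Methods

## Motif model

Smad binding elements are modelled as short exact/IUPAC patterns, not
position-weight matrices: the biochemistry motivating the analysis is a
discrete set of 5-bp elements with high-affinity binding, so a pattern
either matches or it does not. Built-in panels:

| panel | patterns | note |
|---|---|---|
| FIVE_GC | GGCGC, GGCGG, GGCCG, GGCTG | pooled 5GC SBE panel |
| CAGAC | CAGAC | classical SBE |
| GTCT | GTCT | reverse-strand read of the SBE core |
| AGAC | AGAC | 4-bp SBE core |
| DAGAC | AGAC + 5′ base ≠ C | AGAC occurrences outside CAGAC |
| CONSENSUS_5GC | GGCGC, GGCCG | expansion of GGC(GC)\|(CG) |

Scanning is exact, case-insensitive and double-stranded by default:
minus-strand occurrences are reported on forward coordinates with the
forward-strand footprint sequence. Every occurrence is reported,
including overlaps — this matches classical pattern scanners and avoids
an arbitrary dedup rule. The DAGAC context rule is evaluated on the base
immediately 5′ of the match *on the match's strand* (for a minus-strand
hit, the complement of the forward base just 3′ of the footprint); a
sequence edge counts as satisfying "not C". A forward-only mode exists
because double-stranded counting roughly doubles absolute densities for
non-palindromic patterns and some published counts may be single-strand;
all comparisons in this package are internally consistent either way.
Soft-masked (lowercase) sequence matches by default; `mask="exclude"`
makes masked bases unmatchable.

## Regions

Coordinates are 0-based half-open throughout; 1-based conversions happen
only at I/O boundaries. Analysis regions are 200-bp windows centered on
the peak midpoint (narrowPeak summits are honoured only when explicitly
requested, since older peak sets report no summit). Windows that would
cross a chromosome edge are dropped, not clipped, so per-region counts
remain densities over equal width; exact duplicate windows are removed
keeping first-occurrence order. Promoter proximity keeps a region whose
*center* lies within the strand-aware interval `[tss − 1000, tss]` (plus
strand; mirrored for minus) of at least one TSS; a symmetric ±1000 mode
is provided for annotations where upstream orientation is unreliable.
An empty TSS list is an error rather than an empty result, so a missing
annotation cannot masquerade as "no promoters".

The baseline is `n` regions of the same width drawn uniformly over all
valid (chromosome, start) pairs — chromosomes weighted by valid-start
count, so no draw crosses a boundary. Draws with more than 10%
ambiguous bases are rejected and redrawn (assembly gaps would otherwise
deflate baseline motif rates); a bounded redraw budget turns a
pathologically gappy genome into a diagnostic failure instead of a hang.

## Statistics

Fold enrichment is the ratio of per-region mean counts; no variance-based
test is attached to the point estimate because the quantity of interest
is the magnitude, but a percentile bootstrap over regions
(`bootstrap_fold_ci`) is available as an optional extra. A zero baseline
mean raises an explicit error rather than returning infinity. Cluster
distributions report the fractions of regions with exactly 0, 1, 2 and
≥ threshold (default 3) panel motifs; the pooled FIVE_GC count is the sum
of its per-pattern counts, which are also reported for transparency.

Footprint capacity models each bound MH1 domain as occupying 6 bp
anchored at the motif start — the structural contact area extends about
one base 3′ of the 5-bp motif through backbone hydrogen bonds. The
maximum simultaneous occupancy of a hit list is unit-weight interval
scheduling, solved exactly by earliest-end greedy selection (verified
against exhaustive search in tests). The probe tiler emits 20-bp duplex
probes stepping 2 bp, offsets 0 … len − 20 inclusive.

## Synthetic data

The generator emulates the inputs the analysis consumes: an i.i.d.
background genome with configurable GC fraction g (P(G) = P(C) = g/2),
non-overlapping bound regions with planted panel motifs, peak records
jittered around region centers, and a TSS annotation. Defaults are meant
to look like the real analysis setting: g = 0.41 (human genome-wide GC),
500 bound regions of 200 bp, k = 3 planted motifs (the cluster regime of
interest), uniform pattern weights, 50% minus-strand plants, 20-bp peak
jitter, all bound regions promoter-proximal, plus decoy TSS records far
from any bound region so the annotation exists independently of binding.

Two deliberate deviations from naive simulation:

- **Clean insertion.** Writing a GC-rich 5-mer into random sequence
  creates, on average, ~0.22 additional partially-overlapping panel
  matches per plant (fixed GC bases elevate the match probability of
  overlapping GC-rich patterns) and occludes ~0.21 expected background
  hits per region. Either effect makes the "true" motif count of a
  planted region ambiguous. Planting therefore redraws an offset
  whenever the write would destroy an existing panel hit or create an
  extra one at the junction, so a bound region's panel count is exactly
  its background count plus k, and the expected bound mean is
  `expected_background_count(...) + k`.
- **Region spacing.** Bound regions keep ≥ 2000 bp edge-to-edge so that
  a TSS placed ≤ 1000 bp from one region's center can never make a
  different region promoter-proximal; `promoter_fraction` is then exact
  by construction.

Because the background is i.i.d., the expected panel count per baseline
region has the closed form `Σ_patterns Σ_strands (W − k + 1) · Π P(base)`
— exact for the expectation by linearity, though the count distribution
itself is slightly overdispersed relative to Poisson (overlapping
occurrences on two strands clump): the ≥3 tail at g = 0.5, W = 200 is
≈ 0.201 empirically against a Poisson-tail approximation of 0.199.

What the generator does *not* emulate: dinucleotide composition, CpG
islands, repeats, assembly gaps, read-level noise, or peak-calling
artefacts. Passing tests on synthetic data therefore demonstrate the
correctness of the computation — scanning, windowing, filtering,
sampling and the statistics — not that any particular biological dataset
will show enrichment. Real-genome analyses are additionally sensitive to
the TSS annotation version, which changes absolute promoter-region
counts.

For recovery statistics the baseline is sampled from a background-only
genome generated under the same parameters: at desk scale the bound
regions occupy a non-negligible fraction of the synthetic genome
(thousands of 200-bp regions in a few megabases), which would
contaminate a same-genome baseline, whereas random coordinates in a real
genome hit bound regions with negligible probability. Background genomes
are sized ~10–20× the total bases sampled from them so overlap between
baseline draws stays small and naive Monte-Carlo standard errors remain
honest. Problem sizes used by the test suite and acceptance script —
5000 baseline regions for the background oracle, 2000 vs 2000 regions
for parameter recovery, 1000 random sequences for the scanner oracle —
give Monte-Carlo standard errors a few percent of the quantities under
test while keeping a full run in seconds.

## Numerical and degenerate-input choices

- Window centers use `floor((start + end)/2)`; widths must be even.
- Determinism: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); identical inputs give byte-identical
  FASTA, BED and JSON outputs.
- `sample_baseline`, planting and decoy placement use bounded rejection
  sampling with diagnostic failures.
- Empty sequence, empty hit list, zero bound regions, and k = 0 planting
  are all valid inputs with well-defined (empty or background-only)
  outputs; ragged
  region widths, unknown panels, invalid strand selectors, non-ACGTN
  sequence and an empty TSS annotation are rejected loudly.
- The capacity greedy breaks ties by interval end, which is optimal for
  unit weights regardless of tie order.

## Known limitations

- Enrichment is a ratio of means; heavily skewed count distributions at
  very small region counts (tens of regions) deserve the bootstrap CI.
- The promoter filter tests region centers, not overlap, so a region
  straddling the 1000-bp boundary is classified by its midpoint.
- GFF/GTF TSS extraction uses transcript-type features only
  (`transcript`/`mRNA`); gene-only annotations must be converted first.
- Deduplication removes exact duplicate windows; near-duplicate windows
  from adjacent peaks are retained as distinct regions.
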