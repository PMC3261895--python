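# Methods

## Definitions

For a genome of length *n* over {A,C,G,T,N} and parameters *k* (read
length) and *m* (maximum substitutions), the **k-frequency** F[i] of
position *i* is the number of occurrences of the k-mer starting at *i*
in the sequence **and in its reverse complement**, counting as
equivalent every k-mer within Hamming distance *m* (substitutions only;
no indels). The **k-mappability** is M[i] = 1/F[i] ∈ (0,1]; a position
is *uniquely mappable* when F[i] = 1. Positions hosting no valid k-mer
(an N inside the window, or fewer than *k* bases left in the contig)
carry F = 0 and M = 0 and are excluded from every downstream statistic.

Occurrences are counted with strand multiplicity: a window equal to its
own reverse complement contributes two occurrences but one match
*position*. The propagation set P of the approximation below is the set
of distinct forward-strand start positions. Toy examples on
non-DNA alphabets run in a `forward_only` mode in which
characters are compared literally (there, `N` is an ordinary letter);
in DNA mode an N never matches anything, so assembly gaps cannot create
spurious uniqueness or multiplicity.

## The threshold approximation

Exact computation needs one counting query per position. The
approximation visits positions in ascending order and, whenever a query
at *i* returns a match set P with |P| ≥ t, writes the occurrence count
to every member of P (write-once-or-max: positions already holding a
value keep the maximum, so the scheme can only overestimate a
propagated position, never underestimate it below a previously seen
class size); members of P are then skipped by the traversal. Guarantees
(all enforced by tests against an independent brute-force oracle):

* exact everywhere when m = 0 or when t is disabled;
* exact at every unique position for any t (a unique k-mer cannot lie
  in another k-mer's match set);
* any reported value < t was computed directly and is exact.

`t < 2` is rejected: t = 1 would propagate over singleton classes and
destroy the unique-position guarantee. The default t is
`max(8, ceil(log2 n))` (≈27 for 100 Mb, ≈32 for 3 Gb): it grows slowly
with genome size so that small frequency classes stay exact while large
repeat families — where the per-query cost concentrates — are
collapsed. The formula is this package's own choice, exposed as a flag.

## Match engine

`count_matches` is a direct sliding-window scan and defines the
contract. `SearchIndex` is a pigeonhole seed index: a query within *m*
substitutions of a window must match one of its m+1 disjoint
length-⌊k/(m+1)⌋ seed chunks exactly, so exact seed lookups (sorted
rolling-hash tables, built lazily per seed length; hash collisions only
enlarge the candidate set, which full Hamming verification prunes)
yield candidates verified vectorially. Contigs are concatenated with a
separator symbol that poisons any window spanning a boundary, so k-mers
never cross contigs. The two routes are bit-identical; the test suite
enforces this on ≥1000 randomized instances.

## Derived scores

**Pileup mappability** of position *p* at read length *l* (track k = l)
is the mean of M over the valid window starts in [p−l+1, p] within the
same contig; starts with F = 0 are excluded from the mean, and 0 is
returned when none is valid.

**Paired-end mappability** uses mates at start-to-start distance *d*
with zero fragment-size variance. With *u* the target's pileup
mappability and v± those of the two mates, the three cases are:
u ≥ all available mates → u; u < exactly one → (u + that mate)/2;
u < both → (v− + v+)/2. Ties (u equal to a mate) count the mate as
"not better". A mate off the contig or on an undefined position is
unavailable; with no mates available the single-end value is returned.
Rescue by insert-size disambiguation among non-unique pairs is not
modelled.

**Rescue fraction**: among positions with F > 1, the fraction whose
both mates (p±d, same contig) have F = 1. It is NaN on a fully unique
genome (empty denominator) and non-decreasing in *d* on fixtures whose
repeats are shorter than the largest insert, because a repeat shorter
than *d* with unique flanks always places both mates in unique
sequence.

**Proper length**: the smallest ℓ with s^ℓ ≥ n — the word length at
which a random n-length sequence over an s-letter alphabet is expected
to contain a given word about once. Note that at k = proper length a
random genome is *not* nearly all unique: each k-mer is still expected
about once more by chance (both strands ≈ 2n/4^k ≈ 1 extra
occurrence). The fixture test for "background is unique" therefore uses
k = proper length + 5, where the chance collision rate is ~10⁻³.

## Track format and codec

Tracks are written as pseudo-multi-FASTA: `~`-prefixed metadata lines
(k, m, t, codec constants, contig table), then one `>name` record per
contig with one printable character per position, 60 per line. The
codec uses the 94 printable characters `!`..`~`: code 0 = undefined,
codes 1–60 store F exactly, codes 61–93 partition (60, 2³²] into
geometric ranges (growth g fixed by the range count; the last code is
an overflow catch-all). A range code decodes to the geometric midpoint
of its range, minimizing multiplicative error — immaterial for
mappability, since 1/F of a large F is insensitive to it. All constants
are written into the preamble, so files are self-describing; no attempt
is made to read the binary formats of other mappability tools. A
faidx-style JSON sidecar (per-contig byte offset + fixed line width)
supports O(1) region retrieval; memory, full-file and indexed access
are tested to agree bit-exactly at the code level. BedGraph export
merges equal-value runs and emits undefined positions as 0, so interval
lengths always sum to the genome length.

## Projected transcriptome and RPKUM

A gene is the union of its transcripts' exons projected onto the genome
(each exon fragment counted once; overlapping genes are *not* merged
and shared positions count for each gene). The unique exonic length U
is the number of exon-union positions with F = 1. With c unique reads
for the gene, N total mapped reads, L the exonic length:

    RPKM = 10⁹·c/(L·N)     RPKUM = 10⁹·c/(U·N)   (NaN when U = 0)

so RPKUM/RPKM = L/U whenever both are defined. Exonic positions are
genomic k-mer starts; a window near a 3′ exon boundary may run into the
intron (splice-junction k-mers in transcript space are out of scope).
Strand is recorded but ignored, as mappability is strand-symmetric.
Read counts are inputs (TSV), or derived from a BED of read start
positions; alignment itself is outside the package.

## Synthetic fixtures

`generate_genome` plants repeat families in i.i.d. uniform ACGT
background, with optional N-gap runs and optional reverse-complement
copies. Divergence is modelled as family-wide variable sites: each
family draws `max_divergence` site positions once, and every copy draws
its own letters there. Pairwise Hamming distance between copies is
therefore ≤ max_divergence (not twice it), which makes "frequency ≥
copy number at every copy start, for m ≥ max_divergence" a structural
guarantee rather than a tendency — this is what the parameter-recovery
tests assert via the independent oracle. The generator does not emulate
indels, nested/fragmented repeats, GC bias or realistic repeat
evolution; passing tests demonstrate correctness of the computation,
not performance claims about real genomes.

All randomness flows from one integer seed through named substreams
(background, placement, family content, gaps, genes), so outputs are
byte-stable when unrelated features are added.

## Test oracles and problem sizes

The independent oracle for whole-track exactness is an all-pairs
shift-comparison counter (cross-correlation of the concatenated genome
with itself and with its reverse complement, one vectorized pass per
relative shift, O(n²) overall), itself validated against a pure-python
per-query counter on tiny genomes. The exactness suite runs 100 random
repeat genomes spanning 1–50 kb, weighted towards the small end (90 ×
1–3 kb, 6 × 4–8 kb, 2 × 10–15 kb, plus one 20 kb and one 50 kb genome)
so that the quadratic oracle stays tractable while the large-genome
regime is still exercised; these sizes are the package's chosen test
conditions. Whole-mammalian-genome runs are methodologically identical
but are not executed here.

## Numerical and edge-case conventions

* Coordinates are 0-based half-open everywhere internally; GTF input is
  converted on read, BedGraph output is natively 0-based.
* Lowercase (soft-masked) bases are folded to uppercase — mappability
  is computed on the full sequence including repeats; non-ACGT IUPAC
  codes collapse to N (conservative: N never matches).
* The traversal order of the approximation is ascending global
  position, which makes the output a pure function of (ref, k, m, t);
  there is no parallel mode.
* Paired-end comparisons use exact float equality on decoded values;
  case assignment uses strict "smaller than".
* `hamming()` counts a position with N in either string as a mismatch;
  the DNA-mode match engine is stricter (a window containing N never
  matches at any m).

## Known limitations

Edit distance (indels), quality-aware matching, bigWig output,
byte-compatibility with other tools' track files, splice-junction
mappability, and isoform-level statistical quantification are out of
scope. The rescue model ignores nonzero insert-size variance and may
therefore overestimate rescue around long tandem arrays.
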