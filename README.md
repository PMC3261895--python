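# mappability

Fast genome mappability: per-position k-mer frequency and its inverse,
with mismatches, plus the downstream quantities that depend on it.

High-throughput sequencing reads can only be placed confidently where
the genome is locally unique. This package computes, for every position
*i* of a reference, the **k-frequency** F[i] — the number of
occurrences of the k-mer starting at *i* in the sequence and its
reverse complement, counting as equivalent all k-mers within *m*
substitutions — and the **k-mappability** M[i] = 1/F[i] ∈ (0,1]
(M = 1 ⇔ uniquely mappable; M = 0 marks positions with no valid k-mer).
It is intended for people analysing ChIP-seq/RNA-seq/DNA-seq data who
need to know, ahead of mapping, which regions of a genome are
accessible at a given read length and mismatch tolerance.

Exact computation needs one exhaustive counting query per position,
which is slow precisely where genomes are repetitive. The core
algorithm therefore propagates: when the k-mer at position *i* matches
a set P of positions with |P| ≥ t (an approximation threshold), all
members of P receive its occurrence count (keeping the maximum if
written twice) and are skipped thereafter. The approximation is exact
when m = 0, exact when t is disabled, exact at every uniquely mappable
position, and exact at every position whose reported value is below t.

On top of the tracks the package provides:

* **pileup mappability** — mean mappability of the l read-length
  windows covering a position (what a pileup column can see);
* **paired-end mappability** — a three-case mate-rescue rule at
  insert size d, and the **rescue fraction** of non-unique positions
  whose both mates are unique;
* **RPKM / RPKUM** — expression over the projected transcriptome, where
  RPKUM = 10⁹·c/(U·N) normalises by the *uniquely mappable* exonic
  length U instead of the full exonic length L, removing the bias that
  discarding multi-mapping reads inflicts on repetitive genes;
* a compact, self-describing **track format** (printable ASCII codes,
  one character per position: exact codes 1–60, geometric bins above)
  with an indexed retriever and BedGraph export;
* a **synthetic-genome generator** with planted repeat families of
  known copy number and divergence, used as ground truth throughout the
  test suite.

See `docs/methods.md` for the precise definitions, conventions and
limitations.

## Worked example

```python
import mappability as mp

# a 6 kb genome with one planted 5-copy repeat family (unit 40 bp,
# up to 1 substitution per copy)
ref, truth = mp.generate_genome(6000, [mp.RepeatSpec(40, 5, 1)], seed=7)

track = mp.compute_frequency_track(ref, k=36, m=1, t=8)
M = mp.frequency_to_mappability(track)

starts = truth.start.to_numpy()
print(list(track.values[starts]))        # [5, 5, 5, 5, 5]
print(float((track.values == 1).mean())) # 0.9868
print(mp.rescue_fraction(track, mp.LibrarySpec(36, 500)))  # 1.0
```

Every planted copy start reports frequency 5 (the five copies are
mutually within one substitution), i.e. mappability 0.2, while 98.7% of
positions are uniquely mappable (the background, plus repeat-flank
windows). Because the 40 bp repeat is much shorter than the 500 bp
insert size, every non-unique position has both paired-end mates in
unique flanking sequence: the rescue fraction is 1.0 — short repeats
are effectively unique to a paired-end experiment whose library size
exceeds them.

The same pipeline is available from the shell:

```sh
mappability synth --length 6000 --repeat 40,5,1 --seed 7 --out-dir fx
mappability mappability --fasta fx/genome.fa --k 36 --m 1 --t 8 --out g.map
mappability retrieve --track g.map --region chr1:0-100
mappability export-bedgraph --track g.map --out g.bedgraph
```

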