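"""Synthetic genomes and annotations with known ground truth.

Fixtures emulate the one property of real genomes that drives
mappability: interspersed repeat families of controlled copy number,
unit length and divergence, embedded in random (i.i.d. uniform ACGT)
background — a caricature of LTR/non-LTR retrotransposon families,
which dominate the non-unique fraction of real genomes.

Divergence model: each family draws one random master unit and
``max_divergence`` family-wide *variable sites*; every copy then draws
its own letters at those sites (a consensus with polymorphic columns).
Consequently the Hamming distance between any two copies is at most
``max_divergence`` — so with m >= max_divergence every copy start is
guaranteed a frequency of at least the copy number, which is what makes
planted copy numbers recoverable ground truth rather than a tendency.

All randomness flows from one integer seed through named substreams
(background / placement / family content / gaps), so fixtures are
byte-stable under feature addition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import ReferenceSequence, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# substream tags (second word of the rng seed)
_BACKGROUND, _PLACEMENT, _FAMILY, _GAPS, _GENES = range(5)


@dataclass
class RepeatSpec:
    """One planted repeat family."""

    unit_length: int
    copy_number: int
    max_divergence: int = 0
    reverse_complement_copies: bool = False  # plant some copies on the - strand

    def __post_init__(self) -> None:
        if self.copy_number < 2:
            raise ValueError("a repeat family needs >= 2 copies")
        if self.unit_length <= self.max_divergence:
            raise ValueError("unit_length must exceed max_divergence")


@dataclass
class GapSpec:
    """Runs of N emulating assembly gaps."""

    n_gaps: int
    gap_length: int


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _place_intervals(
    rng: np.random.Generator,
    contig_lengths: list[int],
    sizes: list[int],
    max_tries: int = 2000,
) -> list[tuple[int, int]]:
    """Uniformly place non-overlapping intervals; (contig_idx, start) each.

    Rejection sampling over (contig, start) proportional to contig
    length; raises when the packing is infeasible within the attempt
    budget."""
    if sum(sizes) >= sum(contig_lengths):
        raise ValueError("planted span does not fit in the genome")
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(contig_lengths))}
    placements = []
    weights = np.asarray(contig_lengths, dtype=np.float64)
    weights /= weights.sum()
    for size in sizes:
        for attempt in range(max_tries):
            c = int(rng.choice(len(contig_lengths), p=weights))
            if contig_lengths[c] < size:
                continue
            start = int(rng.integers(0, contig_lengths[c] - size + 1))
            if all(start + size <= a or start >= b for a, b in occupied[c]):
                occupied[c].append((start, start + size))
                placements.append((c, start))
                break
        else:
            raise ValueError(
                f"could not place an interval of {size} bp after {max_tries} tries"
            )
    return placements


def generate_genome(
    length: int | list[int],
    repeat_specs: list[RepeatSpec] = (),
    gap_spec: GapSpec | None = None,
    seed: int = 0,
) -> tuple[ReferenceSequence, pd.DataFrame]:
    """Random genome with planted repeat families and optional N gaps.

    ``length`` is one contig length or a list of them (contigs are named
    chr1, chr2, ...).  Returns the reference and a truth table with one
    row per planted copy: family, copy, contig, start, end (half-open),
    strand, divergence (realised substitutions vs the family master).
    Byte-identical output for identical arguments and seed.
    """
    lengths = [int(length)] if np.isscalar(length) else [int(x) for x in length]
    names = [f"chr{i + 1}" for i in range(len(lengths))]
    bg = _rng(seed, _BACKGROUND)
    arrays = [
        _BASES[bg.integers(0, 4, size=L).astype(np.uint8)].copy() for L in lengths
    ]

    # one placement pass covers gaps and every repeat copy
    sizes: list[int] = []
    if gap_spec is not None:
        sizes.extend([gap_spec.gap_length] * gap_spec.n_gaps)
    for spec in repeat_specs:
        sizes.extend([spec.unit_length] * spec.copy_number)
    placements = _place_intervals(_rng(seed, _PLACEMENT), lengths, sizes)

    cursor = 0
    if gap_spec is not None:
        for _ in range(gap_spec.n_gaps):
            c, start = placements[cursor]
            cursor += 1
            arrays[c][start : start + gap_spec.gap_length] = ord("N")

    fam_rng = _rng(seed, _FAMILY)
    truth_rows = []
    for fam_idx, spec in enumerate(repeat_specs):
        master = _BASES[fam_rng.integers(0, 4, size=spec.unit_length)].copy()
        var_sites = (
            fam_rng.choice(spec.unit_length, size=spec.max_divergence, replace=False)
            if spec.max_divergence
            else np.empty(0, dtype=np.int64)
        )
        for copy_idx in range(spec.copy_number):
            unit = master.copy()
            if len(var_sites):
                unit[var_sites] = _BASES[fam_rng.integers(0, 4, size=len(var_sites))]
            divergence = int((unit != master).sum())
            strand = "+"
            if spec.reverse_complement_copies and copy_idx > 0:
                if fam_rng.integers(0, 2) == 1:
                    strand = "-"
            planted = unit
            if strand == "-":
                planted = np.frombuffer(
                    reverse_complement(unit.tobytes().decode("ascii")).encode("ascii"),
                    dtype=np.uint8,
                )
            c, start = placements[cursor]
            cursor += 1
            arrays[c][start : start + spec.unit_length] = planted
            truth_rows.append(
                {
                    "family": fam_idx,
                    "copy": copy_idx,
                    "contig": names[c],
                    "start": start,
                    "end": start + spec.unit_length,
                    "strand": strand,
                    "divergence": divergence,
                }
            )

    contigs = [(name, arr.tobytes().decode("ascii")) for name, arr in zip(names, arrays)]
    truth = pd.DataFrame(
        truth_rows,
        columns=["family", "copy", "contig", "start", "end", "strand", "divergence"],
    )
    return ReferenceSequence(contigs), truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def generate_annotation(
    ref: ReferenceSequence,
    truth: pd.DataFrame,
    n_genes: int,
    classes: dict[str, str] | None = None,
    seed: int = 0,
    margin: int = 100,
) -> tuple[str, pd.DataFrame]:
    """GTF text plus per-gene ground truth over a generated genome.

    ``classes`` maps a class label to a recipe: ``"background"`` places
    all exons in repeat-free sequence (>= ``margin`` bp from any planted
    copy, so every exonic k-mer with k <= margin stays unique up to
    chance collisions), ``"repeat"`` centres one exon on a planted copy.
    Genes cycle through the classes; each gene gets 1–5 exons of
    100–300 bp separated by 50–200 bp introns, all non-overlapping.
    The truth table records gene_id, class, contig, exonic length L and
    the bp of exon union inside planted repeats.
    """
    if classes is None:
        classes = {"protein_coding": "background", "repeat_like": "repeat"}
    rng = _rng(seed, _GENES)
    labels = list(classes)
    # forbidden zones: planted repeats padded by margin, per contig
    forbidden: dict[str, list[tuple[int, int]]] = {n: [] for n in ref.names}
    repeat_ivs: dict[str, list[tuple[int, int]]] = {n: [] for n in ref.names}
    for row in truth.itertuples():
        forbidden[row.contig].append((max(0, row.start - margin), row.end + margin))
        repeat_ivs[row.contig].append((row.start, row.end))
    taken: dict[str, list[tuple[int, int]]] = {n: [] for n in ref.names}

    gtf_lines = []
    truth_rows = []
    for gi in range(n_genes):
        label = labels[gi % len(labels)]
        recipe = classes[label]
        gene_id = f"g{gi + 1:04d}"
        exons = _place_gene(ref, rng, recipe, truth, forbidden, taken)
        if exons is None:
            raise ValueError(f"could not place gene {gene_id}; genome too crowded")
        contig, ivs, strand = exons
        for a, b in ivs:
            gtf_lines.append(
                f"{contig}\tsynth\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1"; '
                f'gene_type "{label}";'
            )
        overlap = _overlap_bp(ivs, repeat_ivs[contig])
        truth_rows.append(
            {
                "gene_id": gene_id,
                "class": label,
                "contig": contig,
                "L": sum(b - a for a, b in ivs),
                "repeat_overlap": overlap,
                "exons": ",".join(f"{a}-{b}" for a, b in ivs),
            }
        )
    return "\n".join(gtf_lines) + "\n", pd.DataFrame(truth_rows)


def _overlap_bp(ivs, repeats) -> int:
    total = 0
    for a, b in ivs:
        for r0, r1 in repeats:
            total += max(0, min(b, r1) - max(a, r0))
    return total


def _place_gene(ref, rng, recipe, truth, forbidden, taken, max_tries: int = 500):
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    for _ in range(max_tries):
        # redraw the structure every attempt so a crowded genome can
        # still accept a smaller gene
        n_exons = int(rng.integers(1, 6))
        exon_lens = rng.integers(100, 301, size=n_exons)
        intron_lens = rng.integers(50, 201, size=max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        if recipe == "repeat" and len(truth):
            row = truth.iloc[int(rng.integers(0, len(truth)))]
            contig = row.contig
            # centre the first exon on the chosen repeat copy
            start = int((row.start + row.end) // 2 - exon_lens[0] // 2)
        else:
            ci = int(rng.integers(0, len(ref.contigs)))
            contig = ref.names[ci]
            L = ref.lengths[ci]
            if L <= span:
                continue
            start = int(rng.integers(0, L - span))
        ivs = []
        pos = start
        for i, el in enumerate(exon_lens):
            ivs.append((pos, pos + int(el)))
            if i < len(intron_lens):
                pos += int(el) + int(intron_lens[i])
        lo, hi = ivs[0][0], ivs[-1][1]
        ci = ref.contig_index(contig)
        if lo < 0 or hi > ref.lengths[ci]:
            continue
        if any(lo < b and hi > a for a, b in taken[contig]):
            continue
        if recipe == "background" and any(
            lo < b and hi > a for a, b in forbidden[contig]
        ):
            continue
        taken[contig].append((lo, hi))
        return contig, ivs, strand
    return None


def write_fixture(
    out_dir,
    ref: ReferenceSequence,
    truth: pd.DataFrame,
    gtf_text: str | None = None,
    gene_truth: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Emit FASTA (+ optional GTF) + truth TSVs into ``out_dir``."""
    import os

    from .genome_io import write_fasta

    os.makedirs(out_dir, exist_ok=True)
    paths = {"fasta": os.path.join(out_dir, "genome.fa")}
    write_fasta(ref, paths["fasta"])
    paths["repeat_truth"] = os.path.join(out_dir, "repeats.tsv")
    truth.to_csv(paths["repeat_truth"], sep="\t", index=False)
    if gtf_text is not None:
        paths["gtf"] = os.path.join(out_dir, "genes.gtf")
        with open(paths["gtf"], "w") as fh:
            fh.write(gtf_text)
    if gene_truth is not None:
        paths["gene_truth"] = os.path.join(out_dir, "genes.tsv")
        gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    return paths
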