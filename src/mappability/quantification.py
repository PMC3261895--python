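"""Projected-transcriptome quantification: exon unions, unique exonic
length, RPKM / RPKUM, and per-class mappability profiles.

The projected transcriptome treats each gene as the genomic union of all
its transcripts' exons, so every exon fragment is considered exactly
once.  Intersecting that union with a frequency track yields, per gene,
the exonic length L and the *unique* exonic length U — the number of
exonic positions whose k-mer occurs exactly once at the chosen (k, m).

When multi-mapping reads are discarded, only unique positions can
contribute reads, so normalising counts by L underestimates expression
of genes with repetitive sequence.  RPKUM replaces L by U:

    RPKM  = 1e9 * c / (L * N)        RPKUM = 1e9 * c / (U * N)

with c the gene's unique-read count and N the total mapped reads.
RPKUM is undefined (NaN) when U = 0.

Positions are genomic k-mer start positions: a k-mer starting near an
exon's 3' boundary may run into the intron; splice-junction k-mers in
transcript space are out of scope.  Strand is recorded but ignored —
mappability is strand-symmetric by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mappability_core import FrequencyTrack

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """One gene of the projected transcriptome.

    ``exon_union`` holds sorted, disjoint, 0-based half-open intervals on
    ``contig``; ``class_label`` is the biotype (protein_coding, lncRNA,
    rRNA, pseudogene, miRNA, snRNA, ...).
    """

    gene_id: str
    class_label: str
    contig: str
    strand: str
    exon_union: list[tuple[int, int]]

    def __post_init__(self) -> None:
        ivs = sorted(self.exon_union)
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if c < b:
                raise ValueError(f"gene {self.gene_id}: overlapping exon intervals")
        for a, b in ivs:
            if b <= a:
                raise ValueError(f"gene {self.gene_id}: empty interval [{a}, {b})")
        self.exon_union = ivs

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exon_union)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping half-open intervals."""
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


# ---------------------------------------------------------------------------
# annotation input
# ---------------------------------------------------------------------------


def project_exons(path, known_contigs: list[str] | None = None) -> list[GeneModel]:
    """Per-gene exon unions from a GTF/GFF3 (or BED12) annotation.

    Overlapping genes stay separate models — no cross-gene merging.
    Transcripts on unknown contigs are skipped with a warning; an
    annotation yielding no genes is an error.
    """
    path = str(path)
    if path.endswith(".bed") or path.endswith(".bed12"):
        genes = _project_bed12(path)
    else:
        genes = _project_gtf(path)
    if known_contigs is not None:
        kept = []
        for g in genes:
            if g.contig in known_contigs:
                kept.append(g)
            else:
                warnings.warn(
                    f"gene {g.gene_id}: unknown contig {g.contig!r}; skipped"
                )
        genes = kept
    if not genes:
        raise ValueError(f"{path}: no usable gene models")
    return genes


def _project_gtf(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    by_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes.get("gene_id", ["?"])[0]
        biotype = (
            exon.attributes.get("gene_type", None)
            or exon.attributes.get("gene_biotype", None)
            or ["unknown"]
        )[0]
        rec = by_gene.setdefault(
            gid,
            {"contig": exon.seqid, "strand": exon.strand or ".", "biotype": biotype,
             "intervals": []},
        )
        # GTF is 1-based closed; convert to 0-based half-open
        rec["intervals"].append((exon.start - 1, exon.end))
    for gid, rec in by_gene.items():
        genes.append(
            GeneModel(
                gid,
                rec["biotype"],
                rec["contig"],
                rec["strand"],
                merge_intervals(rec["intervals"]),
            )
        )
    return genes


def _project_bed12(path) -> list[GeneModel]:
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: BED12 requires 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            ivs = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            rec = by_gene.setdefault(
                name, {"contig": chrom, "strand": strand, "intervals": []}
            )
            rec["intervals"].extend(ivs)
    return [
        GeneModel(gid, "unknown", rec["contig"], rec["strand"],
                  merge_intervals(rec["intervals"]))
        for gid, rec in by_gene.items()
    ]


# ---------------------------------------------------------------------------
# mappability intersection and expression
# ---------------------------------------------------------------------------


def _gene_frequencies(gene: GeneModel, freq_track: FrequencyTrack) -> np.ndarray:
    sl = freq_track.contig_slice(gene.contig)
    F = freq_track.values[sl]
    parts = [F[a:b] for a, b in gene.exon_union]
    return np.concatenate(parts) if parts else np.empty(0, dtype=F.dtype)


def unique_exonic_length(gene: GeneModel, freq_track: FrequencyTrack) -> int:
    """Number of exon-union positions with frequency exactly 1."""
    return int((_gene_frequencies(gene, freq_track) == 1).sum())


def read_counts_tsv(path) -> dict[str, int]:
    """gene_id -> count from a two-column (headerless or headered) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id, count")
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:]  # header row
    return {str(g): int(c) for g, c in zip(df.iloc[:, 0], df.iloc[:, 1])}


def count_reads_from_bed(path, genes: list[GeneModel]) -> dict[str, int]:
    """Count reads (BED lines) whose start position falls in each gene's
    exon union.  Reads overlapping two genes count for both."""
    starts_by_contig: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            starts_by_contig.setdefault(f[0], []).append(int(f[1]))
    sorted_starts = {
        c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in starts_by_contig.items()
    }
    counts = {}
    for gene in genes:
        starts = sorted_starts.get(gene.contig)
        c = 0
        if starts is not None:
            for a, b in gene.exon_union:
                c += int(
                    np.searchsorted(starts, b, "left")
                    - np.searchsorted(starts, a, "left")
                )
        counts[gene.gene_id] = c
    return counts


def compute_expression(
    genes: list[GeneModel],
    counts: dict[str, int],
    total_mapped: int,
    freq_track: FrequencyTrack,
) -> pd.DataFrame:
    """Per-gene expression records (columns gene_id, class, L, U, count,
    rpkm, rpkum); rpkum is NaN where U = 0.  Genes missing from
    ``counts`` get count 0 with a logged warning."""
    if total_mapped < 1:
        raise ValueError("total mapped reads must be >= 1")
    rows = []
    for gene in genes:
        if gene.gene_id not in counts:
            logger.warning("gene %s missing from counts; using 0", gene.gene_id)
        c = counts.get(gene.gene_id, 0)
        if c < 0:
            raise ValueError(f"gene {gene.gene_id}: negative read count")
        L = gene.length
        U = unique_exonic_length(gene, freq_track)
        rpkm = 1e9 * c / (L * total_mapped)
        rpkum = 1e9 * c / (U * total_mapped) if U > 0 else float("nan")
        rows.append(
            {
                "gene_id": gene.gene_id,
                "class": gene.class_label,
                "L": L,
                "U": U,
                "count": c,
                "rpkm": rpkm,
                "rpkum": rpkum,
            }
        )
    return pd.DataFrame(rows)


def class_profile(
    genes: list[GeneModel], freq_track: FrequencyTrack, codec
) -> pd.DataFrame:
    """Per-class mappability summary over exon-union positions.

    For each class label: the fractions of positions that are uniquely
    mappable (F = 1), ambiguous (F > 1) and undefined (F = 0) — summing
    to 1 — plus a histogram over the encoded frequency codes of
    ``codec`` (columns ``bin_<code>``), which exposes concentrations such
    as an rRNA cluster occupying one high-copy bin.
    """
    per_class: dict[str, list[np.ndarray]] = {}
    for gene in genes:
        per_class.setdefault(gene.class_label, []).append(
            _gene_frequencies(gene, freq_track)
        )
    rows = []
    for label, chunks in sorted(per_class.items()):
        F = np.concatenate(chunks)
        total = len(F)
        codes = np.asarray(codec.encode(F))
        hist = np.bincount(codes, minlength=codec.code_count)
        row = {
            "class": label,
            "positions": total,
            "frac_unique": (F == 1).sum() / total,
            "frac_ambiguous": (F > 1).sum() / total,
            "frac_undefined": (F == 0).sum() / total,
        }
        row.update({f"bin_{c}": int(h) for c, h in enumerate(hist)})
        rows.append(row)
    return pd.DataFrame(rows)
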