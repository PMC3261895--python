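import numpy as np
import pandas as pd
import pytest

import mappability as mp
from mappability.mappability_core import FrequencyTrack, TrackParams
from mappability.quantification import GeneModel, merge_intervals


def _gtf(lines):
    return "\n".join(lines) + "\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def _exon(contig, a, b, gene, biotype="protein_coding", strand="+"):
    return (
        f"{contig}\tsynth\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{gene}.t1"; gene_type "{biotype}";'
    )


class TestProjectExons:
    def test_overlapping_transcript_exons_union(self, tmp_path):
        text = _gtf(
            [
                _exon("c1", 100, 200, "gA"),
                _exon("c1", 100, 200, "gA"),
                _exon("c1", 150, 250, "gA"),
            ]
        )
        genes = mp.project_exons(_write(tmp_path, "a.gtf", text))
        assert len(genes) == 1
        assert genes[0].exon_union == [(100, 250)]
        assert genes[0].length == 150

    def test_single_exon_gene(self, tmp_path):
        genes = mp.project_exons(
            _write(tmp_path, "b.gtf", _gtf([_exon("c1", 10, 60, "gB", "lncRNA")]))
        )
        assert genes[0].exon_union == [(10, 60)]
        assert genes[0].class_label == "lncRNA"

    def test_overlapping_genes_stay_separate(self, tmp_path):
        text = _gtf(
            [_exon("c1", 100, 300, "gA"), _exon("c1", 200, 400, "gB")]
        )
        genes = sorted(mp.project_exons(_write(tmp_path, "c.gtf", text)),
                       key=lambda g: g.gene_id)
        assert [g.gene_id for g in genes] == ["gA", "gB"]
        assert genes[0].exon_union == [(100, 300)]
        assert genes[1].exon_union == [(200, 400)]

    def test_unknown_contig_skipped_with_warning(self, tmp_path):
        text = _gtf([_exon("c1", 0, 50, "gA"), _exon("cX", 0, 50, "gB")])
        with pytest.warns(UserWarning):
            genes = mp.project_exons(
                _write(tmp_path, "d.gtf", text), known_contigs=["c1"]
            )
        assert [g.gene_id for g in genes] == ["gA"]

    def test_empty_annotation_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            mp.project_exons(
                _write(tmp_path, "e.gtf", _gtf([_exon("cX", 0, 50, "gB")])),
                known_contigs=["c1"],
            )

    def test_bed12_fallback(self, tmp_path):
        bed = (
            "c1\t100\t400\tgA\t0\t+\t100\t400\t0\t2\t50,80\t0,220\n"
        )
        genes = mp.project_exons(_write(tmp_path, "f.bed", bed))
        assert genes[0].exon_union == [(100, 150), (320, 400)]

    def test_merge_intervals_unions(self):
        assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]


def _track(values, k=4, m=0):
    return FrequencyTrack(np.asarray(values), TrackParams(k, m, None), ["c1"], [len(values)])


class TestUniqueExonicLength:
    def test_fully_unique_region(self):
        gene = GeneModel("g", "protein_coding", "c1", "+", [(2, 8)])
        track = _track(np.ones(20, dtype=int))
        assert mp.unique_exonic_length(gene, track) == 6

    def test_half_repeat_gene(self):
        F = np.ones(20, dtype=int)
        F[5:8] = 2
        gene = GeneModel("g", "protein_coding", "c1", "+", [(2, 8)])
        assert mp.unique_exonic_length(gene, _track(F)) == 3

    def test_gene_in_n_gap_has_zero_unique_length(self):
        F = np.zeros(20, dtype=int)
        gene = GeneModel("g", "protein_coding", "c1", "+", [(2, 8)])
        assert mp.unique_exonic_length(gene, _track(F)) == 0


class TestExpression:
    def test_definition_arithmetic(self):
        gene = GeneModel("g", "protein_coding", "c1", "+", [(0, 1000)])
        track = _track(np.ones(1000, dtype=int))
        table = mp.compute_expression([gene], {"g": 100}, 10**6, track)
        row = table.iloc[0]
        assert row.rpkm == pytest.approx(100.0)
        assert row.rpkum == pytest.approx(100.0)

    def test_half_unique_gene_recovers_equal_expression(self):
        """Two equally expressed genes, one half-repetitive: RPKM halves
        but RPKUM corrects the bias."""
        F = np.ones(2000, dtype=int)
        F[1500:2000] = 2  # second half of gene B sits in a 2-copy repeat
        track = _track(F)
        gA = GeneModel("gA", "protein_coding", "c1", "+", [(0, 1000)])
        gB = GeneModel("gB", "protein_coding", "c1", "+", [(1000, 2000)])
        table = mp.compute_expression(
            [gA, gB], {"gA": 200, "gB": 100}, 10**6, track
        ).set_index("gene_id")
        assert table.loc["gB"].rpkm == pytest.approx(table.loc["gA"].rpkm / 2)
        assert table.loc["gB"].rpkum == pytest.approx(table.loc["gA"].rpkum)

    def test_rpkum_na_when_no_unique_positions(self):
        gene = GeneModel("g", "protein_coding", "c1", "+", [(0, 10)])
        track = _track(np.full(10, 7))
        table = mp.compute_expression([gene], {"g": 5}, 1000, track)
        assert np.isnan(table.iloc[0].rpkum)
        assert table.iloc[0].rpkm > 0

    def test_ratio_identity(self, small_repeat_genome):
        ref, truth = small_repeat_genome
        track = mp.exact_frequency_track(ref, 30, 1)
        rng = np.random.default_rng(8)
        genes = []
        for i in range(6):
            a = int(rng.integers(0, ref.n - 300))
            genes.append(GeneModel(f"g{i}", "protein_coding", "chr1", "+", [(a, a + 250)]))
        counts = {g.gene_id: int(rng.integers(1, 500)) for g in genes}
        table = mp.compute_expression(genes, counts, 10**6, track)
        for row in table.itertuples():
            if row.U > 0:
                assert row.rpkum / row.rpkm == pytest.approx(row.L / row.U)
                assert row.rpkum >= row.rpkm

    def test_missing_gene_counts_as_zero(self):
        gene = GeneModel("g", "protein_coding", "c1", "+", [(0, 10)])
        table = mp.compute_expression([gene], {}, 1000, _track(np.ones(10, dtype=int)))
        assert table.iloc[0]["count"] == 0 and table.iloc[0].rpkm == 0

    def test_counts_from_read_bed(self, tmp_path):
        gene = GeneModel("g", "protein_coding", "c1", "+", [(10, 20), (30, 40)])
        bed = "c1\t12\t48\n" "c1\t25\t61\n" "c1\t35\t71\n" "c2\t15\t51\n"
        p = tmp_path / "reads.bed"
        p.write_text(bed)
        counts = mp.count_reads_from_bed(p, [gene])
        assert counts == {"g": 2}  # starts 12 and 35 fall in the union


class TestClassProfile:
    def test_fractions_sum_to_one(self, small_repeat_genome):
        ref, _ = small_repeat_genome
        track = mp.exact_frequency_track(ref, 30, 1)
        genes = [
            GeneModel("g1", "protein_coding", "chr1", "+", [(50, 400)]),
            GeneModel("g2", "rRNA", "chr1", "+", [(400, 900)]),
        ]
        prof = mp.class_profile(genes, track, mp.EncodingTable())
        for row in prof.itertuples():
            assert row.frac_unique + row.frac_ambiguous + row.frac_undefined == pytest.approx(1.0)

    def test_all_unique_fixture(self, random_dna):
        ref = mp.ReferenceSequence([("c1", random_dna(800, seed=40))])
        track = mp.exact_frequency_track(ref, 25, 0)
        genes = [GeneModel("g1", "protein_coding", "c1", "+", [(100, 500)])]
        prof = mp.class_profile(genes, track, mp.EncodingTable())
        assert prof.iloc[0].frac_unique == pytest.approx(1.0)

    def test_high_copy_cluster_concentrates_in_one_bin(self):
        """An rRNA-like 10-copy cluster shows up as occupancy at the code
        for frequency ~10 while background genes stay unique."""
        ref, truth = mp.generate_genome(8000, [mp.RepeatSpec(120, 10, 0)], seed=13)
        track = mp.exact_frequency_track(ref, 40, 0)
        codec = mp.EncodingTable()
        row0 = truth.iloc[0]
        rrna = GeneModel("rr1", "rRNA", row0.contig, "+", [(row0.start, row0.end)])
        # a background gene well clear of every planted copy
        occ = [(r.start, r.end) for r in truth.itertuples()]
        a = 0
        while any(a < e + 50 and a + 350 > s - 50 for s, e in occ):
            a += 50
        assert a + 350 < ref.n
        pc = GeneModel("pc1", "protein_coding", "chr1", "+", [(a, a + 300)])
        prof = mp.class_profile([rrna, pc], track, codec).set_index("class")
        code10 = int(codec.encode(10))
        rrna_row = prof.loc["rRNA"]
        # most of the cluster's defined k-mers live in the 10-copy class
        assert rrna_row[f"bin_{code10}"] >= 0.5 * rrna_row.positions
        assert prof.loc["protein_coding"].frac_unique > 0.9
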