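"""Format boundary: gene models, VCF, similarity hits, results tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mkscan.seqio import (
    GeneModel,
    MissingChromosomeError,
    SeqIOError,
    VcfFormatError,
    read_gene_models,
    read_results_table,
    read_similarity_hits,
    read_vcf,
    write_results_table,
)


def write_fasta(path, seqs):
    path.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))


def write_gff(path, rows):
    path.write_text("##gff-version 3\n" + "\n".join(rows) + "\n")


def gene_rows(gene_id, chrom, strand, intervals, tx_suffix=".1"):
    tx = gene_id + tx_suffix
    start, end = intervals[0][0] + 1, intervals[-1][1]
    rows = [
        f"{chrom}\tt\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}",
        f"{chrom}\tt\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={tx};Parent={gene_id}",
    ]
    for s, e in intervals:
        rows.append(f"{chrom}\tt\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\tID=c{tx};Parent={tx}")
    return rows


class TestReadGeneModels:
    def test_plus_strand_identity_splice(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"chr1": "ATGAAACCCGGG"})
        write_gff(tmp_path / "a.gff3", gene_rows("g1", "chr1", "+", [(0, 6)]))
        genes, rejected = read_gene_models(tmp_path / "a.gff3", tmp_path / "g.fa")
        assert not rejected
        assert genes[0].cds_sequence == "ATGAAA"

    def test_minus_strand_reverse_complement(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"chr1": "TTTCATCCCGGG"})
        write_gff(tmp_path / "a.gff3", gene_rows("g1", "chr1", "-", [(0, 6)]))
        genes, _ = read_gene_models(tmp_path / "a.gff3", tmp_path / "g.fa")
        assert genes[0].cds_sequence == "ATGAAA"

    def test_two_exon_splice_in_transcription_order(self, tmp_path):
        genome = "ATGCCCCCCCAAA" + "T" * 5
        write_fasta(tmp_path / "g.fa", {"chr1": genome})
        write_gff(tmp_path / "a.gff3", gene_rows("g1", "chr1", "+", [(0, 3), (10, 13)]))
        genes, _ = read_gene_models(tmp_path / "a.gff3", tmp_path / "g.fa")
        assert genes[0].cds_sequence == "ATG" + "AAA"

    def test_longest_cds_transcript_selected(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"chr1": "ATGAAATTTTAG"})
        rows = gene_rows("g1", "chr1", "+", [(0, 6)], tx_suffix=".1")
        rows += gene_rows("g1", "chr1", "+", [(0, 9)], tx_suffix=".2")[1:]
        write_gff(tmp_path / "a.gff3", rows)
        genes, _ = read_gene_models(tmp_path / "a.gff3", tmp_path / "g.fa")
        assert len(genes) == 1
        assert genes[0].cds_sequence == "ATGAAATTT"

    @pytest.mark.parametrize(
        "seq,reason",
        [
            ("ATGAA", "Frame"),          # length not divisible by 3
            ("ATGTAACCC", "InternalStop"),
            ("ATGNNNAAA", "Ambiguous"),
        ],
    )
    def test_invalid_genes_rejected_not_returned(self, tmp_path, seq, reason):
        write_fasta(tmp_path / "g.fa", {"chr1": seq + "GGGG"})
        write_gff(tmp_path / "a.gff3", gene_rows("g1", "chr1", "+", [(0, len(seq))]))
        genes, rejected = read_gene_models(tmp_path / "a.gff3", tmp_path / "g.fa")
        assert genes == []
        assert len(rejected) == 1 and reason in rejected[0]["reason"]

    def test_missing_chromosome_is_hard_error(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"chr2": "ATGAAA"})
        write_gff(tmp_path / "a.gff3", gene_rows("g1", "chr1", "+", [(0, 6)]))
        with pytest.raises(MissingChromosomeError):
            read_gene_models(tmp_path / "a.gff3", tmp_path / "g.fa")

    def test_bed12_blocks_as_cds(self, tmp_path):
        genome = "ATGCCCCCCCAAA" + "T" * 5
        write_fasta(tmp_path / "g.fa", {"chr1": genome})
        bed = "chr1\t0\t13\tg1\t0\t+\t0\t13\t0\t2\t3,3\t0,10\n"
        (tmp_path / "a.bed").write_text(bed)
        genes, _ = read_gene_models(tmp_path / "a.bed", tmp_path / "g.fa")
        assert genes[0].cds_sequence == "ATGAAA"


class TestGeneModelCoordinates:
    def test_interval_lengths_equal_sequence_length(self, tiny_dataset):
        config, paths = tiny_dataset
        genes, rejected = read_gene_models(paths["gff"], paths["genome"])
        assert not rejected and len(genes) == config.n_genes
        for gene in genes:
            assert sum(e - s for s, e in gene.cds_intervals) == gene.cds_length

    def test_genomic_cds_round_trip(self, tiny_dataset):
        _, paths = tiny_dataset
        genes, _ = read_gene_models(paths["gff"], paths["genome"])
        for gene in genes[:10]:
            for off in range(0, gene.cds_length, 7):
                assert gene.genomic_to_cds(gene.cds_to_genomic(off)) == off


def write_vcf_text(path, body_rows, samples=("s1", "s2", "s3", "s4", "s5")):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    path.write_text(header + "".join(r + "\n" for r in body_rows))


class TestReadVcf:
    def test_alt_presence_counts_het_and_hom(self, tmp_path):
        row = "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t1|1\t0|1\t1|0\t0|0\t0|0"
        write_vcf_text(tmp_path / "v.vcf", [row])
        records, skipped = read_vcf(tmp_path / "v.vcf")
        assert len(records) == 1
        assert records[0].accession_presence == frozenset({"s1", "s2", "s3"})
        assert not any(skipped.values())

    def test_indel_and_multiallelic_skipped_and_counted(self, tmp_path):
        rows = [
            "chr1\t10\t.\tA\tAT\t.\tPASS\t.\tGT\t1|1\t0|0\t0|0\t0|0\t0|0",
            "chr1\t20\t.\tA\tT,G\t.\tPASS\t.\tGT\t1|1\t0|0\t0|0\t0|0\t0|0",
            "chr1\t30\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t0|0\t0|0\t0|0\t0|0",
        ]
        write_vcf_text(tmp_path / "v.vcf", rows)
        records, skipped = read_vcf(tmp_path / "v.vcf")
        assert [r.pos for r in records] == [30]
        assert skipped["indel"] == 1 and skipped["multiallelic"] == 1

    def test_unknown_accession_rejected(self, tmp_path):
        row = "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t1|1\t0|0\t0|0\t0|0\t0|0"
        write_vcf_text(tmp_path / "v.vcf", [row])
        with pytest.raises(VcfFormatError):
            read_vcf(tmp_path / "v.vcf", accession_ids=["nope"])

    def test_unparseable_file_raises(self, tmp_path):
        (tmp_path / "v.vcf").write_text("this is not a VCF\n")
        with pytest.raises(VcfFormatError):
            read_vcf(tmp_path / "v.vcf")


class TestSimilarityHits:
    @staticmethod
    def row(q, s, length=100, evalue=1e-50, bits=200.0):
        return f"{q}\t{s}\t99.0\t{length}\t1\t0\t1\t{length}\t1\t{length}\t{evalue}\t{bits}"

    def test_best_hsp_reduction(self, tmp_path):
        rows = [self.row("a", "b", bits=50.0), self.row("a", "b", bits=80.0)]
        (tmp_path / "h.tsv").write_text("\n".join(rows) + "\n")
        hits = read_similarity_hits(tmp_path / "h.tsv", {"a": 100})
        assert len(hits) == 1 and hits[0].bitscore == 80.0

    def test_coverage_from_alignment_length(self, tmp_path):
        (tmp_path / "h.tsv").write_text(self.row("a", "b", length=95) + "\n")
        hits = read_similarity_hits(tmp_path / "h.tsv", {"a": 100})
        assert hits[0].query_coverage == pytest.approx(0.95)

    def test_thirteenth_column_used_when_present(self, tmp_path):
        (tmp_path / "h.tsv").write_text(self.row("a", "b") + "\t0.87\n")
        hits = read_similarity_hits(tmp_path / "h.tsv")
        assert hits[0].query_coverage == pytest.approx(0.87)

    def test_empty_file_gives_empty_list(self, tmp_path):
        (tmp_path / "h.tsv").write_text("")
        assert read_similarity_hits(tmp_path / "h.tsv", {}) == []


class TestResultsTable:
    def test_na_encoding_and_gene_order(self, tmp_path):
        df = pd.DataFrame(
            {"gene_id": ["g2", "g1"], "x": [1.5, math.nan], "label": ["b", "a"]}
        )
        out = tmp_path / "t.tsv"
        write_results_table(df, out)
        text = out.read_text().splitlines()
        assert text[1].startswith("g1") and "NA" in text[1]

    @given(
        values=st.lists(
            st.one_of(
                st.floats(allow_nan=False, allow_infinity=False, width=64),
                st.just(math.nan),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_is_lossless(self, values):
        import tempfile, os

        df = pd.DataFrame(
            {"gene_id": [f"g{i:04d}" for i in range(len(values))], "value": values}
        )
        fd, name = tempfile.mkstemp(suffix=".tsv")
        os.close(fd)
        try:
            write_results_table(df, name)
            back = read_results_table(name)
            assert len(back) == len(df)
            for orig, rt in zip(df["value"], back["value"]):
                assert (math.isnan(orig) and math.isnan(rt)) or orig == rt
        finally:
            os.unlink(name)
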