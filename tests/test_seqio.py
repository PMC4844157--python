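"""File formats, gene-id parsing, and gene-model structural facts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famscan.seqio import (
    FormatError,
    GeneModel,
    count_exons_introns,
    gene_table,
    parse_gene_id,
    read_fasta,
    read_gff3,
    read_tsv_table,
    write_fasta,
    write_gff3,
    write_tsv_tables,
)
from famscan.synthetic_data import back_translate


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">g1\nMKV\n")
        assert dict(read_fasta(p)) == {"g1": "MKV"}

    def test_duplicate_id_is_an_error(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">g1\nMKV\n>g1\nMKW\n")
        with pytest.raises(FormatError, match="g1"):
            read_fasta(p)

    def test_empty_sequence_is_an_error(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">g1\n\n>g2\nMKV\n")
        with pytest.raises(FormatError, match="empty"):
            read_fasta(p)

    def test_trailing_stop_stripped_and_recorded(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">g1\nMKV*\n>g2\nMKW\n")
        seqs = read_fasta(p)
        assert seqs["g1"] == "MKV"
        assert seqs.stripped_stop_ids == ["g1"]

    def test_internal_stop_is_an_error(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">g1\nMK*V\n")
        with pytest.raises(FormatError, match="internal stop"):
            read_fasta(p)

    def test_round_trip_identity_on_50_records(self, tmp_path, rng):
        seqs = {
            f"gene_{i:03d}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 1 + int(rng.integers(200))))
            for i in range(50)
        }
        p = tmp_path / "rt.fa"
        write_fasta(seqs, p)
        assert dict(read_fasta(p)) == seqs


class TestGeneIdParsing:
    @pytest.mark.parametrize(
        "gene_id, expected",
        [
            ("Traes_2AS_0001", ("A", 2, "S", "chromosome")),
            ("Traes_7DL_0042", ("D", 7, "L", "chromosome")),
            ("Traes_5BS_12ab", ("B", 5, "S", "chromosome")),
            ("scaffold_991_g3", ("unknown", "scaffold_991", "none", "scaffold")),
            ("not-a-wheat-id", ("unknown", "not-a-wheat-id", "none", "scaffold")),
        ],
    )
    def test_examples(self, gene_id, expected):
        assert tuple(parse_gene_id(gene_id)) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.text(min_size=0, max_size=30))
    def test_total_over_strings(self, s):
        p = parse_gene_id(s)
        assert p.placement in ("chromosome", "scaffold")
        if p.placement == "chromosome":
            assert p.sub_genome in "ABD" and 1 <= p.chromosome <= 7


def _gene(n_exons: int) -> GeneModel:
    protein = "MKVLWAALHE" * 3
    cds = back_translate(protein, "Traes_1AS_0001")
    exon_len = len(cds) // n_exons
    exons, pos = [], 100
    for k in range(n_exons):
        L = exon_len if k < n_exons - 1 else len(cds) - exon_len * (n_exons - 1)
        exons.append((pos, pos + L - 1))
        pos += L + 50
    return GeneModel.from_parts(
        "Traes_1AS_0001", 100, exons[-1][1], "+", exons, cds, protein
    )


class TestGeneModel:
    @pytest.mark.parametrize("n_exons, expected", [(1, (1, 0)), (4, (4, 3)), (8, (8, 7))])
    def test_exon_intron_counts(self, n_exons, expected):
        assert count_exons_introns(_gene(n_exons)) == expected

    def test_no_exons_is_an_error(self):
        g = _gene(1)
        g.exons = ()
        with pytest.raises(FormatError):
            count_exons_introns(g)

    def test_cds_protein_length_mismatch_rejected(self):
        with pytest.raises(FormatError, match="CDS length"):
            GeneModel.from_parts("g1", 1, 90, "+", [(1, 90)], "ATG" * 30, "M" * 10)

    def test_translation_matches_protein_on_synthetic_records(self, small_sim):
        for g in small_sim.genome_a:
            assert g.translated() == g.protein


class TestGff3:
    def test_minimal_single_gene(self, tmp_path):
        protein = "MKV"
        cds = back_translate(protein, "g1")  # 12 nt with stop
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1A\tsrc\tgene\t10\t21\t.\t+\t.\tID=g1\n"
            "1A\tsrc\tmRNA\t10\t21\t.\t+\t.\tID=g1.m;Parent=g1\n"
            "1A\tsrc\texon\t10\t21\t.\t+\t.\tID=e1;Parent=g1.m\n"
        )
        gs = read_gff3(gff, {"g1": cds}, {"g1": protein})
        assert len(gs) == 1
        assert gs.genes["g1"].exons == ((10, 21),)

    def test_exon_outside_gene_span_reports_line(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "1A\tsrc\tgene\t10\t20\t.\t+\t.\tID=g1\n"
            "1A\tsrc\texon\t5\t20\t.\t+\t.\tID=e1;Parent=g1\n"
        )
        with pytest.raises(FormatError, match=r":2:"):
            read_gff3(gff, {"g1": "ATGTAA"}, {"g1": "M"})

    def test_cds_not_divisible_by_three_rejected(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("1A\tsrc\tgene\t1\t8\t.\t+\t.\tID=g1\n")
        with pytest.raises(FormatError, match="divisible by 3"):
            read_gff3(gff, {"g1": "ATGTAAA"}, {"g1": "M"})

    def test_round_trip_preserves_all_coordinates(self, tmp_path, small_sim):
        genome = small_sim.genome_a
        p = tmp_path / "rt.gff3"
        write_gff3(genome, p)
        back = read_gff3(p, genome.transcripts(), genome.proteins())
        assert set(back.genes) == set(genome.genes)
        for gid, g in genome.genes.items():
            b = back.genes[gid]
            assert (b.start, b.end, b.strand, b.exons) == (g.start, g.end, g.strand, g.exons)
            assert (b.sub_genome, b.chromosome, b.placement) == (
                g.sub_genome, g.chromosome, g.placement
            )


class TestTsvTables:
    def test_round_trip_with_provenance_header(self, tmp_path, small_sim):
        df = gene_table(small_sim.genome_a)
        write_tsv_tables({"genes": df}, tmp_path, header_lines=["famscan test"])
        back = read_tsv_table(tmp_path / "genes.tsv")
        assert list(back.columns) == list(df.columns)
        assert back["gene_id"].tolist() == df["gene_id"].tolist()
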