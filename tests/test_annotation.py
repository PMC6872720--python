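"""Circular-coordinate arithmetic, gene-table and GenBank I/O."""

import pytest

from mitochar import refdata
from mitochar.annotation import (
    AnnotationError,
    GeneFeature,
    GenomeSequence,
    MitoAnnotation,
    UnsupportedLocationError,
    extract_sequence,
    gene_length,
    read_gene_table,
    read_genbank,
    reverse_complement,
    spacer_lengths,
    write_gene_table,
    write_genbank,
)


def brute_force_length(start, end, genome_length):
    """Independent oracle: walk the circle one base at a time."""
    pos, n = start, 1
    while pos != end:
        pos = pos % genome_length + 1
        n += 1
    return n


@pytest.mark.parametrize(
    "start,end,genome_length,expected",
    [
        (11217, 12514, 15955, 1298),  # rrnL span
        (5, 5, 100, 1),  # single base
        (15950, 3, 15955, 9),  # wraps through the origin
        (1, 1542, 15955, 1542),  # first gene of the circle
    ],
)
def test_gene_length_matches_brute_force_walk(start, end, genome_length, expected):
    f = GeneFeature("x", "rRNA", start, end, "H")
    assert gene_length(f, genome_length) == expected
    assert gene_length(f, genome_length) == brute_force_length(start, end, genome_length)


class TestSpacers:
    def test_reference_overlaps_and_gaps(self, ref_annotation):
        spacers = dict(spacer_lengths(ref_annotation))
        assert spacers["atp8"] == -7  # atp8/atp6 overlap
        assert spacers["trnL2"] == 2  # trnL2 -> cox2 gap
        assert spacers["trnY"] == 4  # wrap pair back to cox1

    def test_abutting_genes_have_zero_spacer(self):
        a = MitoAnnotation(
            200,
            [GeneFeature("a", "tRNA", 1, 100, "H"), GeneFeature("b", "tRNA", 101, 150, "H")],
        )
        spacers = dict(spacer_lengths(a))
        assert spacers["a"] == 0
        assert spacers["b"] == 50  # wrap: 150 -> 1 around a 200 bp circle

    def test_linear_annotation_omits_wrap_pair(self):
        a = MitoAnnotation(
            200,
            [GeneFeature("a", "tRNA", 1, 100, "H"), GeneFeature("b", "tRNA", 101, 150, "H")],
            circular=False,
        )
        assert [name for name, _ in spacer_lengths(a)] == ["a"]

    def test_circular_conservation_on_reference(self, ref_annotation):
        total = sum(
            gene_length(f, ref_annotation.genome_length) for f in ref_annotation
        ) + sum(s for _, s in spacer_lengths(ref_annotation))
        assert total == ref_annotation.genome_length


class TestReferenceGeometry:
    def test_category_and_strand_census(self, ref_annotation):
        assert ref_annotation.category_counts() == {"PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1}
        assert ref_annotation.strand_counts() == {"H": 23, "L": 14}

    def test_trna_lengths_sum_to_region_size(self, ref_annotation):
        total = sum(ref_annotation.length_of(f.name) for f in ref_annotation.of_category("tRNA"))
        assert total == 1438

    def test_printed_length_discrepancies_are_surfaced(self, ref_annotation):
        disc = dict((n, (c, p)) for n, c, p in refdata.length_discrepancies(ref_annotation))
        assert disc["cox2"] == (690, 675)
        assert disc["nad4l"] == (300, 264)
        assert "rrnL" not in disc  # agreeing rows are not reported


class TestGeneTableIO:
    def test_round_trip_identity(self, ref_annotation, tmp_path):
        p = tmp_path / "genes.tsv"
        write_gene_table(ref_annotation, p)
        again = read_gene_table(p)
        assert again.genome_length == ref_annotation.genome_length
        assert again.features == ref_annotation.features

    @pytest.mark.parametrize(
        "rows,message",
        [
            (["a\ttRNA\t1\t50\t+", "a\ttRNA\t60\t100\t+"], "duplicate"),
            (["a\ttRNA\t1\t250\t+"], "outside"),
            (["a\tsnRNA\t1\t50\t+"], "category"),
            ([], "no feature rows"),
        ],
    )
    def test_validation_errors(self, tmp_path, rows, message):
        p = tmp_path / "bad.tsv"
        p.write_text("#genome_length=200\nname\tcategory\tstart\tend\tstrand\n" + "\n".join(rows))
        with pytest.raises(AnnotationError, match=message):
            read_gene_table(p)

    def test_missing_pragma_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("name\tcategory\tstart\tend\tstrand\na\ttRNA\t1\t50\t+\n")
        with pytest.raises(AnnotationError, match="genome_length"):
            read_gene_table(p)


class TestGenBankIO:
    def _tiny(self):
        ann = MitoAnnotation(
            60,
            [
                GeneFeature("g1", "PCG", 1, 30, "H", start_codon="ATG", stop_codon="TAA"),
                GeneFeature("g2", "tRNA", 31, 45, "L", anticodon="TTT"),
                GeneFeature("CR", "CR", 46, 60, None),
            ],
        )
        genome = GenomeSequence("ATGAAATTTGGGCCCAAATTTGGGCCCTAA" + "ACGT" * 7 + "AC")
        return ann, genome

    def test_round_trip_identity(self, tmp_path):
        ann, genome = self._tiny()
        p = tmp_path / "tiny.gb"
        write_genbank(ann, genome, p)
        ann2, genome2 = read_genbank(p)
        assert ann2.features == ann.features
        assert genome2.residues == genome.residues

    def test_complement_location_becomes_L_strand(self, tmp_path):
        ann, genome = self._tiny()
        p = tmp_path / "tiny.gb"
        write_genbank(ann, genome, p)
        ann2, _ = read_genbank(p)
        assert ann2.get("g2").strand == "L"
        assert ann2.get("CR").strand is None

    def test_join_location_rejected(self, tmp_path):
        ann, genome = self._tiny()
        p = tmp_path / "tiny.gb"
        write_genbank(ann, genome, p)
        text = p.read_text().replace("31..45", "join(55..60,1..9)")
        p.write_text(text)
        with pytest.raises(UnsupportedLocationError):
            read_genbank(p)

    def test_multi_record_rejected(self, tmp_path):
        ann, genome = self._tiny()
        p = tmp_path / "tiny.gb"
        write_genbank(ann, genome, p)
        p.write_text(p.read_text() * 2)
        with pytest.raises(AnnotationError, match="one GenBank record"):
            read_genbank(p)


class TestExtractSequence:
    def test_h_strand_coding_equals_genome_slice(self):
        g = GenomeSequence("ACGTACGTAC")
        f = GeneFeature("x", "tRNA", 2, 5, "H")
        assert extract_sequence(f, g, "coding") == extract_sequence(f, g, "genome") == "CGTA"

    def test_l_strand_coding_is_reverse_complement(self):
        g = GenomeSequence("AAACGTAAAA")
        f = GeneFeature("x", "tRNA", 4, 7, "L")
        assert extract_sequence(f, g, "genome") == "CGTA"
        assert extract_sequence(f, g, "coding") == "TACG"

    def test_origin_spanning_matches_rotation_oracle(self):
        residues = "ACGTTGCAAC"
        g = GenomeSequence(residues)
        f = GeneFeature("x", "tRNA", 8, 3, "H")
        # Oracle: rotate the genome so the feature start is position 1, then slice.
        rotated = residues[7:] + residues[:7]
        expected = rotated[: gene_length(f, len(residues))]
        assert extract_sequence(f, g, "genome") == expected

    def test_length_equals_gene_length(self, ref_annotation):
        g = GenomeSequence("A" * ref_annotation.genome_length)
        for f in ref_annotation:
            assert len(extract_sequence(f, g)) == gene_length(f, ref_annotation.genome_length)


def test_reverse_complement_involution():
    s = "ACGTTGCANN"
    assert reverse_complement(reverse_complement(s)) == s
    assert reverse_complement("ACGT") == "ACGT"
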