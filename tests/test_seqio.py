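"""I/O: FASTA parsing, FASTQ variants and conversion, GFF dialects,
GFF3 writing and spliced-sequence extraction."""

import io

import pytest
from Bio import SeqIO as BioSeqIO

from seqforge import DNA, FormatError, ValidationError, make_sequence
from seqforge.errors import ConsistencyError
from seqforge.seqio import (
    Feature,
    FastqRecord,
    convert_fastq,
    extract_spliced,
    phred_to_solexa,
    read_fasta,
    read_fastq,
    read_gff,
    solexa_to_phred,
    write_fasta,
    write_fastq,
    write_gff3,
)

from conftest import random_dna


class TestFasta:
    def test_minimal_record(self):
        recs = read_fasta(io.StringIO(">s1 desc\nACGT\n"))
        assert len(recs) == 1
        assert recs[0].identifier == "s1"
        assert recs[0].description == "desc"
        assert str(recs[0]) == "ACGT"

    def test_wrapped_lines_concatenate(self):
        recs = read_fasta(io.StringIO(">a\nAC\nGT\n>b\nTT\n"))
        assert [str(r) for r in recs] == ["ACGT", "TT"]
        assert [r.identifier for r in recs] == ["a", "b"]

    def test_missing_header_is_format_error_with_line(self):
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(io.StringIO("ACGT\n"))

    def test_round_trip_preserves_content(self, rng):
        recs = [
            make_sequence(random_dna(rng, rng.randint(0, 150)), DNA, f"r{i}", "d")
            for i in range(5)
        ]
        text = write_fasta(recs)
        back = read_fasta(io.StringIO(text), alphabet=DNA)
        assert [str(r) for r in back] == [str(r) for r in recs]
        assert [r.identifier for r in back] == [r.identifier for r in recs]


class TestFastqParsing:
    def test_sanger_decoding(self):
        rec = next(read_fastq(io.StringIO("@r1\nAC\n+\nII\n"), "sanger"))
        assert rec.qualities == (40, 40)  # 'I' = 73; 73 - 33

    def test_illumina13_decoding(self):
        rec = next(read_fastq(io.StringIO("@r1\nAC\n+\nhh\n"), "illumina13"))
        assert rec.qualities == (40, 40)  # 'h' = 104; 104 - 64

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError, match="length"):
            list(read_fastq(io.StringIO("@r1\nACG\n+\nII\n"), "sanger"))

    def test_truncated_record_rejected(self):
        with pytest.raises(FormatError, match="truncated"):
            list(read_fastq(io.StringIO("@r1\nACG\n"), "sanger"))

    def test_out_of_range_quality_rejected(self):
        # '!' encodes −5 Solexa (legal) but Phred −31 under illumina13
        with pytest.raises(FormatError, match="range"):
            list(read_fastq(io.StringIO("@r\nA\n+\n!\n"), "illumina13"))

    def test_streaming_is_lazy(self):
        stream = io.StringIO("@a\nA\n+\nI\n@broken\nAC\n+\nI\n")
        it = read_fastq(stream, "sanger")
        assert next(it).identifier == "a"
        with pytest.raises(FormatError):
            next(it)


class TestFastqRoundTrip:
    @pytest.mark.parametrize("variant", ["sanger", "solexa", "illumina13"])
    def test_write_read_is_byte_exact(self, rng, variant):
        from seqforge.seqio import VARIANTS

        spec = VARIANTS[variant]
        records = []
        for i in range(100):
            n = rng.randint(1, 40)
            records.append(
                FastqRecord(
                    f"read{i}",
                    make_sequence(random_dna(rng, n), DNA),
                    tuple(rng.randint(spec.qmin, spec.qmax) for _ in range(n)),
                    variant,
                )
            )
        text = write_fastq(records, variant)
        again = write_fastq(list(read_fastq(io.StringIO(text), variant)), variant)
        assert text == again

    def test_q0_sanger_writes_bang(self):
        rec = FastqRecord("r", make_sequence("A", DNA), (0,), "sanger")
        assert write_fastq([rec], "sanger").splitlines()[3] == "!"

    def test_out_of_range_rejected_at_write(self):
        with pytest.raises(ValidationError):
            FastqRecord("r", make_sequence("A", DNA), (63,), "illumina13")


class TestFastqConversion:
    def test_sanger_illumina13_round_trip_is_identity(self):
        for q in range(0, 63):
            rec = FastqRecord("r", make_sequence("A", DNA), (q,), "sanger")
            there = convert_fastq(rec, "illumina13")
            back = convert_fastq(there, "sanger")
            assert back.qualities == (q,)

    def test_sanger_q40_becomes_h(self):
        rec = FastqRecord("r", make_sequence("A", DNA), (40,), "sanger")
        out = convert_fastq(rec, "illumina13")
        assert write_fastq([out], "illumina13").splitlines()[3] == "h"

    def test_solexa_minus5_maps_to_phred_1(self):
        rec = FastqRecord("r", make_sequence("A", DNA), (-5,), "solexa")
        assert convert_fastq(rec, "sanger").qualities == (1,)

    def test_sanger_q93_clamped_to_illumina_max(self):
        rec = FastqRecord("r", make_sequence("A", DNA), (93,), "sanger")
        assert convert_fastq(rec, "illumina13").qualities == (62,)

    def test_solexa_to_phred_is_monotone(self):
        values = [solexa_to_phred(q) for q in range(-5, 63)]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_solexa_phred_mappings_are_inverse(self):
        for q in range(1, 63):
            assert abs(solexa_to_phred(phred_to_solexa(q)) - q) < 1e-9

    def test_conversion_matches_biopython(self, rng):
        """Cross-check the Solexa mapping against Biopython's FASTQ
        variant conversion on random records."""
        for _ in range(20):
            n = rng.randint(1, 30)
            quals = tuple(rng.randint(-5, 40) for _ in range(n))
            rec = FastqRecord("r", make_sequence(random_dna(rng, n), DNA), quals, "solexa")
            ours = convert_fastq(rec, "sanger")
            text = write_fastq([rec], "solexa")
            out = io.StringIO()
            BioSeqIO.convert(io.StringIO(text), "fastq-solexa", out, "fastq")
            bio = next(BioSeqIO.parse(io.StringIO(out.getvalue()), "fastq"))
            theirs = tuple(bio.letter_annotations["phred_quality"])
            assert ours.qualities == theirs


class TestGff:
    GFF3 = (
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t9\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
        "chr1\tsrc\tCDS\t1\t3\t.\t+\t0\tParent=t1\n"
        "chr1\tsrc\tCDS\t7\t9\t.\t+\t0\tParent=t1\n"
    )

    def test_gff3_fields_and_parent_links(self):
        feats = read_gff(io.StringIO(self.GFF3))
        gene = feats[0]
        assert (gene.type, gene.start, gene.end, gene.strand) == ("gene", 1, 9, "+")
        assert gene.id == "g1"
        mrna = feats[1]
        assert [p.id for p in mrna.parents] == ["g1"]
        assert all(p.id == "t1" for f in feats[2:] for p in f.parents)

    def test_gtf_attributes(self):
        line = 'chr1\tGeneMark\tCDS\t1\t9\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
        feat = read_gff(io.StringIO(line), "gtf")[0]
        assert feat.attributes == {"gene_id": ["g1"], "transcript_id": ["t1"]}

    def test_wrong_column_count_is_format_error(self):
        with pytest.raises(FormatError, match="line 1"):
            read_gff(io.StringIO("chr1\tsrc\tgene\t1\t9\t.\t+\t.\n"))

    def test_write_read_round_trip(self):
        feats = read_gff(io.StringIO(self.GFF3))
        back = read_gff(io.StringIO(write_gff3(feats)))
        assert back == feats

    def test_reserved_characters_percent_escaped(self):
        f = Feature("c", "s", "exon", 1, 2, attributes={"Note": ["a;b=c,d"]})
        line = write_gff3([f]).splitlines()[1]
        assert "Note=a%3Bb%3Dc%2Cd" in line
        assert read_gff(io.StringIO(write_gff3([f])))[0].attributes == f.attributes

    def test_cds_without_phase_rejected_on_write(self):
        f = Feature("c", "s", "CDS", 1, 3)
        with pytest.raises(ValidationError, match="phase"):
            write_gff3([f])

    def test_empty_feature_list_writes_header_only(self):
        assert write_gff3([]) == "##gff-version 3\n"


class TestExtractSpliced:
    genome = make_sequence("AAACCCGGGTTT", DNA)

    def test_plus_strand_single_segment(self):
        f = Feature("c", "s", "CDS", 4, 6, strand="+", phase=0)
        assert str(extract_spliced([f], self.genome)) == "CCC"

    def test_minus_strand_reverse_complements(self):
        f = Feature("c", "s", "CDS", 4, 6, strand="-", phase=0)
        assert str(extract_spliced([f], self.genome)) == "GGG"

    def test_two_segments_concatenate(self):
        fs = [
            Feature("c", "s", "CDS", 1, 3, strand="+", phase=0),
            Feature("c", "s", "CDS", 7, 9, strand="+", phase=0),
        ]
        assert str(extract_spliced(fs, self.genome)) == "AAAGGG"

    def test_mixed_strands_rejected(self):
        fs = [
            Feature("c", "s", "CDS", 1, 3, strand="+", phase=0),
            Feature("c", "s", "CDS", 7, 9, strand="-", phase=0),
        ]
        with pytest.raises(ConsistencyError):
            extract_spliced(fs, self.genome)

    def test_overlap_rejected(self):
        fs = [
            Feature("c", "s", "CDS", 1, 5, strand="+", phase=0),
            Feature("c", "s", "CDS", 4, 9, strand="+", phase=0),
        ]
        with pytest.raises(ConsistencyError):
            extract_spliced(fs, self.genome)

    def test_strand_mirror_symmetry(self, rng):
        """Extracting on '+' equals extracting the mirrored coordinates on
        '−' from the reverse-complemented genome."""
        from seqforge import reverse_complement

        for _ in range(20):
            n = rng.randint(20, 60)
            genome = make_sequence(random_dna(rng, n), DNA)
            segs = []
            pos = 1
            while pos < n - 4 and len(segs) < 3:
                start = pos + rng.randint(0, 3)
                end = min(n, start + rng.randint(0, 5))
                if start > end:
                    break
                segs.append((start, end))
                pos = end + 2
            if not segs:
                continue
            plus = [
                Feature("c", "s", "CDS", s, e, strand="+", phase=0)
                for s, e in segs
            ]
            mirrored = [
                Feature("c", "s", "CDS", n - e + 1, n - s + 1, strand="-", phase=0)
                for s, e in segs
            ]
            assert extract_spliced(plus, genome) == extract_spliced(
                mirrored, reverse_complement(genome)
            )
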