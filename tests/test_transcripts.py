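"""Annotation parsing, mature-RNA extraction and six-track encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaclr.transcripts import (
    GenePredParseError,
    GenomicInterval,
    MatureRNA,
    TranscriptModel,
    decode_six_track,
    encode_six_track,
    extract_mature_rna,
    read_genepred,
    read_toga_bed,
    reverse_complement,
)


def _genepred_row(name, chrom, strand, starts, ends, cds=(0, 0), gene=None):
    fields = [
        name, chrom, strand, str(starts[0]), str(ends[-1]),
        str(cds[0]), str(cds[1]), str(len(starts)),
        ",".join(map(str, starts)) + ",", ",".join(map(str, ends)) + ",",
    ]
    if gene:
        fields += ["0", gene]
    return "\t".join(fields)


class TestReadGenePred:
    def test_single_exon_row(self, tmp_path):
        path = tmp_path / "a.genePred"
        path.write_text(_genepred_row("t1", "chr1", "+", [100], [200], cds=(130, 190)) + "\n")
        (m,) = read_genepred(path)
        assert len(m.exons) == 1
        assert (m.cds_start, m.cds_end) == (130, 190)
        assert m.is_coding

    def test_exon_count_mismatch_names_line(self, tmp_path):
        path = tmp_path / "bad.genePred"
        row = "\t".join(
            ["t1", "chr1", "+", "0", "300", "0", "0", "2", "0,100,200,", "50,150,250,"]
        )
        path.write_text(row + "\n")
        with pytest.raises(GenePredParseError, match="line 1"):
            read_genepred(path)

    def test_three_row_fixture_with_bin_column(self, tmp_path):
        rows = [
            "0\t" + _genepred_row("tA", "chr1", "+", [0, 100], [50, 160]),
            "1\t" + _genepred_row("tB", "chr1", "-", [0], [90]),
            "2\t" + _genepred_row("tC", "chr2", "+", [10], [40], cds=(10, 40)),
        ]
        path = tmp_path / "b.genePred"
        path.write_text("\n".join(rows) + "\n")
        models = read_genepred(path)
        assert [m.transcript_id for m in models] == ["tA", "tB", "tC"]
        assert not models[0].is_coding  # cdsStart == cdsEnd convention


class TestReadBed12:
    def _bed(self, name, thick=(0, 0), sizes=(50, 60), offsets=(0, 100)):
        start = 1000
        return "\t".join(
            [
                "chr3", str(start), str(start + offsets[-1] + sizes[-1]), name, "0", "+",
                str(thick[0]), str(thick[1]), "0", str(len(sizes)),
                ",".join(map(str, sizes)) + ",", ",".join(map(str, offsets)) + ",",
            ]
        )

    def test_two_blocks_give_mature_length_110(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text(self._bed("o1") + "\n")
        (m,) = read_toga_bed(path)
        assert len(m.exons) == 2
        assert m.mature_length == 110
        assert m.exons[0].start == 1000 and m.exons[1].start == 1100

    def test_thick_start_equals_end_is_noncoding(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text(self._bed("o1", thick=(1000, 1000)) + "\n")
        (m,) = read_toga_bed(path)
        assert not m.is_coding

    def test_four_record_fixture(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("\n".join(self._bed(f"o{i}") for i in range(4)) + "\n")
        assert len(read_toga_bed(path)) == 4

    def test_block_count_mismatch(self, tmp_path):
        path = tmp_path / "a.bed"
        bad = self._bed("o1").split("\t")
        bad[9] = "3"
        path.write_text("\t".join(bad) + "\n")
        with pytest.raises(GenePredParseError):
            read_toga_bed(path)


class TestExtraction:
    genome = {"chr1": "ATGCNNNNGGTA", "chr2": "ATGC"}

    def _model(self, exons, strand="+", cds=None, chrom="chr1"):
        return TranscriptModel(
            transcript_id="t", gene_id="g", gene_name="g", species="ref",
            exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
            cds_start=cds[0] if cds else None, cds_end=cds[1] if cds else None,
        )

    def test_plus_strand_concatenation_and_junction(self):
        rna = extract_mature_rna(self._model([(0, 4), (8, 12)]), self.genome)
        assert rna.sequence == "ATGCGGTA"
        assert rna.junction_positions == frozenset({4})

    def test_minus_strand_is_reverse_complement(self):
        rna = extract_mature_rna(self._model([(0, 4)], strand="-", chrom="chr2"), self.genome)
        assert rna.sequence == "GCAT"

    def test_minus_strand_multi_exon_property(self):
        exons = [(0, 4), (8, 12)]
        plus = extract_mature_rna(self._model(exons), self.genome)
        minus = extract_mature_rna(self._model(exons, strand="-"), self.genome)
        assert minus.sequence == reverse_complement(plus.sequence)

    def test_codon_start_positions(self):
        # CDS spans mature [2, 11): codon starts at 2, 5, 8
        genome = {"c": "AAATGGGGTAAGG"}
        rna = extract_mature_rna(self._model([(0, 13)], cds=(2, 11), chrom="c"), genome)
        assert rna.codon_start_positions == frozenset({2, 5, 8})
        assert (rna.utr5_len, rna.cds_len, rna.utr3_len) == (2, 9, 2)

    def test_out_of_bounds_exon(self):
        with pytest.raises(IndexError):
            extract_mature_rna(self._model([(0, 99)]), self.genome)

    def test_missing_chromosome(self):
        with pytest.raises(KeyError):
            extract_mature_rna(self._model([(0, 4)], chrom="chrX"), self.genome)


def _rna(seq, junctions=(), codon_starts=(), utr5=0, cds=0):
    return MatureRNA(
        transcript_id="t", sequence=seq,
        junction_positions=frozenset(junctions),
        codon_start_positions=frozenset(codon_starts),
        utr5_len=utr5, cds_len=cds, utr3_len=len(seq) - utr5 - cds,
    )


class TestSixTrack:
    def test_full_cds_codon_track(self):
        rna = _rna("ATGGCCTAA", codon_starts=(0, 3, 6), cds=9)
        enc = encode_six_track(rna)
        assert enc.matrix[:, 5].tolist() == [1, 0, 0, 1, 0, 0, 1, 0, 0]
        assert enc.matrix[:, 4].sum() == 0

    def test_n_has_no_nucleotide_channel(self):
        enc = encode_six_track(_rna("AANA"))
        assert enc.matrix[2, :4].sum() == 0
        assert enc.matrix[[0, 1, 3], :4].sum() == 3

    def test_junction_marks_first_base_of_downstream_exon(self):
        enc = encode_six_track(_rna("ATGCGGTA", junctions=(4,)))
        assert np.flatnonzero(enc.matrix[:, 4]).tolist() == [4]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode_six_track(_rna(""))

    def test_truncation_drops_three_prime_end(self):
        rna = _rna("ACGTACGTACGT", junctions=(4, 8))
        enc = encode_six_track(rna, max_len=6)
        assert len(enc) == 6
        assert decode_six_track(enc).sequence == "ACGTAC"

    def test_decode_rejects_double_nucleotide(self):
        enc = encode_six_track(_rna("ACGT"))
        enc.matrix[0, 1] = 1.0
        with pytest.raises(ValueError):
            decode_six_track(enc)

    def test_track_sums_conserved(self):
        rna = _rna("ACGTACGTACGTAC", junctions=(3, 9), codon_starts=(2, 5, 8), utr5=2, cds=9)
        enc = encode_six_track(rna)
        assert enc.matrix[:, 4].sum() == len(rna.junction_positions)
        assert enc.matrix[:, 5].sum() == rna.cds_len / 3


@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_encode_decode_round_trip(data):
    """decode(encode(x)) == x for any in-length transcript, including Ns."""
    L = data.draw(st.integers(1, 80))
    seq = "".join(data.draw(st.sampled_from("ACGTN")) for _ in range(L))
    junctions = data.draw(st.sets(st.integers(1, L - 1), max_size=4)) if L > 1 else set()
    utr5 = data.draw(st.integers(0, L))
    cds = data.draw(st.sampled_from(range(0, L - utr5 + 1, 3)))
    rna = _rna(seq, junctions=junctions,
               codon_starts={utr5 + 3 * k for k in range(cds // 3)}, utr5=utr5 if cds else 0,
               cds=cds)
    back = decode_six_track(encode_six_track(rna, max_len=128))
    assert back.sequence == rna.sequence
    assert back.junction_positions == rna.junction_positions
    assert back.codon_start_positions == rna.codon_start_positions
    assert (back.utr5_len, back.cds_len) == (rna.utr5_len, rna.cds_len)
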