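"""Augmentation-set construction, transforms, and positive-pair sampling."""

import numpy as np
import pytest

from rnaclr.pairs import (
    AugmentationSet,
    PairSampler,
    build_orthology_sets,
    build_splicing_sets,
    count_pairs,
    mask_augment,
    merge_naive_orthology,
    utr_combination_transform,
)
from rnaclr.transcripts import GenomicInterval, MatureRNA, TranscriptModel, encode_six_track


def _model(tid, gene, species="ref", name=None):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, gene_name=name or gene, species=species,
        exons=(GenomicInterval("chr1", 0, 30, "+"),),
    )


def _rna(tid, seq, utr5=0, cds=0, junctions=()):
    return MatureRNA(
        transcript_id=tid, sequence=seq,
        junction_positions=frozenset(junctions),
        codon_start_positions=frozenset(utr5 + 3 * k for k in range(cds // 3)),
        utr5_len=utr5 if cds else 0, cds_len=cds,
        utr3_len=len(seq) - (utr5 if cds else 0) - cds,
    )


class TestSetConstruction:
    def test_three_isoform_gene(self):
        sets = build_splicing_sets([_model(t, "g1") for t in ("t1", "t2", "t3")])
        assert {m for m, _ in sets["t1"].members} == {"t2", "t3"}
        assert all(src == "splicing" for _, src in sets["t1"].members)

    def test_single_isoform_gene_empty(self):
        sets = build_splicing_sets([_model("t1", "g1")])
        assert len(sets["t1"]) == 0

    def test_two_genes_two_isoforms_each(self):
        models = [_model("t1", "g1"), _model("t2", "g1"), _model("t3", "g2"), _model("t4", "g2")]
        sets = build_splicing_sets(models)
        assert all(len(s) == 1 for s in sets.values())

    def test_symmetric_closure(self):
        models = [_model(f"t{i}", f"g{i % 3}") for i in range(9)]
        sets = build_splicing_sets(models)
        for ref, s in sets.items():
            for member, src in s.members:
                assert (ref, src) in sets[member].members

    def test_orthology_addition_and_unknown_skip(self, caplog):
        sets = build_splicing_sets([_model("t1", "g1")])
        orth = [_model("o1", "g1", species="sp1"), _model("o2", "g1", species="sp2")]
        build_orthology_sets(sets, orth, {"t1": ["o1", "o2", "oMissing"]})
        assert {m for m, s in sets["t1"].members if s == "orthology"} == {"o1", "o2"}

    def test_empty_mapping_is_identity(self):
        sets = build_splicing_sets([_model("t1", "g1")])
        before = list(sets["t1"].members)
        build_orthology_sets(sets, [], {})
        assert sets["t1"].members == before

    def test_naive_orthology_pools_same_gene_name_across_species(self):
        human = [_model("h1", "g_h", name="TP53"), _model("h2", "g_h", name="TP53")]
        mouse = [_model("m1", "g_m", species="mouse", name="TP53")]
        other = [_model("x1", "g_x", species="mouse", name="tp53")]  # case differs
        sets = build_splicing_sets(human)
        merge_naive_orthology(sets, human + mouse + other)
        assert ("m1", "naive_orthology") in sets["h1"].members
        assert all(m != "x1" for m, _ in sets["h1"].members)


class TestUTRCombination:
    def test_definitional_chimera(self):
        iso = _rna("iso", "AACCCCCCCCCGG", utr5=2, cds=9)
        orth = _rna("orth", "ATGGGGTAA", cds=9)
        chim = utr_combination_transform(iso, orth)
        assert chim.sequence == "AAATGGGGTAAGG"
        assert chim.codon_start_positions == frozenset({2, 5, 8})

    def test_empty_utrs_yield_cds(self):
        iso = _rna("iso", "ATGTAA", cds=6)
        orth = _rna("orth", "ATGGGGTAA", cds=9)
        assert utr_combination_transform(iso, orth).sequence == orth.sequence

    def test_length_arithmetic(self):
        iso = _rna("iso", "A" * 7 + "C" * 9 + "G" * 4, utr5=7, cds=9)
        orth = _rna("orth", "T" * 9, cds=9)
        assert len(utr_combination_transform(iso, orth).sequence) == 20

    def test_noncoding_isoform_rejected(self):
        iso = _rna("iso", "ACGT")
        orth = _rna("orth", "ATGTAA", cds=6)
        with pytest.raises(ValueError):
            utr_combination_transform(iso, orth)

    def test_ortholog_junctions_shift(self):
        iso = _rna("iso", "AAACGTCGTTT", utr5=2, cds=6)
        orth = _rna("orth", "ATGTAA", cds=6, junctions=(3,))
        assert utr_combination_transform(iso, orth).junction_positions == frozenset({5})


class TestMaskAugment:
    def test_fraction_zero_identity(self):
        enc = encode_six_track(_rna("t", "ACGTACGT"))
        out = mask_augment(enc, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.matrix, enc.matrix)

    def test_fraction_one_zeroes_all_nucleotides(self):
        enc = encode_six_track(_rna("t", "ACGTACGT"))
        out = mask_augment(enc, 1.0, np.random.default_rng(0))
        assert out.matrix[:, :4].sum() == 0

    def test_exact_count_and_originals_untouched(self):
        enc = encode_six_track(_rna("t", "ACGT" * 25))
        out = mask_augment(enc, 0.30, np.random.default_rng(1))
        assert (out.matrix[:, :4].sum(axis=1) == 0).sum() == 30
        assert enc.matrix[:, :4].sum() == 100  # input not modified in place
        assert np.array_equal(out.matrix[:, 4:], enc.matrix[:, 4:])

    def test_bad_fraction(self):
        enc = encode_six_track(_rna("t", "ACGT"))
        with pytest.raises(ValueError):
            mask_augment(enc, 1.5)


class TestSampler:
    def _sampler(self, members, orthology_weight=0.8):
        rnas = {
            "ref": _rna("ref", "AAACGTCGTGGG", utr5=3, cds=6),
            "s1": _rna("s1", "AAACGTGGG", utr5=3, cds=3),
            "s2": _rna("s2", "CGTCGT", cds=6),
            "o1": _rna("o1", "TTTGGGTAA", cds=9),
        }
        aset = AugmentationSet("ref")
        for mid, src in members:
            aset.add(mid, src)
        return PairSampler(
            sets={"ref": aset}, mature=rnas.__getitem__, max_len=64,
            seed=3, orthology_weight=orthology_weight,
        )

    def test_deterministic_given_seed_epoch(self):
        s = self._sampler([("s1", "splicing"), ("s2", "splicing"), ("o1", "orthology")])
        p1 = s.sample("ref", epoch=4)
        p2 = s.sample("ref", epoch=4)
        assert p1.member_id == p2.member_id and p1.source == p2.source

    def test_epoch_resampling_varies(self):
        s = self._sampler([("s1", "splicing"), ("s2", "splicing")])
        members = {s.sample("ref", e).member_id for e in range(100)}
        assert members == {"s1", "s2"}

    def test_empty_set_falls_back_to_masking(self):
        s = self._sampler([])
        p = s.sample("ref", epoch=0)
        assert p.source == "masking" and p.weight == 1.0
        assert p.x2.matrix[:, :4].sum() < p.x1.matrix[:, :4].sum()

    def test_orthology_weight_and_chimera(self):
        s = self._sampler([("o1", "orthology")])
        p = s.sample("ref", epoch=0)
        assert p.weight == 0.8
        # chimera = ref UTRs around the ortholog CDS: 3 + 9 + 3 bases
        assert len(p.x2) == 15

    def test_weight_rule_over_many_draws(self):
        s = self._sampler([("s1", "splicing"), ("s2", "splicing"), ("o1", "orthology")])
        for e in range(500):
            p = s.sample("ref", e)
            assert p.weight == (0.8 if p.source == "orthology" else 1.0)

    def test_uniform_draw_frequencies(self):
        """Monte-Carlo: each of 3 members drawn with frequency 1/3 ± 0.03."""
        s = self._sampler([("s1", "splicing"), ("s2", "splicing"), ("o1", "orthology")])
        draws = [s.sample("ref", e).member_id for e in range(3000)]
        for m in ("s1", "s2", "o1"):
            assert abs(draws.count(m) / 3000 - 1 / 3) < 0.03


class TestCountPairs:
    def test_three_isoforms_make_six_ordered_pairs(self):
        sets = build_splicing_sets([_model(t, "g") for t in ("t1", "t2", "t3")])
        stats = count_pairs(sets)
        assert stats.n_pairs == 6
        assert stats.per_source["splicing"] == 6

    def test_no_augmentations_zero_pairs(self):
        sets = {f"t{i}": AugmentationSet(f"t{i}") for i in range(5)}
        assert count_pairs(sets).n_pairs == 0

    def test_mixed_fixture_hand_count(self):
        models = [_model(t, "g1") for t in ("t1", "t2")] + [_model(t, "g2") for t in ("t3", "t4")]
        sets = build_splicing_sets(models)
        orth = [_model("o1", "g1", species="sp1"), _model("o2", "g1", species="sp2")]
        build_orthology_sets(sets, orth, {"t1": ["o1", "o2"], "t3": ["o1"]})
        stats = count_pairs(sets)
        # splicing: 2 per gene x 2 genes; orthology: 2 + 1
        assert stats.per_source == {"splicing": 4, "orthology": 3, "naive_orthology": 0}
        assert stats.n_pairs == 7
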