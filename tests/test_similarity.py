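"""Similarity scores, Jaccard metrics, pair sampling, clustering, exon deltas."""

import math

import numpy as np
import pytest

from rnaclr.simulate import SimulationConfig, simulate_corpus
from rnaclr.similarity import (
    PairComparison,
    cluster_isoforms,
    delete_exon,
    embedding_similarity,
    exon_deletion_delta,
    interval_jaccard,
    jaccard,
    linkage_to_newick,
    sample_pair_groups,
    similarity_report,
)
from rnaclr.ssm import SSMConfig, SSMEncoder
from rnaclr.transcripts import GenomicInterval, TranscriptModel


class TestEmbeddingSimilarity:
    def test_forced_values(self):
        e = np.zeros(4)
        assert embedding_similarity(e, np.array([1.0, 0, 0, 0])) == pytest.approx(1.0)
        assert embedding_similarity(e, np.array([math.e, 0, 0, 0])) == pytest.approx(0.0)

    def test_identical_vectors_hit_epsilon_floor(self):
        e = np.ones(3)
        assert embedding_similarity(e, e) == pytest.approx(1.0 - math.log(1e-8))

    def test_symmetry_and_monotonicity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert embedding_similarity(a, b) == embedding_similarity(b, a)
        sims = [
            embedding_similarity(np.zeros(2), np.array([d, 0.0]))
            for d in (0.5, 1.0, 2.0, 4.0)
        ]
        assert sims == sorted(sims, reverse=True)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            embedding_similarity(np.zeros(3), np.zeros(4))


class TestJaccard:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [
            ({"A", "B"}, {"B", "C"}, 1 / 3),
            ({"A"}, {"A"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            (set(), set(), 1.0),
            (set(), {"A"}, 0.0),
        ],
    )
    def test_set_jaccard(self, d1, d2, expected):
        assert jaccard(d1, d2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([(0, 100)], [(50, 150)], 1 / 3),
            ([(0, 10), (20, 30)], [(0, 10), (20, 30)], 1.0),
            # intersection [5,10) + [20,25) = 10 bp; union [0,30) = 30 bp
            ([(0, 10), (20, 30)], [(5, 25)], 1 / 3),
        ],
    )
    def test_interval_jaccard(self, a, b, expected):
        assert interval_jaccard(a, b) == pytest.approx(expected)

    def test_split_invariance(self):
        whole = [(0, 60)]
        split = [(0, 20), (20, 45), (45, 60)]
        other = [(30, 90)]
        assert interval_jaccard(whole, other) == interval_jaccard(split, other)

    def test_different_chromosomes_are_zero(self):
        a = [GenomicInterval("chr1", 0, 10, "+")]
        b = [GenomicInterval("chr2", 0, 10, "+")]
        assert interval_jaccard(a, b) == 0.0


@pytest.fixture(scope="module")
def small_corpus():
    return simulate_corpus(SimulationConfig(n_families=20, seed=6))


class TestPairGroups:
    def test_counts_and_exclusions(self, small_corpus):
        pairs = sample_pair_groups(small_corpus, 10, 30, 10, 3, seed=0)
        groups = {g: [p for p in pairs if p.group == g] for g in ("intragene", "intergene", "same_class")}
        assert groups["intragene"] and groups["intergene"] and groups["same_class"]
        for p in groups["intragene"]:
            g1 = small_corpus.model(p.id1).gene_id
            g2 = small_corpus.model(p.id2).gene_id
            assert g1 == g2
        for p in groups["intergene"] + groups["same_class"]:
            f1 = small_corpus.family_of_transcript(p.id1)
            f2 = small_corpus.family_of_transcript(p.id2)
            assert f1 != f2
        for p in groups["same_class"]:
            c1 = small_corpus.functional_class[small_corpus.model(p.id1).gene_id]
            c2 = small_corpus.functional_class[small_corpus.model(p.id2).gene_id]
            assert c1 == c2

    def test_intragene_pair_count_is_choose_two(self, small_corpus):
        pairs = sample_pair_groups(small_corpus, 1000, 0, 0, 0, seed=1)
        by_gene = {}
        for p in pairs:
            by_gene.setdefault(small_corpus.model(p.id1).gene_id, []).append(p)
        for g, ps in by_gene.items():
            k = sum(
                1 for m in small_corpus.reference_models() if m.gene_id == g
            )
            assert len(ps) == k * (k - 1) // 2

    def test_seeded_determinism(self, small_corpus):
        p1 = sample_pair_groups(small_corpus, 5, 20, 5, 2, seed=9)
        p2 = sample_pair_groups(small_corpus, 5, 20, 5, 2, seed=9)
        assert [(p.id1, p.id2, p.group) for p in p1] == [(p.id1, p.id2, p.group) for p in p2]


class TestReport:
    def test_identical_group_distributions_are_not_separated(self):
        rng = np.random.default_rng(3)
        emb = {f"t{i}": rng.normal(size=8) for i in range(60)}
        pairs = []
        ids = list(emb)
        for i in range(0, 40, 2):
            pairs.append(PairComparison(ids[i], ids[i + 1], "intragene"))
            pairs.append(PairComparison(ids[i + 20], ids[i + 21], "intergene"))
        _, stats = similarity_report(pairs, emb)
        assert stats["mannwhitney_p"]["intragene_vs_intergene"] > 0.05

    def test_missing_embeddings_dropped(self):
        emb = {"a": np.zeros(3), "b": np.ones(3)}
        pairs = [
            PairComparison("a", "b", "intragene"),
            PairComparison("a", "missing", "intragene"),
        ]
        filled, _ = similarity_report(pairs, emb)
        assert len(filled) == 1


class TestClustering:
    def test_identical_pair_merges_first(self):
        emb = {"a": np.zeros(4), "b": np.zeros(4), "c": np.full(4, 10.0)}
        Z, order, norm = cluster_isoforms(emb)
        first = sorted(Z[0, :2].astype(int))
        assert first == [0, 1]  # ids "a", "b"
        assert set(order) == set(emb)

    def test_normalized_diagonal_is_max(self):
        rng = np.random.default_rng(1)
        emb = {f"t{i}": rng.normal(size=6) for i in range(5)}
        _, _, norm = cluster_isoforms(emb)
        assert np.allclose(np.diag(norm), 1.0)
        assert norm.min() >= 0.0 and norm.max() <= 1.0

    def test_two_module_gene_recovers_clusters(self):
        rng = np.random.default_rng(2)
        base1, base2 = rng.normal(size=8), rng.normal(size=8) + 10
        emb = {f"m1_{i}": base1 + 0.01 * rng.normal(size=8) for i in range(3)}
        emb |= {f"m2_{i}": base2 + 0.01 * rng.normal(size=8) for i in range(3)}
        from scipy.cluster import hierarchy

        Z, order, _ = cluster_isoforms(emb)
        cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        ids = sorted(emb)
        modules = {}
        for tid, c in zip(ids, cut):
            modules.setdefault(c, set()).add(tid.split("_")[0])
        assert all(len(v) == 1 for v in modules.values())

    def test_single_isoform_rejected(self):
        with pytest.raises(ValueError):
            cluster_isoforms({"a": np.zeros(3)})

    def test_newick_serialization_parses(self):
        emb = {f"t{i}": np.random.default_rng(i).normal(size=4) for i in range(4)}
        Z, _, _ = cluster_isoforms(emb)
        nwk = linkage_to_newick(Z, sorted(emb))
        assert nwk.endswith(";") and nwk.count("(") == 3
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert {t.name for t in tree.get_terminals()} == set(emb)


class TestExonDeletion:
    @pytest.fixture()
    def encoder(self):
        return SSMEncoder(SSMConfig(d_model=16, d_state=4, n_layers=1, max_len=256))

    def test_noop_guard_is_zero(self, small_corpus, encoder):
        tid = small_corpus.canonical["G0000"]
        m = small_corpus.model(tid)
        res = exon_deletion_delta(m, None, small_corpus.genomes["ref"], encoder)
        assert res.delta == 0.0

    def test_any_deletion_is_nonnegative_and_changes_length(self, small_corpus, encoder):
        tid = small_corpus.canonical["G0001"]
        m = small_corpus.model(tid)
        res = exon_deletion_delta(m, 1, small_corpus.genomes["ref"], encoder)
        assert res.delta >= 0.0
        rna, _ = delete_exon(m, 1, small_corpus.genomes["ref"])
        assert len(rna.sequence) == m.mature_length - len(m.exons[1])

    def test_frame_flag_and_cds_consistency(self, small_corpus):
        genome = small_corpus.genomes["ref"]
        for gene in list(small_corpus.canonical)[:10]:
            m = small_corpus.model(small_corpus.canonical[gene])
            for i in range(1, len(m.exons) - 1):
                rna, frame_broken = delete_exon(m, i, genome)
                assert rna.cds_len % 3 == 0
                # internal exons are multiples of 3 in this corpus
                assert not frame_broken

    def test_single_exon_rejected(self):
        m = TranscriptModel(
            "t", "g", "g", "ref", (GenomicInterval("c", 0, 30, "+"),)
        )
        with pytest.raises(ValueError):
            delete_exon(m, 0, {"c": "A" * 30})
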