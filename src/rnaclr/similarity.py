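"""Embedding-based isoform functional-similarity analytics.

Embedding similarity between two transcripts is scored as ``1 − ln(L2
distance)`` (natural log; distances are floored at 1e-8 so identical
embeddings get a finite score) — higher means closer in latent space.
Annotation agreement is scored with Jaccard indices: over protein-domain
sets, over genomic base-pair interval sets (full exons, or exons restricted
to the CDS), with the convention that two empty sets are identical (J = 1).

Pair groups mirror the standard three-way comparison: transcript pairs within
a gene (intragene), canonical transcripts of non-homologous gene pairs
(intergene), and non-homologous gene pairs sharing a functional class
(same-class).  Group differences are tested with two-sided Mann-Whitney U.

Exon-deletion deltas measure how much a transcript's embedding moves when one
exon is removed — a proxy for the functional importance of that exon.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .transcripts import (
    GenomicInterval,
    MatureRNA,
    TranscriptModel,
    encode_six_track,
)

__all__ = [
    "PairComparison",
    "embedding_similarity",
    "jaccard",
    "interval_jaccard",
    "sample_pair_groups",
    "similarity_report",
    "cluster_isoforms",
    "exon_deletion_delta",
    "delete_exon",
    "ExonDeletionResult",
]

logger = logging.getLogger(__name__)

DISTANCE_FLOOR = 1e-8

GROUPS = ("intragene", "intergene", "same_class")


@dataclasses.dataclass
class PairComparison:
    id1: str
    id2: str
    group: str
    embedding_sim: float | None = None
    domain_jaccard: float | None = None
    cds_jaccard: float | None = None
    sequence_jaccard: float | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown pair group {self.group!r}")


# ---------------------------------------------------------------------------
# elementary scores
# ---------------------------------------------------------------------------

def embedding_similarity(e1: np.ndarray, e2: np.ndarray) -> float:
    """``1 − ln(max(‖e1 − e2‖₂, 1e-8))``; strictly decreasing in distance."""
    e1 = np.asarray(e1, float)
    e2 = np.asarray(e2, float)
    if e1.shape != e2.shape:
        raise ValueError(f"dimension mismatch: {e1.shape} vs {e2.shape}")
    d = float(np.linalg.norm(e1 - e2))
    return 1.0 - float(np.log(max(d, DISTANCE_FLOOR)))


def jaccard(d1: set, d2: set) -> float:
    """|D1∩D2| / |D1∪D2|; two empty sets count as identical (1)."""
    if not d1 and not d2:
        return 1.0
    return len(set(d1) & set(d2)) / len(set(d1) | set(d2))


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def interval_jaccard(
    ivs1: Sequence[GenomicInterval | tuple[int, int]],
    ivs2: Sequence[GenomicInterval | tuple[int, int]],
) -> float:
    """Base-pair Jaccard of two genomic interval sets."""

    def _norm(ivs):
        chroms = set()
        spans = []
        for iv in ivs:
            if isinstance(iv, GenomicInterval):
                chroms.add(iv.chrom)
                spans.append((iv.start, iv.end))
            else:
                spans.append((int(iv[0]), int(iv[1])))
        return chroms, _merge(spans)

    c1, m1 = _norm(ivs1)
    c2, m2 = _norm(ivs2)
    if c1 and c2 and c1.isdisjoint(c2):
        logger.warning("interval Jaccard across different chromosomes is 0")
        return 0.0
    inter = 0
    for s1, e1 in m1:
        for s2, e2 in m2:
            inter += max(0, min(e1, e2) - max(s1, s2))
    union = sum(e - s for s, e in m1) + sum(e - s for s, e in m2) - inter
    return inter / union if union else 1.0


# ---------------------------------------------------------------------------
# pair-group sampling
# ---------------------------------------------------------------------------

def sample_pair_groups(
    corpus,
    n_intragene_genes: int = 1000,
    n_intergene: int = 1000,
    n_class_terms: int = 5000,
    pairs_per_term: int = 5,
    seed: int = 0,
) -> list[PairComparison]:
    """Sample intragene / intergene / same-class transcript pairs from a corpus.

    ``corpus`` needs gene families, canonical transcripts and functional
    classes (a :class:`rnaclr.simulate.SyntheticCorpus`).  Requested counts
    scale down to what the corpus supports.  Non-homologous means different
    family ids; intergene and same-class pairs use canonical transcripts.
    """
    rng = np.random.default_rng(seed)
    ref = corpus.reference_models()
    by_gene: dict[str, list[str]] = {}
    for m in ref:
        by_gene.setdefault(m.gene_id, []).append(m.transcript_id)
    genes = sorted(by_gene)
    pairs: list[PairComparison] = []

    multi = [g for g in genes if len(by_gene[g]) >= 2]
    chosen = rng.choice(multi, size=min(n_intragene_genes, len(multi)), replace=False)
    for g in chosen:
        for a, b in itertools.combinations(sorted(by_gene[g]), 2):
            pairs.append(PairComparison(a, b, "intragene"))

    n_inter = min(n_intergene, len(genes) * (len(genes) - 1) // 2)
    seen: set[tuple[str, str]] = set()
    attempts = 0
    while len(seen) < n_inter and attempts < 50 * n_inter:
        attempts += 1
        g1, g2 = rng.choice(genes, size=2, replace=False)
        if corpus.family_of_gene[g1] == corpus.family_of_gene[g2]:
            continue  # homologous genes are excluded from the intergene group
        key = tuple(sorted((g1, g2)))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            PairComparison(corpus.canonical[key[0]], corpus.canonical[key[1]], "intergene")
        )

    classes: dict[int, list[str]] = {}
    for g in genes:
        classes.setdefault(corpus.functional_class[g], []).append(g)
    usable = [c for c, gs in sorted(classes.items()) if len(gs) >= 2]
    if not usable:
        logger.warning("corpus has no multi-gene functional classes; same-class group skipped")
    for c in usable[: min(n_class_terms, len(usable))]:
        gs = classes[c]
        for _ in range(pairs_per_term):
            g1, g2 = rng.choice(gs, size=2, replace=False)
            if corpus.family_of_gene[g1] == corpus.family_of_gene[g2]:
                continue
            pairs.append(
                PairComparison(corpus.canonical[g1], corpus.canonical[g2], "same_class")
            )
    return pairs


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _cds_intervals(m: TranscriptModel) -> list[tuple[int, int]]:
    if not m.is_coding:
        return []
    out = []
    for e in m.exons:
        lo, hi = max(e.start, m.cds_start), min(e.end, m.cds_end)
        if hi > lo:
            out.append((lo, hi))
    return out


def similarity_report(
    pairs: Sequence[PairComparison],
    embeddings: Mapping[str, np.ndarray],
    domains: Mapping[str, frozenset] | None = None,
    models: Mapping[str, TranscriptModel] | None = None,
) -> tuple[list[PairComparison], dict]:
    """Fill pair scores and compute group statistics.

    Returns the filled pairs (pairs with missing embeddings are dropped and
    logged) and a statistics dict with per-group medians, pairwise two-sided
    Mann-Whitney U p-values on embedding similarity, and — for intragene
    pairs grouped per gene — median per-gene Pearson/Spearman correlations of
    domain overlap against embedding similarity and against two baselines
    (transcript-length similarity and genomic sequence overlap).
    """
    filled: list[PairComparison] = []
    for p in pairs:
        if p.id1 not in embeddings or p.id2 not in embeddings:
            logger.warning("missing embedding for pair (%s, %s); dropped", p.id1, p.id2)
            continue
        p = dataclasses.replace(p)
        p.embedding_sim = embedding_similarity(embeddings[p.id1], embeddings[p.id2])
        if domains is not None:
            p.domain_jaccard = jaccard(set(domains.get(p.id1, ())), set(domains.get(p.id2, ())))
        if models is not None and p.id1 in models and p.id2 in models:
            m1, m2 = models[p.id1], models[p.id2]
            if m1.chrom != m2.chrom:
                # different chromosomes cannot overlap; expected for intergene
                p.sequence_jaccard = 0.0
                p.cds_jaccard = 0.0
            else:
                p.sequence_jaccard = interval_jaccard(m1.exons, m2.exons)
                p.cds_jaccard = interval_jaccard(_cds_intervals(m1), _cds_intervals(m2))
        filled.append(p)

    by_group: dict[str, list[float]] = {g: [] for g in GROUPS}
    for p in filled:
        by_group[p.group].append(p.embedding_sim)
    stats_out: dict = {
        "group_median": {g: (float(np.median(v)) if v else None) for g, v in by_group.items()},
        "group_n": {g: len(v) for g, v in by_group.items()},
        "mannwhitney_p": {},
    }
    for g1, g2 in itertools.combinations(GROUPS, 2):
        a, b = by_group[g1], by_group[g2]
        if len(a) >= 2 and len(b) >= 2:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            stats_out["mannwhitney_p"][f"{g1}_vs_{g2}"] = float(p)

    if models is not None and domains is not None:
        per_gene: dict[str, list[PairComparison]] = {}
        for p in filled:
            if p.group != "intragene":
                continue
            per_gene.setdefault(models[p.id1].gene_id, []).append(p)
        cors = {"domain_vs_embedding": [], "domain_vs_length": [], "domain_vs_sequence": []}
        cors_sp = {"domain_vs_embedding": []}
        for gene, ps in per_gene.items():
            if len(ps) < 3:
                continue
            sd = np.array([p.domain_jaccard for p in ps])
            so = np.array([p.embedding_sim for p in ps])
            seqj = np.array([p.sequence_jaccard for p in ps])
            lens = np.array(
                [
                    min(models[p.id1].mature_length, models[p.id2].mature_length)
                    / max(models[p.id1].mature_length, models[p.id2].mature_length)
                    for p in ps
                ]
            )
            if np.std(sd) < 1e-12:
                continue
            for key, other in (
                ("domain_vs_embedding", so),
                ("domain_vs_length", lens),
                ("domain_vs_sequence", seqj),
            ):
                if np.std(other) > 1e-12:
                    cors[key].append(float(stats.pearsonr(sd, other).statistic))
            if np.std(so) > 1e-12:
                cors_sp["domain_vs_embedding"].append(
                    float(stats.spearmanr(sd, so).statistic)
                )
        stats_out["per_gene_pearson_median"] = {
            k: (float(np.median(v)) if v else None) for k, v in cors.items()
        }
        stats_out["per_gene_spearman_median"] = {
            k: (float(np.median(v)) if v else None) for k, v in cors_sp.items()
        }
    return filled, stats_out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_isoforms(
    embeddings: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Hierarchically cluster one gene's isoforms by embedding similarity.

    Returns (average-linkage matrix, leaf-order ids, per-gene min-max
    normalized similarity matrix).  Distances are ``max(sim) − sim``.
    """
    ids = sorted(embeddings)
    if len(ids) < 2:
        raise ValueError("clustering needs at least 2 isoforms")
    k = len(ids)
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = (
                embedding_similarity(embeddings[ids[i]], embeddings[ids[j]])
                if i != j
                else np.nan
            )
    off = sim[~np.isnan(sim)]
    lo, hi = off.min(), off.max()
    norm = (sim - lo) / (hi - lo) if hi > lo else np.ones_like(sim)
    np.fill_diagonal(norm, 1.0)  # diagonal = maximal similarity
    dist = 1.0 - norm
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [ids[i] for i in hierarchy.leaves_list(Z)]
    return Z, order, norm


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a newick tree string."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_dist):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_dist - node.dist:.6f}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{parent_dist - node.dist:.6f}"

    return build(tree, tree.dist).rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# exon deletion
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ExonDeletionResult:
    delta: float
    frame_broken: bool
    deleted_exon: int | None


def delete_exon(model: TranscriptModel, exon_index: int, genome) -> tuple[MatureRNA, bool]:
    """Re-splice a transcript without one exon, recomputing CDS annotation.

    If the deleted exon removes a non-multiple-of-3 stretch of CDS, the
    reading frame downstream is broken; the CDS is then truncated to the last
    complete codon and the deletion is flagged.
    """
    if len(model.exons) < 2:
        raise ValueError("cannot delete the only exon of a transcript")
    if not 0 <= exon_index < len(model.exons):
        raise ValueError(f"exon index {exon_index} out of range")
    kept = tuple(e for i, e in enumerate(model.exons) if i != exon_index)
    removed = model.exons[exon_index]
    frame_broken = False
    cds_start, cds_end = model.cds_start, model.cds_end
    if model.is_coding:
        lost = max(0, min(removed.end, cds_end) - max(removed.start, cds_start))
        frame_broken = lost % 3 != 0
        cds_in_kept = sum(
            max(0, min(e.end, cds_end) - max(e.start, cds_start)) for e in kept
        )
        if cds_in_kept == 0:
            cds_start = cds_end = None
    new_model = dataclasses.replace(
        model,
        transcript_id=f"{model.transcript_id}~del{exon_index}",
        exons=kept,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    from .transcripts import extract_mature_rna

    if frame_broken:
        return extract_frame_tolerant(new_model, genome), True
    return extract_mature_rna(new_model, genome), False


def extract_frame_tolerant(model: TranscriptModel, genome) -> MatureRNA:
    """Mature RNA extraction that truncates a frame-broken CDS to whole codons."""
    from .transcripts import extract_mature_rna

    nc = dataclasses.replace(model, cds_start=None, cds_end=None)
    rna = extract_mature_rna(nc, genome)
    # recompute utr5/cds lengths directly from genomic overlap
    utr5 = 0
    cds = 0
    minus = model.strand == "-"
    for e in model.exons:
        cds += max(0, min(e.end, model.cds_end) - max(e.start, model.cds_start))
        if minus:
            utr5 += max(0, e.end - max(e.start, model.cds_end))
        else:
            utr5 += max(0, min(e.end, model.cds_start) - e.start)
    cds -= cds % 3
    return MatureRNA(
        transcript_id=model.transcript_id,
        sequence=rna.sequence,
        junction_positions=rna.junction_positions,
        codon_start_positions=frozenset(utr5 + 3 * k for k in range(cds // 3)),
        utr5_len=utr5,
        cds_len=cds,
        utr3_len=len(rna.sequence) - utr5 - cds,
    )


def exon_deletion_delta(
    model: TranscriptModel,
    exon_index: int | None,
    genome,
    encoder,
    max_len: int | None = None,
) -> ExonDeletionResult:
    """L2 distance between a transcript's embedding and the embedding after
    deleting one exon; ``exon_index=None`` is the no-op guard (delta 0)."""
    from .transcripts import extract_mature_rna

    max_len = max_len if max_len is not None else encoder.config.max_len
    base = encoder.encode(encode_six_track(extract_mature_rna(model, genome), max_len)).embedding
    if exon_index is None:
        return ExonDeletionResult(0.0, False, None)
    rna, frame_broken = delete_exon(model, exon_index, genome)
    mutant = encoder.encode(encode_six_track(rna, max_len)).embedding
    return ExonDeletionResult(float(np.linalg.norm(base - mutant)), frame_broken, exon_index)
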