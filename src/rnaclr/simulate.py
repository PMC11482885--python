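"""Synthetic gene-family corpora with the structure contrastive pre-training assumes.

The generator emulates, at desk scale, the statistical structure of a
splicing + orthology pre-training corpus:

* **gene families** — each family is one ancestral gene laid out on its own
  chromosome with real intron/exon structure, a 5'UTR, a frame-consistent CDS
  and a 3'UTR.  Internal exon lengths are multiples of three, so any subset of
  internal exons preserves reading frame.
* **splice isoforms** — exon subsets that always retain both terminal exons
  (and hence the UTRs and CDS ends).
* **orthologs** — CDS-only transcripts (mirroring ortholog projections that
  lack UTR annotation) derived from the canonical isoform by per-site
  substitution.  Positions inside planted motifs are left untouched: conserved
  functional segments embedded in neutral sequence are exactly the signal a
  contrastive objective is meant to find.
* **planted label motifs** — 6-mers written into the 3'UTR whose counts
  linearly determine a continuous property label
  ``y = sum_m beta_m * count_m + gamma * ln(cds_len) + eps``.
* **functional classes** — families sharing a conserved, domain-like sequence
  block planted in internal-exon CDS (GO-sharing genes share domain-scale
  sequence); these support GO-term-like same-class pair sampling, and the
  exons carrying them double as protein-domain-bearing, functionally
  important exons for exon-deletion analyses.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import math
import os
from typing import Iterable

import numpy as np

from .transcripts import (
    GenomicInterval,
    MatureRNA,
    TranscriptModel,
    extract_mature_rna,
    reverse_complement,
)

__all__ = ["SimulationConfig", "SyntheticCorpus", "simulate_corpus", "corpus_to_probe_task"]

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic corpus; defaults give the standard study corpus."""

    n_families: int = 200
    isoforms_per_gene: tuple[int, int] = (2, 4)  # inclusive range
    n_ortholog_species: int = 2
    exons_per_gene: tuple[int, int] = (4, 7)
    internal_exon_len: tuple[int, int] = (21, 60)  # rounded to multiples of 3
    utr5_len: tuple[int, int] = (10, 30)
    utr3_len: tuple[int, int] = (70, 120)
    terminal_cds_len: tuple[int, int] = (12, 60)  # multiples of 3
    intron_len: tuple[int, int] = (50, 150)
    substitution_rate: float = 0.1
    motif_library: tuple[str, ...] = ("TGTAAA", "CCTGCC", "AATAAA", "GCGCGC", "TTTGTT")
    motif_betas: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    motif_max_count: int = 2
    gamma_cds_len: float = 0.5
    label_noise_sd: float = 0.5
    n_functional_classes: int = 10
    class_block_len: int = 45  # domain-like conserved module shared within a class
    class_motif_copies: int = 2
    minus_strand_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if len(self.motif_library) != len(self.motif_betas):
            raise ValueError("motif_library and motif_betas must align")
        for lo, hi in (self.isoforms_per_gene, self.exons_per_gene):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty")
        if self.exons_per_gene[0] < 4:
            raise ValueError("genes need at least 4 exons (2 internal) for isoform structure")


@dataclasses.dataclass
class SyntheticCorpus:
    config: SimulationConfig
    genomes: dict[str, dict[str, str]]  # species -> chrom -> sequence
    models: list[TranscriptModel]  # all species
    family_of_gene: dict[str, int]
    functional_class: dict[str, int]  # gene_id -> class
    canonical: dict[str, str]  # gene_id -> transcript_id
    domains: dict[str, frozenset[str]]  # transcript_id -> domain ids
    labels: dict[str, float]  # reference transcripts only
    ortholog_map: dict[str, tuple[str, ...]]  # reference tid -> ortholog tids
    motif_exons: dict[str, tuple[bool, ...]]  # tid -> per-exon class-motif flag

    _mature_cache: dict[str, MatureRNA] = dataclasses.field(default_factory=dict, repr=False)

    # -- convenience accessors -------------------------------------------
    def reference_models(self) -> list[TranscriptModel]:
        return [m for m in self.models if m.species == "ref"]

    def model(self, transcript_id: str) -> TranscriptModel:
        if not hasattr(self, "_by_id"):
            self._by_id = {m.transcript_id: m for m in self.models}
        return self._by_id[transcript_id]

    def mature(self, transcript_id: str) -> MatureRNA:
        if transcript_id not in self._mature_cache:
            m = self.model(transcript_id)
            self._mature_cache[transcript_id] = extract_mature_rna(
                m, self.genomes[m.species]
            )
        return self._mature_cache[transcript_id]

    def family_of_transcript(self, transcript_id: str) -> int:
        return self.family_of_gene[self.model(transcript_id).gene_id]

    # -- serialization ----------------------------------------------------
    def write(self, outdir: str) -> None:
        """Write the corpus in standard formats (genePred, BED12, FASTA, TSV)."""
        os.makedirs(outdir, exist_ok=True)
        ref = [m for m in self.models if m.species == "ref"]
        with open(os.path.join(outdir, "ref.genePred"), "w") as fh:
            for m in ref:
                starts = ",".join(str(e.start) for e in m.exons) + ","
                ends = ",".join(str(e.end) for e in m.exons) + ","
                cs = m.cds_start if m.is_coding else m.exons[-1].end
                ce = m.cds_end if m.is_coding else m.exons[-1].end
                fh.write(
                    "\t".join(
                        [
                            m.transcript_id, m.chrom, m.strand,
                            str(m.exons[0].start), str(m.exons[-1].end),
                            str(cs), str(ce), str(len(m.exons)), starts, ends,
                            "0", m.gene_id,
                        ]
                    )
                    + "\n"
                )
        for species, chroms in self.genomes.items():
            with open(os.path.join(outdir, f"{species}.fa"), "w") as fh:
                for chrom, seq in chroms.items():
                    fh.write(f">{chrom}\n")
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")
        for species in sorted({m.species for m in self.models} - {"ref"}):
            with open(os.path.join(outdir, f"{species}.bed"), "w") as fh:
                for m in self.models:
                    if m.species != species:
                        continue
                    start = m.exons[0].start
                    sizes = ",".join(str(len(e)) for e in m.exons) + ","
                    offs = ",".join(str(e.start - start) for e in m.exons) + ","
                    fh.write(
                        "\t".join(
                            [
                                m.chrom, str(start), str(m.exons[-1].end),
                                m.transcript_id, "0", m.strand,
                                str(m.cds_start), str(m.cds_end),
                                "0", str(len(m.exons)), sizes, offs,
                            ]
                        )
                        + "\n"
                    )
        with open(os.path.join(outdir, "labels.tsv"), "w") as fh:
            fh.write("transcript_id\ty\tfunctional_class\tfamily\n")
            for m in ref:
                fh.write(
                    f"{m.transcript_id}\t{self.labels[m.transcript_id]:.6f}\t"
                    f"{self.functional_class[m.gene_id]}\t{self.family_of_gene[m.gene_id]}\n"
                )
        with open(os.path.join(outdir, "domains.tsv"), "w") as fh:
            fh.write("transcript_id\tdomains\n")
            for m in ref:
                doms = ";".join(sorted(self.domains.get(m.transcript_id, ())))
                fh.write(f"{m.transcript_id}\t{doms}\n")
        with open(os.path.join(outdir, "ortholog_map.tsv"), "w") as fh:
            fh.write("reference_id\tortholog_id\n")
            for tid, orths in self.ortholog_map.items():
                for o in orths:
                    fh.write(f"{tid}\t{o}\n")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _rand_mult3(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Uniform multiple of 3 in [lo, hi]."""
    lo3 = (lo + 2) // 3
    hi3 = hi // 3
    return 3 * int(rng.integers(lo3, hi3 + 1))


def _plant(seq: list[str], motif: str, pos: int) -> None:
    seq[pos : pos + len(motif)] = list(motif)


def simulate_corpus(cfg: SimulationConfig) -> SyntheticCorpus:
    """Generate a deterministic corpus of gene families with isoforms and orthologs."""
    rng = np.random.default_rng(cfg.seed)

    n_motifs = len(cfg.motif_library)
    class_blocks = [_rand_seq(rng, cfg.class_block_len) for _ in range(cfg.n_functional_classes)]
    family_class = rng.integers(0, cfg.n_functional_classes, size=cfg.n_families)

    genomes: dict[str, dict[str, str]] = {"ref": {}}
    for s in range(cfg.n_ortholog_species):
        genomes[f"sp{s + 1}"] = {}
    models: list[TranscriptModel] = []
    family_of_gene: dict[str, int] = {}
    functional_class: dict[str, int] = {}
    canonical: dict[str, str] = {}
    domains: dict[str, frozenset[str]] = {}
    labels: dict[str, float] = {}
    ortholog_map: dict[str, tuple[str, ...]] = {}
    motif_exons: dict[str, tuple[bool, ...]] = {}

    for fam in range(cfg.n_families):
        gene_id = f"G{fam:04d}"
        fam_class = int(family_class[fam])
        family_of_gene[gene_id] = fam
        functional_class[gene_id] = fam_class

        # ---- ancestral exon contents (mature order) ---------------------
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        n_internal = n_exons - 2
        utr5 = int(rng.integers(*cfg.utr5_len))
        utr3 = int(rng.integers(*cfg.utr3_len))
        first_cds = _rand_mult3(rng, *cfg.terminal_cds_len)
        last_cds = _rand_mult3(rng, *cfg.terminal_cds_len)
        internal_lens = [
            _rand_mult3(rng, *cfg.internal_exon_len) for _ in range(n_internal)
        ]
        exon_contents = [list(_rand_seq(rng, utr5 + first_cds))]
        exon_contents += [list(_rand_seq(rng, L)) for L in internal_lens]
        exon_contents.append(list(_rand_seq(rng, last_cds + utr3)))

        # ---- plant the functional-class motif in internal exons ---------
        if cfg.class_motif_copies <= 0:
            n_copies = 0  # motif planting disabled
        else:
            # always leave at least one neutral internal exon
            n_copies = max(1, min(cfg.class_motif_copies, n_internal - 1))
        motif_exon_idx = set(
            int(i) + 1 for i in rng.choice(n_internal, size=n_copies, replace=False)
        )  # ancestral exon indices (0-based, mature order)
        conserved: dict[int, set[int]] = {i: set() for i in range(n_exons)}
        for ei in motif_exon_idx:
            # plant the class's domain block, truncated to the carrying exon
            cm = class_blocks[fam_class][: len(exon_contents[ei])]
            pos = int(rng.integers(0, len(exon_contents[ei]) - len(cm) + 1))
            _plant(exon_contents[ei], cm, pos)
            conserved[ei].update(range(pos, pos + len(cm)))

        # ---- plant label motifs in the 3'UTR -----------------------------
        counts = rng.integers(0, cfg.motif_max_count + 1, size=n_motifs)
        last = exon_contents[-1]
        utr3_lo = len(last) - utr3
        slots = np.arange(utr3_lo, len(last) - 6 + 1, 6)
        rng.shuffle(slots)
        slot_i = 0
        for mi, c in enumerate(counts):
            for _ in range(int(c)):
                _plant(last, cfg.motif_library[mi], int(slots[slot_i]))
                conserved[n_exons - 1].add(int(slots[slot_i]))
                slot_i += 1

        # ---- genomic layout ----------------------------------------------
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        introns = [
            _rand_seq(rng, int(rng.integers(*cfg.intron_len))) for _ in range(n_exons + 1)
        ]
        plus_parts: list[str] = [introns[0]]
        exon_plus: list[tuple[int, int]] = []
        pos = len(introns[0])
        for i, content in enumerate(exon_contents):
            exon_plus.append((pos, pos + len(content)))
            plus_parts.append("".join(content))
            pos += len(content)
            plus_parts.append(introns[i + 1])
            pos += len(introns[i + 1])
        plus_chrom = "".join(plus_parts)
        cds_plus = (exon_plus[0][0] + utr5, exon_plus[-1][1] - utr3)
        chrom_name = f"chr_{gene_id}"
        Lc = len(plus_chrom)
        if strand == "+":
            genomes["ref"][chrom_name] = plus_chrom
            exon_coords = exon_plus
            cds_start, cds_end = cds_plus
        else:
            genomes["ref"][chrom_name] = reverse_complement(plus_chrom)
            exon_coords = [(Lc - e, Lc - s) for (s, e) in exon_plus][::-1]
            cds_start, cds_end = Lc - cds_plus[1], Lc - cds_plus[0]

        def _iv(mature_idx: int) -> GenomicInterval:
            # genomic interval of ancestral exon `mature_idx` (mature order)
            if strand == "+":
                s, e = exon_coords[mature_idx]
            else:
                s, e = exon_coords[n_exons - 1 - mature_idx]
            return GenomicInterval(chrom_name, s, e, strand)

        # ---- exon-level domain annotation --------------------------------
        exon_domains: dict[int, frozenset[str]] = {}
        for i in range(1, n_exons - 1):
            k = int(rng.integers(0, 3)) if i not in motif_exon_idx else max(
                1, int(rng.integers(0, 3))
            )
            exon_domains[i] = frozenset(f"DOM_f{fam}_e{i}_{j}" for j in range(k))

        # ---- splice isoforms ---------------------------------------------
        n_iso = int(rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1))
        chosen_subsets: list[tuple[int, ...]] = [tuple(range(n_exons))]  # canonical
        for _ in range(n_iso - 1):
            for _attempt in range(20):
                keep = [0]
                keep += [i for i in range(1, n_exons - 1) if rng.random() < 0.7]
                keep.append(n_exons - 1)
                subset = tuple(keep)
                if subset not in chosen_subsets and len(keep) >= 2:
                    chosen_subsets.append(subset)
                    break

        gene_tids: list[str] = []
        for iso_i, subset in enumerate(chosen_subsets):
            tid = f"{gene_id}.T{iso_i}"
            gene_tids.append(tid)
            exons_sorted = sorted((_iv(i) for i in subset), key=lambda iv: iv.start)
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    gene_name=gene_id,
                    species="ref",
                    exons=tuple(exons_sorted),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
            dom: set[str] = set()
            for i in subset:
                dom |= exon_domains.get(i, frozenset())
            domains[tid] = frozenset(dom)
            flags_mature = [i in motif_exon_idx for i in subset]
            motif_exons[tid] = tuple(
                flags_mature[::-1] if strand == "-" else flags_mature
            )  # aligned to model.exons (genomic order)
        canonical[gene_id] = gene_tids[0]

        # ---- orthologs (CDS-only, substituted outside motifs) ------------
        cds_content: list[str] = []
        cds_conserved: set[int] = set()
        off = 0
        for i in range(n_exons):
            content = exon_contents[i]
            lo = utr5 if i == 0 else 0
            hi = len(content) - utr3 if i == n_exons - 1 else len(content)
            for p in range(lo, hi):
                cds_content.append(content[p])
                if p in conserved[i]:
                    cds_conserved.add(off)
                off += 1
        cds_len_anc = len(cds_content)
        orth_ids: list[str] = []
        for s in range(cfg.n_ortholog_species):
            species = f"sp{s + 1}"
            seq = list(cds_content)
            hits = np.flatnonzero(rng.random(cds_len_anc) < cfg.substitution_rate)
            for p in hits:
                if int(p) in cds_conserved:
                    continue
                old = seq[p]
                choices = [b for b in "ACGT" if b != old]
                seq[p] = choices[int(rng.integers(0, 3))]
            oid = f"{gene_id}.O{s + 1}"
            orth_ids.append(oid)
            ochrom = f"chr_{gene_id}_{species}"
            pad = _rand_seq(rng, 30)
            genomes[species][ochrom] = pad + "".join(seq) + _rand_seq(rng, 30)
            models.append(
                TranscriptModel(
                    transcript_id=oid,
                    gene_id=gene_id,
                    gene_name=gene_id,
                    species=species,
                    exons=(GenomicInterval(ochrom, 30, 30 + cds_len_anc, "+"),),
                    cds_start=30,
                    cds_end=30 + cds_len_anc,
                )
            )
        for tid in gene_tids:
            ortholog_map[tid] = tuple(orth_ids)

        # ---- property labels ---------------------------------------------
        utr3_seq = "".join(last[utr3_lo:])
        for tid, subset in zip(gene_tids, chosen_subsets):
            cds_len = (
                first_cds + last_cds + sum(internal_lens[i - 1] for i in subset[1:-1])
            )
            y = float(
                sum(
                    b * utr3_seq.count(m)
                    for m, b in zip(cfg.motif_library, cfg.motif_betas)
                )
                + cfg.gamma_cds_len * math.log(cds_len)
                + rng.normal(0.0, cfg.label_noise_sd)
            )
            labels[tid] = y

    return SyntheticCorpus(
        config=cfg,
        genomes=genomes,
        models=models,
        family_of_gene=family_of_gene,
        functional_class=functional_class,
        canonical=canonical,
        domains=domains,
        labels=labels,
        ortholog_map=ortholog_map,
        motif_exons=motif_exons,
    )


def corpus_to_probe_task(corpus: SyntheticCorpus, label: str = "y"):
    """Expose corpus labels as a probing task (regression on ``y`` or
    classification on the functional class)."""
    from .probing import ProbeTask

    ref = corpus.reference_models()
    families = {
        m.transcript_id: corpus.family_of_gene[m.gene_id] for m in ref
    }
    if label == "y":
        return ProbeTask(
            name="planted_property",
            kind="regression",
            labels={m.transcript_id: corpus.labels[m.transcript_id] for m in ref},
            families=families,
        )
    if label == "class":
        return ProbeTask(
            name="functional_class",
            kind="classification",
            labels={
                m.transcript_id: corpus.functional_class[m.gene_id] for m in ref
            },
            families=families,
        )
    raise ValueError(f"unknown label {label!r}")
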