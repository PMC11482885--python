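"""Positive-pair construction for contrastive pre-training.

Positive pairs are built from three biological augmentation sources plus a
degenerate fallback:

* ``splicing`` — other isoforms of the same gene,
* ``orthology`` — orthologous transcripts from other species.  These usually
  lack UTR annotation, so sampled orthologs are passed through the
  UTR-combination transform: the reference isoform's UTRs are attached to the
  ortholog's coding sequence, preventing the objective from learning that
  UTRs are dispensable,
* ``naive_orthology`` — transcripts of genes with an identical name in another
  species (exact, case-sensitive match),
* ``masking`` — when a reference has no related transcripts, its partner is a
  copy of itself with 30% of positions' nucleotide channels zeroed.

Sampling is uniform over the union of sources and deterministic in
``(seed, epoch, reference_id)``, so every epoch re-draws partners without any
stored state.  Orthology-sourced pairs carry a reduced loss weight
(default 0.8); all other sources weigh 1.0.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from typing import Callable, Iterable, Mapping

import numpy as np

from .transcripts import (
    MatureRNA,
    SixTrackEncoding,
    TranscriptModel,
    encode_six_track,
)

__all__ = [
    "AugmentationSet",
    "PositivePair",
    "PairDatasetStats",
    "build_splicing_sets",
    "build_orthology_sets",
    "merge_naive_orthology",
    "utr_combination_transform",
    "mask_augment",
    "PairSampler",
    "count_pairs",
    "ORTHOLOGY_WEIGHT_DEFAULT",
]

logger = logging.getLogger(__name__)

#: Loss weight for orthology-derived positive pairs.
ORTHOLOGY_WEIGHT_DEFAULT = 0.8

SOURCES = ("splicing", "orthology", "naive_orthology")


@dataclasses.dataclass
class AugmentationSet:
    """All positive partners of one reference transcript, tagged by source."""

    reference_id: str
    members: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def add(self, member_id: str, source: str) -> None:
        if source not in SOURCES:
            raise ValueError(f"unknown source {source!r}")
        if member_id == self.reference_id:
            return
        if (member_id, source) not in self.members:
            self.members.append((member_id, source))

    def __len__(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class PositivePair:
    x1: SixTrackEncoding
    x2: SixTrackEncoding
    source: str
    weight: float
    reference_id: str = ""
    member_id: str = ""


@dataclasses.dataclass
class PairDatasetStats:
    n_transcripts: int
    n_pairs: int
    per_source: dict[str, int]


# ---------------------------------------------------------------------------
# set construction
# ---------------------------------------------------------------------------

def build_splicing_sets(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, AugmentationSet]:
    """One augmentation set per transcript, containing its sibling isoforms."""
    transcripts = list(transcripts)
    by_gene: dict[tuple[str, str], list[str]] = {}
    for m in transcripts:
        by_gene.setdefault((m.species, m.gene_id), []).append(m.transcript_id)
    sets: dict[str, AugmentationSet] = {}
    for m in transcripts:
        s = AugmentationSet(m.transcript_id)
        for sib in by_gene[(m.species, m.gene_id)]:
            if sib != m.transcript_id:
                s.add(sib, "splicing")
        sets[m.transcript_id] = s
    return sets


def build_orthology_sets(
    sets: dict[str, AugmentationSet],
    ortholog_models: Iterable[TranscriptModel],
    mapping: Mapping[str, Iterable[str]],
) -> dict[str, AugmentationSet]:
    """Append ortholog members (from a reference→ortholog id mapping) in place."""
    known = {m.transcript_id for m in ortholog_models}
    for ref_id, orth_ids in mapping.items():
        if ref_id not in sets:
            sets[ref_id] = AugmentationSet(ref_id)
        for oid in orth_ids:
            if oid not in known:
                logger.warning("ortholog %s for %s not found; skipped", oid, ref_id)
                continue
            sets[ref_id].add(oid, "orthology")
    return sets


def merge_naive_orthology(
    sets: dict[str, AugmentationSet],
    transcripts: Iterable[TranscriptModel],
) -> dict[str, AugmentationSet]:
    """Pool transcripts of same-named genes across species (exact name match)."""
    transcripts = list(transcripts)
    by_name: dict[str, list[TranscriptModel]] = {}
    for m in transcripts:
        by_name.setdefault(m.gene_name, []).append(m)
    for m in transcripts:
        if m.transcript_id not in sets:
            continue
        for other in by_name[m.gene_name]:
            if other.species != m.species:
                sets[m.transcript_id].add(other.transcript_id, "naive_orthology")
    return sets


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def utr_combination_transform(isoform: MatureRNA, ortholog_cds: MatureRNA) -> MatureRNA:
    """Chimeric transcript: the isoform's UTRs around the ortholog's CDS.

    The ortholog must be a bare coding sequence (``cds_len == len(sequence)``);
    its codon starts are recomputed at the new offset and its splice junctions
    are shifted into chimera coordinates.
    """
    if not isoform.is_coding:
        raise ValueError(f"{isoform.transcript_id}: UTR chimera needs a coding isoform")
    if ortholog_cds.cds_len != len(ortholog_cds.sequence):
        raise ValueError(
            f"{ortholog_cds.transcript_id}: ortholog must be CDS-only "
            f"(cds_len {ortholog_cds.cds_len} != length {len(ortholog_cds.sequence)})"
        )
    utr5 = isoform.utr5
    utr3 = isoform.utr3
    off = len(utr5)
    seq = utr5 + ortholog_cds.sequence + utr3
    codon_starts = frozenset(off + 3 * k for k in range(ortholog_cds.cds_len // 3))
    junctions = frozenset(off + j for j in ortholog_cds.junction_positions)
    return MatureRNA(
        transcript_id=f"{isoform.transcript_id}|{ortholog_cds.transcript_id}~chimera",
        sequence=seq,
        junction_positions=junctions,
        codon_start_positions=codon_starts,
        utr5_len=len(utr5),
        cds_len=ortholog_cds.cds_len,
        utr3_len=len(utr3),
    )


def mask_augment(
    enc: SixTrackEncoding, fraction: float = 0.30, rng: np.random.Generator | None = None
) -> SixTrackEncoding:
    """Zero the nucleotide channels at ⌊fraction·L⌋ uniformly chosen valid
    positions; structural channels (junction, codon start) are retained."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    out = enc.copy()
    valid = np.flatnonzero(enc.mask)
    k = int(fraction * valid.size)
    if k > 0:
        chosen = rng.choice(valid, size=k, replace=False)
        out.matrix[chosen, :4] = 0.0
    return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _stable_hash(s: str) -> int:
    return zlib.crc32(s.encode())


@dataclasses.dataclass
class PairSampler:
    """Draw a positive pair for a reference transcript, deterministically.

    ``mature`` maps a transcript id to its :class:`MatureRNA`.  The draw for a
    given ``(seed, epoch, reference_id)`` is fixed, but varies across epochs,
    reproducing per-epoch partner re-sampling without storing draws.
    """

    sets: dict[str, AugmentationSet]
    mature: Callable[[str], MatureRNA]
    max_len: int = 1024
    seed: int = 0
    orthology_weight: float = ORTHOLOGY_WEIGHT_DEFAULT
    mask_fraction: float = 0.30

    def _rng(self, epoch: int, reference_id: str) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed % (2**31), epoch % (2**31), _stable_hash(reference_id)]
        )

    def sample(self, reference_id: str, epoch: int) -> PositivePair:
        rng = self._rng(epoch, reference_id)
        ref_rna = self.mature(reference_id)
        x1 = encode_six_track(ref_rna, self.max_len)
        aset = self.sets.get(reference_id)
        if aset is None or len(aset) == 0:
            x2 = mask_augment(x1, self.mask_fraction, rng)
            return PositivePair(x1, x2, "masking", 1.0, reference_id, reference_id)
        member_id, source = aset.members[int(rng.integers(0, len(aset)))]
        partner = self.mature(member_id)
        if source == "orthology" and ref_rna.is_coding:
            partner = utr_combination_transform(ref_rna, partner)
        x2 = encode_six_track(partner, self.max_len)
        weight = self.orthology_weight if source == "orthology" else 1.0
        return PositivePair(x1, x2, source, weight, reference_id, member_id)


def count_pairs(sets: Mapping[str, AugmentationSet]) -> PairDatasetStats:
    """Count ordered reference→member pairs, broken down by source."""
    per_source = {s: 0 for s in SOURCES}
    for aset in sets.values():
        for _, source in aset.members:
            per_source[source] += 1
    return PairDatasetStats(
        n_transcripts=len(sets),
        n_pairs=sum(per_source.values()),
        per_source=per_source,
    )


def write_pair_manifest(sets: Mapping[str, AugmentationSet], path, orthology_weight: float = ORTHOLOGY_WEIGHT_DEFAULT) -> None:
    """TSV manifest of ordered pairs: reference_id, member_id, source, weight."""
    with open(path, "w") as fh:
        fh.write("reference_id\tmember_id\tsource\tweight\n")
        for ref_id in sorted(sets):
            for member_id, source in sets[ref_id].members:
                w = orthology_weight if source == "orthology" else 1.0
                fh.write(f"{ref_id}\t{member_id}\t{source}\t{w}\n")
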