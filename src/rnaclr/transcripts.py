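"""Transcript annotation parsing, mature-RNA extraction, and six-track encoding.

A mature mRNA is the spliced product of a gene: the exons of one transcript
concatenated 5'→3', comprising a 5' untranslated region (UTR), a coding
sequence (CDS), and a 3' UTR.  The model input used throughout this package is
a per-position "six-track" matrix: four one-hot nucleotide channels (A, C, G,
T) plus two structural indicator channels — one marking splice junctions (the
first base of every exon after the first, in mature coordinates) and one
marking the first nucleotide of every codon in the CDS.

Genomic coordinates follow the UCSC convention: 0-based, half-open.  The
alphabet is DNA (T, not U); sequences are upper-cased on ingestion.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "MatureRNA",
    "SixTrackEncoding",
    "GenePredParseError",
    "read_genepred",
    "read_toga_bed",
    "extract_mature_rna",
    "encode_six_track",
    "decode_six_track",
    "reverse_complement",
    "MAX_LEN_DEFAULT",
]

#: Default maximum model input length in nucleotides; longer transcripts are
#: truncated from the 3' end so 5'UTR and CDS start are always retained.
MAX_LEN_DEFAULT = 12_288

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class GenePredParseError(ValueError):
    """Raised for malformed annotation rows; the message names the line."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class TranscriptModel:
    """Genomic exon/CDS structure of a single transcript."""

    transcript_id: str
    gene_id: str
    gene_name: str
    species: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int | None = None  # genomic; None for non-coding
    cds_end: int | None = None
    biotype: str = "protein_coding"

    def __post_init__(self):
        if not self.exons:
            raise ValueError("a transcript needs at least one exon")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted and non-overlapping"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or both absent")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclasses.dataclass(frozen=True)
class MatureRNA:
    """A spliced transcript sequence with its structural annotations.

    ``junction_positions`` hold the mature coordinate of the first base of
    each exon after the first; ``codon_start_positions`` the mature coordinate
    of the first base of each codon in the CDS (the stop codon is counted as
    part of the CDS).  Non-coding transcripts use the convention
    ``utr5_len = cds_len = 0`` and ``utr3_len = len(sequence)``.
    """

    transcript_id: str
    sequence: str
    junction_positions: frozenset[int]
    codon_start_positions: frozenset[int]
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self):
        if self.utr5_len + self.cds_len + self.utr3_len != len(self.sequence):
            raise ValueError("utr5_len + cds_len + utr3_len must equal sequence length")
        if self.cds_len % 3 != 0:
            raise ValueError("cds_len must be divisible by 3")

    @property
    def utr5(self) -> str:
        return self.sequence[: self.utr5_len]

    @property
    def cds(self) -> str:
        return self.sequence[self.utr5_len : self.utr5_len + self.cds_len]

    @property
    def utr3(self) -> str:
        return self.sequence[self.utr5_len + self.cds_len :]

    @property
    def is_coding(self) -> bool:
        return self.cds_len > 0


@dataclasses.dataclass
class SixTrackEncoding:
    """L×6 model input: A, C, G, T one-hot + splice-junction + codon-start."""

    matrix: np.ndarray  # (L, 6), float
    mask: np.ndarray  # (L,), bool; False marks padding
    transcript_id: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 6:
            raise ValueError("matrix must be L x 6")
        if self.mask.shape != (self.matrix.shape[0],):
            raise ValueError("mask length must match matrix")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def copy(self) -> "SixTrackEncoding":
        return SixTrackEncoding(self.matrix.copy(), self.mask.copy(), self.transcript_id)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

def _parse_int_list(field: str, line_no: int) -> list[int]:
    try:
        return [int(x) for x in field.rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise GenePredParseError(f"line {line_no}: bad integer list {field!r}") from exc


def read_genepred(path, species: str = "ref") -> list[TranscriptModel]:
    """Read a UCSC genePred file (tab-separated, optional leading bin column).

    Columns: name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd, exonCount,
    exonStarts, exonEnds[, score, name2, ...].  ``cdsStart == cdsEnd`` marks a
    non-coding transcript.  Rows with malformed coordinates raise
    :class:`GenePredParseError` naming the line.
    """
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            # auto-detect the optional bin column: strand sits at index 2
            # without it, index 3 with it.
            if len(fields) > 2 and fields[2] in ("+", "-"):
                off = 0
            elif len(fields) > 3 and fields[3] in ("+", "-"):
                off = 1
            else:
                raise GenePredParseError(f"line {line_no}: cannot locate strand column")
            if len(fields) < off + 10:
                raise GenePredParseError(f"line {line_no}: too few columns")
            name = fields[off]
            chrom = fields[off + 1]
            strand = fields[off + 2]
            try:
                cds_start = int(fields[off + 5])
                cds_end = int(fields[off + 6])
                exon_count = int(fields[off + 7])
            except ValueError as exc:
                raise GenePredParseError(f"line {line_no}: bad coordinate field") from exc
            starts = _parse_int_list(fields[off + 8], line_no)
            ends = _parse_int_list(fields[off + 9], line_no)
            if len(starts) != exon_count or len(ends) != exon_count:
                raise GenePredParseError(
                    f"line {line_no}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            gene = fields[off + 11] if len(fields) > off + 11 and fields[off + 11] else name
            exons = tuple(
                GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
            )
            coding = cds_start < cds_end
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=gene,
                    gene_name=gene,
                    species=species,
                    exons=exons,
                    cds_start=cds_start if coding else None,
                    cds_end=cds_end if coding else None,
                    biotype="protein_coding" if coding else "non_coding",
                )
            )
    return models


def read_toga_bed(path, species: str = "query") -> list[TranscriptModel]:
    """Read BED12 ortholog projections (e.g. TOGA output).

    Exons are ``blockStarts``/``blockSizes`` offsets from ``chromStart``;
    ``thickStart``/``thickEnd`` give the CDS.  ``thickStart == thickEnd``
    marks a non-coding projection.
    """
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GenePredParseError(f"line {line_no}: BED12 needs 12 columns")
            chrom, chrom_start, _chrom_end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            block_count = int(fields[9])
            sizes = _parse_int_list(fields[10], line_no)
            offsets = _parse_int_list(fields[11], line_no)
            if len(sizes) != block_count or len(offsets) != block_count:
                raise GenePredParseError(
                    f"line {line_no}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(offsets)} offsets"
                )
            exons = tuple(
                GenomicInterval(chrom, chrom_start + o, chrom_start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            coding = thick_start < thick_end
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=name,
                    gene_name=name,
                    species=species,
                    exons=exons,
                    cds_start=thick_start if coding else None,
                    cds_end=thick_end if coding else None,
                    biotype="protein_coding" if coding else "non_coding",
                )
            )
    return models


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice a chromosome from a dict of strings or a pyfaidx.Fasta."""
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not found in genome")
    if isinstance(record, str):
        if end > len(record):
            raise IndexError(f"exon [{start}, {end}) beyond end of {chrom} ({len(record)} bp)")
        return record[start:end]
    # pyfaidx-style record: len() and slicing both work
    if end > len(record):
        raise IndexError(f"exon [{start}, {end}) beyond end of {chrom} ({len(record)} bp)")
    return str(record[start:end])


def extract_mature_rna(model: TranscriptModel, genome) -> MatureRNA:
    """Splice a transcript out of the genome into a :class:`MatureRNA`.

    Exon sequences are concatenated in 5'→3' transcript order; minus-strand
    transcripts are reverse-complemented.  ``genome`` may be a
    ``pyfaidx.Fasta`` or any mapping of chromosome name → sequence string.
    """
    exon_seqs = [
        _fetch(genome, e.chrom, e.start, e.end).upper() for e in model.exons
    ]
    plus_seq = "".join(exon_seqs)
    minus = model.strand == "-"
    sequence = reverse_complement(plus_seq) if minus else plus_seq

    # mature order of exons and cumulative offsets
    lengths = [len(e) for e in model.exons]
    if minus:
        lengths = lengths[::-1]
    offsets = np.cumsum([0] + lengths)
    junctions = frozenset(int(o) for o in offsets[1:-1])

    if model.is_coding:
        # mature bases strictly 5' of the first CDS base (transcript orientation)
        cds_len = 0
        utr5_plus = 0  # bases before CDS in genomic orientation
        for e in model.exons:
            lo = max(e.start, model.cds_start)
            hi = min(e.end, model.cds_end)
            if hi > lo:
                cds_len += hi - lo
            utr5_plus += max(0, min(e.end, model.cds_start) - e.start)
        total = sum(len(e) for e in model.exons)
        if minus:
            utr3_plus = 0
            for e in model.exons:
                utr3_plus += max(0, e.end - max(e.start, model.cds_end))
            utr5_len = utr3_plus
        else:
            utr5_len = utr5_plus
        if cds_len % 3 != 0:
            raise ValueError(
                f"{model.transcript_id}: CDS length {cds_len} not divisible by 3"
            )
        codon_starts = frozenset(utr5_len + 3 * k for k in range(cds_len // 3))
        utr3_len = total - utr5_len - cds_len
    else:
        cds_len, utr5_len = 0, 0
        utr3_len = len(sequence)
        codon_starts = frozenset()

    return MatureRNA(
        transcript_id=model.transcript_id,
        sequence=sequence,
        junction_positions=junctions,
        codon_start_positions=codon_starts,
        utr5_len=utr5_len,
        cds_len=cds_len,
        utr3_len=utr3_len,
    )


# ---------------------------------------------------------------------------
# six-track encoding
# ---------------------------------------------------------------------------

def encode_six_track(rna: MatureRNA, max_len: int = MAX_LEN_DEFAULT) -> SixTrackEncoding:
    """Encode a mature RNA as an L×6 matrix (L = min(len, max_len)).

    Channel order: A, C, G, T, splice junction, codon start.  'N' bases leave
    all four nucleotide channels zero.  Sequences longer than ``max_len`` are
    truncated from the 3' end, preserving the 5'UTR and CDS start.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if not rna.sequence:
        raise ValueError("cannot encode an empty sequence")
    L = min(len(rna.sequence), max_len)
    mat = np.zeros((L, 6), dtype=np.float64)
    for i, base in enumerate(rna.sequence[:L]):
        j = _NT_INDEX.get(base)
        if j is not None:
            mat[i, j] = 1.0
    for p in rna.junction_positions:
        if p < L:
            mat[p, 4] = 1.0
    for p in rna.codon_start_positions:
        if p < L:
            mat[p, 5] = 1.0
    return SixTrackEncoding(mat, np.ones(L, dtype=bool), rna.transcript_id)


def decode_six_track(enc: SixTrackEncoding) -> MatureRNA:
    """Invert :func:`encode_six_track` (exact for untruncated transcripts)."""
    mat = enc.matrix[enc.mask]
    nt = mat[:, :4]
    if np.any(nt.sum(axis=1) > 1):
        raise ValueError("position with more than one nucleotide channel set")
    bases = []
    for row in nt:
        hits = np.flatnonzero(row == 1.0)
        bases.append("ACGT"[hits[0]] if hits.size else "N")
    seq = "".join(bases)
    junctions = frozenset(int(i) for i in np.flatnonzero(mat[:, 4] == 1.0))
    codon_starts = frozenset(int(i) for i in np.flatnonzero(mat[:, 5] == 1.0))
    # codons cut off by 3' truncation cannot count toward the CDS length
    complete = sorted(p for p in codon_starts if p + 3 <= len(seq))
    if complete:
        utr5 = complete[0]
        cds = 3 * len(complete)
    else:
        utr5, cds = 0, 0
    return MatureRNA(
        transcript_id=enc.transcript_id,
        sequence=seq,
        junction_positions=junctions,
        codon_start_positions=codon_starts,
        utr5_len=utr5,
        cds_len=cds,
        utr3_len=len(seq) - utr5 - cds,
    )


def write_fasta(rnas: Iterable[MatureRNA], path) -> None:
    """Write mature sequences as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        for r in rnas:
            fh.write(f">{r.transcript_id}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")
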