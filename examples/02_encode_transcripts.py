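"""Parse standard annotation formats and build six-track model inputs.

The corpus is written to disk as genePred + FASTA (+ BED12 for orthologs) and
read back through the same parsers that handle real annotation files; each
mature RNA becomes an L x 6 matrix: A/C/G/T one-hot, splice-junction marks,
and codon-start marks.
"""

import tempfile

import pyfaidx

from rnaclr import SimulationConfig, simulate_corpus
from rnaclr import read_genepred, read_toga_bed, extract_mature_rna, encode_six_track

with tempfile.TemporaryDirectory() as d:
    simulate_corpus(SimulationConfig(n_families=5, seed=1)).write(d)

    models = read_genepred(f"{d}/ref.genePred", species="ref")
    genome = pyfaidx.Fasta(f"{d}/ref.fa")
    print(f"parsed {len(models)} transcripts from genePred")

    m = models[0]
    rna = extract_mature_rna(m, genome)
    enc = encode_six_track(rna, max_len=512)
    print(f"\n{m.transcript_id}: {len(m.exons)} exons on {m.strand} strand")
    print(f"encoding shape {enc.matrix.shape}  (positions x tracks)")
    print(f"junction marks: {int(enc.matrix[:, 4].sum())} (= exons - 1)")
    print(f"codon-start marks: {int(enc.matrix[:, 5].sum())} (= CDS length / 3 = {rna.cds_len // 3})")

    orths = read_toga_bed(f"{d}/sp1.bed", species="sp1")
    orna = extract_mature_rna(orths[0], pyfaidx.Fasta(f"{d}/sp1.fa"))
    print(f"\northolog {orths[0].transcript_id}: CDS-only "
          f"(cds_len {orna.cds_len} == length {len(orna.sequence)})")
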