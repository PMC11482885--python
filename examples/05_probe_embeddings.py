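"""Linear probing: is the planted property label decodable from embeddings?

Uses the standard study corpus (200 gene families) and training budget
(10 epochs); smaller corpora leave the contrastive encoder undertrained and
the comparison noisy.  Freezes the trained encoder and fits ridge probes on
the pooled embeddings under homology-aware splits (whole gene families held
out), comparing against an untrained encoder of the same architecture.
Runs roughly ten minutes on one CPU.
"""

import numpy as np

from rnaclr import SimulationConfig, simulate_corpus, TrainConfig, pretrain
from rnaclr import SSMEncoder, encode_six_track, corpus_to_probe_task
from rnaclr import homology_split, fit_linear_probe

corpus = simulate_corpus(SimulationConfig(seed=11))
cfg = TrainConfig(batch_size=32, epochs=10, seed=1)
state = pretrain(corpus, cfg)

tids = [m.transcript_id for m in corpus.reference_models()]
encs = [encode_six_track(corpus.mature(t), cfg.max_len) for t in tids]
emb = dict(zip(tids, state.encoder.encode_batch(encs)))
emb0 = dict(zip(tids, SSMEncoder(state.encoder.config).encode_batch(encs)))

task = corpus_to_probe_task(corpus, "y")
rs, rs0 = [], []
for seed in range(5):
    split = homology_split(tids, task.families, seed=seed)
    rs.append(fit_linear_probe(emb, task, split, seed=seed))
    rs0.append(fit_linear_probe(emb0, task, split, seed=seed))

print(f"test Pearson R, trained encoder : {np.mean(rs):.3f} (seeds: {[f'{r:.3f}' for r in rs]})")
print(f"test Pearson R, untrained       : {np.mean(rs0):.3f}")
print("\nHigher R for the trained encoder means contrastive pre-training made the")
print("planted 3'UTR motif signal linearly accessible to a frozen-feature probe.")
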