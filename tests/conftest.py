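"""Shared fixtures.

The expensive fixture is ``micro_run``: one contrastive pre-training run of
the micro encoder (2 layers, d_model 64) on the standard 200-family synthetic
corpus, with embedding snapshots captured at epoch boundaries.  It is built
once per session and shared by the integration-level tests (representation
recovery, group separation, exon-deletion analysis, probe ordering).
"""

import numpy as np
import pytest

from rnaclr.simulate import SimulationConfig, simulate_corpus, corpus_to_probe_task
from rnaclr.ssm import SSMEncoder
from rnaclr.train import TrainConfig, pretrain
from rnaclr.transcripts import encode_six_track

CORPUS_SEED = 11
TRAIN_SEED = 1
SNAPSHOT_EPOCHS = (3, 6, 10)


@pytest.fixture(scope="session")
def micro_run():
    corpus = simulate_corpus(SimulationConfig(seed=CORPUS_SEED))
    cfg = TrainConfig(batch_size=32, epochs=10, seed=TRAIN_SEED)
    ref = corpus.reference_models()
    tids = [m.transcript_id for m in ref]
    encs = [encode_six_track(corpus.mature(t), cfg.max_len) for t in tids]

    snapshots: dict[int, dict[str, np.ndarray]] = {}

    def snap(encoder) -> dict[str, np.ndarray]:
        return dict(zip(tids, encoder.encode_batch(encs)))

    def on_epoch(state):
        if state.epoch in SNAPSHOT_EPOCHS:
            snapshots[state.epoch] = snap(state.encoder)

    state = pretrain(corpus, cfg, epoch_callback=on_epoch)
    untrained = SSMEncoder(state.encoder.config)
    snapshots[0] = snap(untrained)
    return {
        "corpus": corpus,
        "config": cfg,
        "state": state,
        "embeddings": snapshots[max(SNAPSHOT_EPOCHS)],
        "embeddings_untrained": snapshots[0],
        "snapshots": snapshots,
        "task": corpus_to_probe_task(corpus, "y"),
        "transcript_ids": tids,
    }
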