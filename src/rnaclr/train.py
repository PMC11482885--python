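"""Contrastive / MLM pre-training loop.

Ties together positive-pair sampling, the sequence encoder, the projection
head and the objectives, with seeded, reproducible batching: partner draws
depend only on ``(seed, epoch, reference_id)`` and batch composition only on
``(seed, epoch)``, so a run is exactly reproducible and resumable from an
epoch checkpoint without serializing generator state.

Batching is gene-exclusive by default — at most one transcript per gene per
batch — so that sibling isoforms of the anchor never appear among its
in-batch negatives.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from typing import Callable, Iterable, Sequence

import numpy as np

from ._autodiff import Tensor
from .losses import DCLConfig, apply_mlm_corruption, dcl_loss_tensor, mlm_loss_from_logits
from .pairs import (
    ORTHOLOGY_WEIGHT_DEFAULT,
    AugmentationSet,
    PairSampler,
    PositivePair,
    build_orthology_sets,
    build_splicing_sets,
    merge_naive_orthology,
)
from .ssm import ProjectionHead, SSMConfig, SSMEncoder, pad_batch, preset_config

__all__ = ["TrainConfig", "TrainState", "Adam", "make_batches", "pretrain", "build_augmentation_sets"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 10
    lr: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    objective: str = "cl"  # "cl", "mlm", or "cl+mlm"
    alpha: float = 0.95
    temperature: float = 0.1
    orthology_weight: float = ORTHOLOGY_WEIGHT_DEFAULT
    encoder_preset: str = "micro"
    max_len: int = 448
    mlm_fraction: float = 0.15
    mask_fraction: float = 0.30
    gene_exclusive: bool = True
    cosine_decay: bool = True
    weight_decay: float = 0.0
    use_splicing: bool = True
    use_orthology: bool = True
    use_naive_orthology: bool = False

    def __post_init__(self):
        if self.objective not in ("cl", "mlm", "cl+mlm"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if "cl" in self.objective and self.batch_size < 2:
            raise ValueError("contrastive objectives need batch_size >= 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


class Adam:
    """Adam with optional decoupled weight decay and cosine learning-rate decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, total_steps: int | None = None,
                 cosine_decay: bool = False):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.cosine_decay = cosine_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        if self.cosine_decay and self.total_steps:
            frac = min(self.t / self.total_steps, 1.0)
            return self.lr * 0.5 * (1.0 + math.cos(math.pi * frac))
        return self.lr

    def step(self) -> None:
        lr = self.current_lr()
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclasses.dataclass
class TrainState:
    encoder: SSMEncoder
    head: ProjectionHead
    optimizer: Adam
    config: TrainConfig
    epoch: int = 0
    step: int = 0
    log: list[dict] = dataclasses.field(default_factory=list)

    def save(self, path: str) -> None:
        arrays = {f"enc{i}": p.data for i, p in enumerate(self.encoder.params())}
        arrays |= {f"head{i}": p.data for i, p in enumerate(self.head.params())}
        arrays |= {f"adam_m{i}": m for i, m in enumerate(self.optimizer.m)}
        arrays |= {f"adam_v{i}": v for i, v in enumerate(self.optimizer.v)}
        meta = {
            "epoch": self.epoch,
            "step": self.step,
            "adam_t": self.optimizer.t,
            "train_config": dataclasses.asdict(self.config),
            "encoder_config": dataclasses.asdict(self.encoder.config),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainState":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = TrainConfig(**meta["train_config"])
            encoder = SSMEncoder(SSMConfig(**meta["encoder_config"]))
            head = ProjectionHead(encoder.config.d_model, encoder.config.proj_dim, seed=cfg.seed)
            for i, p in enumerate(encoder.params()):
                p.data[...] = data[f"enc{i}"]
            for i, p in enumerate(head.params()):
                p.data[...] = data[f"head{i}"]
            opt = Adam(encoder.params() + head.params(), lr=cfg.lr,
                       weight_decay=cfg.weight_decay, cosine_decay=cfg.cosine_decay)
            opt.t = meta["adam_t"]
            for i in range(len(opt.m)):
                opt.m[i] = data[f"adam_m{i}"].copy()
                opt.v[i] = data[f"adam_v{i}"].copy()
            return cls(encoder=encoder, head=head, optimizer=opt, config=cfg,
                       epoch=meta["epoch"], step=meta["step"])

    def write_log(self, path: str) -> None:
        cols = ["step", "epoch", "lr", "l_cl", "l_mlm", "l_total"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.log:
                fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def make_batches(
    references: Sequence[str],
    epoch: int,
    cfg: TrainConfig,
    gene_of: dict[str, str] | None = None,
) -> list[list[str]]:
    """Seeded per-epoch shuffle into batches of reference ids.

    With ``gene_exclusive`` (and a gene map), no two transcripts of the same
    gene share a batch; overflow transcripts spill into later batches.
    """
    rng = np.random.default_rng([cfg.seed % (2**31), epoch % (2**31), 11])
    order = list(references)
    rng.shuffle(order)
    if not (cfg.gene_exclusive and gene_of):
        return [order[i : i + cfg.batch_size] for i in range(0, len(order), cfg.batch_size)]
    batches: list[list[str]] = []
    pending = order
    while pending:
        batch: list[str] = []
        genes: set[str] = set()
        rest: list[str] = []
        for tid in pending:
            g = gene_of.get(tid, tid)
            if len(batch) < cfg.batch_size and g not in genes:
                batch.append(tid)
                genes.add(g)
            else:
                rest.append(tid)
        batches.append(batch)
        pending = rest
    return batches


def build_augmentation_sets(corpus, cfg: TrainConfig) -> dict[str, AugmentationSet]:
    """Assemble augmentation sets for a synthetic corpus per the config flags."""
    ref_models = corpus.reference_models()
    if cfg.use_splicing:
        sets = build_splicing_sets(ref_models)
    else:
        sets = {m.transcript_id: AugmentationSet(m.transcript_id) for m in ref_models}
    if cfg.use_orthology:
        orth_models = [m for m in corpus.models if m.species != "ref"]
        build_orthology_sets(sets, orth_models, corpus.ortholog_map)
    if cfg.use_naive_orthology:
        merge_naive_orthology(sets, corpus.models)
    return sets


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _nt_targets(X: np.ndarray) -> np.ndarray:
    """One-hot nucleotide targets from the first four tracks ('N' rows excluded)."""
    return X[:, :, :4]


def pretrain(
    corpus,
    cfg: TrainConfig,
    run_dir: str | None = None,
    epoch_callback: Callable[["TrainState"], None] | None = None,
    state: TrainState | None = None,
) -> TrainState:
    """Pre-train an encoder on a corpus; returns the final :class:`TrainState`.

    ``corpus`` is any object exposing ``reference_models()``, ``mature(tid)``
    and (for orthology) ``ortholog_map`` — in practice a
    :class:`rnaclr.simulate.SyntheticCorpus`.  Pass ``state`` to continue a
    previous run (e.g. from :meth:`TrainState.load`).
    """
    sets = build_augmentation_sets(corpus, cfg)
    ref_models = corpus.reference_models()
    references = [m.transcript_id for m in ref_models]
    gene_of = {m.transcript_id: m.gene_id for m in ref_models}
    sampler = PairSampler(
        sets=sets,
        mature=corpus.mature,
        max_len=cfg.max_len,
        seed=cfg.seed,
        orthology_weight=cfg.orthology_weight,
        mask_fraction=cfg.mask_fraction,
    )
    n_batches = max(1, math.ceil(len(references) / cfg.batch_size))
    if state is None:
        enc_cfg = dataclasses.replace(preset_config(cfg.encoder_preset), max_len=cfg.max_len, seed=cfg.seed)
        encoder = SSMEncoder(enc_cfg)
        head = ProjectionHead(enc_cfg.d_model, enc_cfg.proj_dim, seed=cfg.seed)
        optimizer = Adam(
            encoder.params() + head.params(), lr=cfg.lr, weight_decay=cfg.weight_decay,
            total_steps=cfg.epochs * n_batches, cosine_decay=cfg.cosine_decay,
        )
        state = TrainState(encoder=encoder, head=head, optimizer=optimizer, config=cfg)
    else:
        state.optimizer.total_steps = cfg.epochs * n_batches
    dcl_cfg = DCLConfig(
        temperature=cfg.temperature,
        source_weights=(
            ("splicing", 1.0), ("orthology", cfg.orthology_weight),
            ("naive_orthology", 1.0), ("masking", 1.0),
        ),
    )
    if run_dir:
        os.makedirs(run_dir, exist_ok=True)

    for epoch in range(state.epoch, cfg.epochs):
        for batch_ids in make_batches(references, epoch, cfg, gene_of):
            if "cl" in cfg.objective and len(batch_ids) < 2:
                continue  # a lone transcript has no in-batch negatives
            pairs = [sampler.sample(tid, epoch) for tid in batch_ids]
            row: dict = {"step": state.step, "epoch": epoch, "lr": state.optimizer.current_lr()}
            loss, row = _objective(state, pairs, cfg, dcl_cfg, epoch, row)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at step {state.step} "
                    f"(batch: {', '.join(batch_ids[:8])}...)"
                )
            state.optimizer.zero_grad()
            loss.backward()
            state.optimizer.step()
            state.log.append(row)
            state.step += 1
        state.epoch = epoch + 1
        if run_dir:
            state.save(os.path.join(run_dir, f"checkpoint_epoch{state.epoch:03d}.npz"))
        if epoch_callback is not None:
            epoch_callback(state)
    if run_dir:
        state.write_log(os.path.join(run_dir, "train_log.tsv"))
    return state


def _objective(state: TrainState, pairs: list[PositivePair], cfg: TrainConfig,
               dcl_cfg: DCLConfig, epoch: int, row: dict):
    encoder, head = state.encoder, state.head
    l_cl = None
    l_mlm = None
    if "cl" in cfg.objective and len(pairs) >= 2:
        X1, M1 = pad_batch([p.x1 for p in pairs])
        X2, M2 = pad_batch([p.x2 for p in pairs])
        z1 = head.forward(encoder.forward_embedding(X1, M1))
        z2 = head.forward(encoder.forward_embedding(X2, M2))
        w = np.array([dcl_cfg.weight(p.source) for p in pairs])
        l_cl = dcl_loss_tensor(z1, z2, w, dcl_cfg.temperature)
        row["l_cl"] = float(l_cl.data)
    if "mlm" in cfg.objective:
        rng = np.random.default_rng(
            [cfg.seed % (2**31), epoch % (2**31), state.step % (2**31), 13]
        )
        corrupted = []
        masked_sets = []
        for p in pairs:
            c, m = apply_mlm_corruption(p.x1, cfg.mlm_fraction, rng)
            corrupted.append(c)
            masked_sets.append(m)
        Xc, Mc = pad_batch(corrupted)
        Xo, _ = pad_batch([p.x1 for p in pairs])
        hidden = encoder.forward_hidden(Xc, Mc)
        logits = hidden @ encoder.W_mlm + encoder.b_mlm
        mask_flags = np.zeros(Xc.shape[:2], dtype=bool)
        for i, m in enumerate(masked_sets):
            mask_flags[i, m] = True
        # positions that were 'N' in the original carry no nucleotide target
        mask_flags &= _nt_targets(Xo).sum(axis=2) > 0
        l_mlm = mlm_loss_from_logits(logits, _nt_targets(Xo), mask_flags)
        row["l_mlm"] = float(l_mlm.data)
    if l_cl is not None and l_mlm is not None:
        loss = l_cl * (1.0 - cfg.alpha) + l_mlm * cfg.alpha
        row["l_total"] = float(loss.data)
    elif l_cl is not None:
        loss = l_cl
        row["l_total"] = row["l_cl"]
    elif l_mlm is not None:
        loss = l_mlm
        row["l_total"] = row["l_mlm"]
    else:
        raise RuntimeError("batch too small for the contrastive objective")
    return loss, row
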