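"""Downstream evaluation: linear probing, few-shot subsampling, homology-aware
splits, and ablation Z-score statistics.

Linear probing asks whether a label is linearly decodable from frozen
embeddings: a ridge-regularized linear map for regression (scored by
Pearson's R) or a regularized logistic map for classification (scored by
auPRC, macro-averaged across classes), with the regularization strength
selected on a validation partition.

Splits are homology-aware: all members of a gene family land in exactly one
partition, so test performance cannot come from memorizing near-duplicate
sequences.

For ablation comparisons across tasks with different metrics and dynamic
ranges, scores are normalized to Z-scores against a pooled reference
distribution: all configurations' scores for a task are pooled (regression
scores Fisher-transformed first, ``arctanh(r)``), the pool's μ and σ
standardize every score, per-task Z is the mean over seeds, and a
configuration's aggregate Z averages its task Zs.  Configurations are placed
in the top performance tier when a one-sided Welch test against the reference
configuration fails to reject (p > 0.05).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import average_precision_score
from sklearn.preprocessing import StandardScaler, label_binarize

__all__ = [
    "ProbeTask",
    "ProbeResult",
    "ZScoreTable",
    "homology_split",
    "fit_linear_probe",
    "few_shot_subsample",
    "fisher_z",
    "zscore_normalize",
    "welch_one_sided",
    "top_tier_flags",
]

logger = logging.getLogger(__name__)

#: 7 log-spaced regularization strengths tried by every probe.
REGULARIZATION_GRID = np.logspace(-3, 3, 7)


@dataclasses.dataclass
class ProbeTask:
    name: str
    kind: str  # "regression" | "classification"
    labels: dict[str, float]
    families: dict[str, int]  # transcript id -> family id (for splits)

    def __post_init__(self):
        if self.kind not in ("regression", "classification"):
            raise ValueError(f"unknown task kind {self.kind!r}")


@dataclasses.dataclass
class ProbeResult:
    task: str
    config_id: str
    kind: str
    scores: list[float]  # one per seed

    @property
    def n_seeds(self) -> int:
        return len(self.scores)


@dataclasses.dataclass
class ZScoreTable:
    task_mu: dict[str, float]
    task_sigma: dict[str, float]
    per_config_task: dict[tuple[str, str], float]  # (config, task) -> mean Z
    aggregate: dict[str, float]  # config -> mean of task Zs


# ---------------------------------------------------------------------------
# splits and subsampling
# ---------------------------------------------------------------------------

def homology_split(
    ids: Sequence[str],
    family_ids: Mapping[str, int],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Train/val/test split keeping every gene family within one partition."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    fam_members: dict[int, list[str]] = {}
    for tid in ids:
        fam_members.setdefault(family_ids[tid], []).append(tid)
    fams = sorted(fam_members)
    rng = np.random.default_rng(seed)
    rng.shuffle(fams)
    n = len(ids)
    targets = [f * n for f in fractions]
    filled = [0.0, 0.0, 0.0]
    parts: tuple[list[str], list[str], list[str]] = ([], [], [])
    for fam in fams:
        members = fam_members[fam]
        if any(len(members) > t for t in targets):
            logger.warning("family %s larger than a partition target", fam)
        deficits = [t - f for t, f in zip(targets, filled)]
        k = int(np.argmax(deficits))
        parts[k].extend(sorted(members))
        filled[k] += len(members)
    # guarantee non-empty partitions when there are enough families
    if len(fams) >= 3:
        fam_lists = {
            k: sorted({family_ids[t] for t in parts[k]}) for k in range(3)
        }
        for k in range(3):
            if parts[k]:
                continue
            donor = max(range(3), key=lambda j: len(fam_lists[j]))
            fam = min(fam_lists[donor], key=lambda f: len(fam_members[f]))
            moved = fam_members[fam]
            parts[donor][:] = [t for t in parts[donor] if t not in set(moved)]
            parts[k].extend(sorted(moved))
            fam_lists[donor].remove(fam)
            fam_lists[k].append(fam)
    return parts


def few_shot_subsample(train_ids: Sequence[str], n: int, seed: int = 0) -> list[str]:
    """Uniform subsample of the training ids, without replacement."""
    if n > len(train_ids):
        raise ValueError(f"cannot subsample {n} from {len(train_ids)} train ids")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(train_ids), size=n, replace=False)
    return [train_ids[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

def _auprc(y_true: np.ndarray, scores: np.ndarray, classes: np.ndarray) -> float:
    """Macro-averaged area under the precision-recall curve."""
    if classes.size == 2:
        return float(average_precision_score(y_true == classes[1], scores[:, 1]))
    Y = label_binarize(y_true, classes=classes)
    vals = []
    for j in range(classes.size):
        if Y[:, j].any():
            vals.append(average_precision_score(Y[:, j], scores[:, j]))
    return float(np.mean(vals))


def fit_linear_probe(
    embeddings: Mapping[str, np.ndarray],
    task: ProbeTask,
    split: tuple[Sequence[str], Sequence[str], Sequence[str]],
    seed: int = 0,
) -> float:
    """Fit a linear probe on frozen embeddings; returns the test metric
    (Pearson's R for regression, macro auPRC for classification)."""
    train, val, test = split
    if set(train) & set(val) or set(train) & set(test) or set(val) & set(test):
        raise ValueError("split partitions must be disjoint")

    def _xy(ids):
        X = np.stack([embeddings[i] for i in ids])
        y = np.array([task.labels[i] for i in ids])
        return X, y

    Xtr, ytr = _xy(train)
    Xva, yva = _xy(val)
    Xte, yte = _xy(test)
    scaler = StandardScaler().fit(Xtr)
    Xtr, Xva, Xte = scaler.transform(Xtr), scaler.transform(Xva), scaler.transform(Xte)

    if task.kind == "regression":
        if np.allclose(ytr, ytr[0]):
            raise ValueError("training labels are constant")
        best = None
        for alpha in REGULARIZATION_GRID:
            model = Ridge(alpha=alpha).fit(Xtr, ytr)
            pred = model.predict(Xva)
            r = _safe_pearson(yva, pred)
            if best is None or r > best[0]:
                best = (r, model)
        pred = best[1].predict(Xte)
        return _safe_pearson(yte, pred)

    classes = np.unique(ytr)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    best = None
    for c in REGULARIZATION_GRID:
        model = LogisticRegression(C=c, max_iter=500, random_state=seed).fit(Xtr, ytr)
        score = _auprc(yva, model.predict_proba(Xva), model.classes_)
        if best is None or score > best[0]:
            best = (score, model)
    return _auprc(yte, best[1].predict_proba(Xte), best[1].classes_)


def _safe_pearson(y: np.ndarray, pred: np.ndarray) -> float:
    if np.std(pred) < 1e-12 or np.std(y) < 1e-12:
        return 0.0
    return float(stats.pearsonr(y, pred).statistic)


# ---------------------------------------------------------------------------
# ablation statistics
# ---------------------------------------------------------------------------

def fisher_z(r: float) -> float:
    """Variance-stabilizing transform of a correlation: arctanh(r)."""
    if not -1.0 < r < 1.0:
        raise ValueError("Fisher transform requires |r| < 1")
    return float(np.arctanh(r))


def zscore_normalize(
    results: Sequence[ProbeResult],
) -> ZScoreTable:
    """Normalize probe scores per task against the pooled reference distribution."""
    by_task: dict[str, list[ProbeResult]] = {}
    for r in results:
        by_task.setdefault(r.task, []).append(r)
    if len({r.config_id for r in results}) < 2:
        raise ValueError("Z normalization needs at least 2 configurations")
    task_mu: dict[str, float] = {}
    task_sigma: dict[str, float] = {}
    per_config_task: dict[tuple[str, str], float] = {}
    config_tasks: dict[str, list[float]] = {}
    for task, rs in by_task.items():
        kinds = {r.kind for r in rs}
        if len(kinds) != 1:
            raise ValueError(f"mixed result kinds for task {task!r}")
        kind = kinds.pop()
        transform = fisher_z if kind == "regression" else float

        def _tf(scores):
            return np.array([transform(s) for s in scores])

        pooled = np.concatenate([_tf(r.scores) for r in rs])
        if any(r.n_seeds < 2 for r in rs):
            raise ValueError("each configuration needs at least 2 seeds")
        mu = float(pooled.mean())
        sigma = float(pooled.std())
        if sigma == 0.0:
            raise ValueError(f"pooled scores for task {task!r} have zero variance")
        task_mu[task], task_sigma[task] = mu, sigma
        for r in rs:
            z = float(np.mean((_tf(r.scores) - mu) / sigma))
            per_config_task[(r.config_id, task)] = z
            config_tasks.setdefault(r.config_id, []).append(z)
    aggregate = {c: float(np.mean(zs)) for c, zs in config_tasks.items()}
    return ZScoreTable(task_mu, task_sigma, per_config_task, aggregate)


def welch_one_sided(
    reference: Sequence[float], candidate: Sequence[float], paired: bool = False
) -> float:
    """p-value for the alternative "reference mean > candidate mean".

    Unequal-variance (Welch) t-test with Satterthwaite degrees of freedom by
    default; ``paired`` switches to a paired t-test (samples paired by seed).
    """
    ref = np.asarray(reference, float)
    cand = np.asarray(candidate, float)
    if ref.size < 2 or cand.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(ref) == 0.0 and np.std(cand) == 0.0:
        if np.isclose(ref.mean(), cand.mean()):
            return 0.5
        return 0.0 if ref.mean() > cand.mean() else 1.0
    if paired:
        res = stats.ttest_rel(ref, cand, alternative="greater")
    else:
        res = stats.ttest_ind(ref, cand, equal_var=False, alternative="greater")
    return float(res.pvalue)


def top_tier_flags(
    results: Sequence[ProbeResult], reference_config: str, paired: bool = False
) -> dict[tuple[str, str], bool]:
    """Per (config, task): True when not significantly below the reference
    (one-sided Welch p > 0.05)."""
    by_task: dict[str, dict[str, ProbeResult]] = {}
    for r in results:
        by_task.setdefault(r.task, {})[r.config_id] = r
    flags: dict[tuple[str, str], bool] = {}
    for task, configs in by_task.items():
        if reference_config not in configs:
            raise ValueError(f"reference config missing for task {task!r}")
        ref_scores = configs[reference_config].scores
        for cid, r in configs.items():
            p = welch_one_sided(ref_scores, r.scores, paired=paired)
            flags[(cid, task)] = bool(p > 0.05)
    return flags
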