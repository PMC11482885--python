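"""Probing harness and ablation statistics."""

import numpy as np
import pytest

from rnaclr.probing import (
    ProbeResult,
    ProbeTask,
    REGULARIZATION_GRID,
    few_shot_subsample,
    fisher_z,
    fit_linear_probe,
    homology_split,
    top_tier_flags,
    welch_one_sided,
    zscore_normalize,
)


class TestHomologySplit:
    def _ids(self, n_fam=10, size=10):
        ids = [f"f{f}_t{i}" for f in range(n_fam) for i in range(size)]
        fams = {t: int(t.split("_")[0][1:]) for t in ids}
        return ids, fams

    def test_80_10_10_family_counts(self):
        ids, fams = self._ids()
        tr, va, te = homology_split(ids, fams, (0.8, 0.1, 0.1), seed=0)
        fam_of = lambda part: {fams[t] for t in part}
        assert (len(fam_of(tr)), len(fam_of(va)), len(fam_of(te))) == (8, 1, 1)

    def test_no_family_straddles_partitions(self):
        ids, fams = self._ids(n_fam=13, size=7)
        for seed in range(200):
            tr, va, te = homology_split(ids, fams, seed=seed)
            sets = [{fams[t] for t in p} for p in (tr, va, te)]
            assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
            assert sorted(tr + va + te) == sorted(ids)

    def test_seeds_change_assignment_not_sizes(self):
        ids, fams = self._ids()
        s1 = homology_split(ids, fams, seed=1)
        s2 = homology_split(ids, fams, seed=2)
        assert [len(p) for p in s1] == [len(p) for p in s2]
        assert s1 != s2
        assert homology_split(ids, fams, seed=1) == s1

    def test_fraction_validation(self):
        ids, fams = self._ids()
        with pytest.raises(ValueError):
            homology_split(ids, fams, (0.5, 0.2, 0.2))


class TestFewShot:
    def test_subsample_properties(self):
        train = [f"t{i}" for i in range(1000)]
        sub = few_shot_subsample(train, 30, seed=3)
        assert len(sub) == 30 and len(set(sub)) == 30
        assert few_shot_subsample(train, 30, seed=3) == sub
        assert few_shot_subsample(train, 1000, seed=0) == train

    def test_oversample_rejected(self):
        with pytest.raises(ValueError):
            few_shot_subsample(["a"], 2)


class TestLinearProbe:
    def _task_and_embeddings(self, n=600, d=16, kind="regression", seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"t{i}" for i in range(n)]
        emb = {t: rng.normal(size=d) for t in ids}
        fams = {t: i % 40 for i, t in enumerate(ids)}
        w = rng.normal(size=d)
        if kind == "regression":
            labels = {t: float(w @ emb[t]) for t in ids}
        else:
            labels = {t: int(w @ emb[t] > 0) for t in ids}
        return ids, emb, ProbeTask("toy", kind, labels, fams)

    def test_linear_labels_are_recovered(self):
        ids, emb, task = self._task_and_embeddings()
        split = homology_split(ids, task.families, seed=0)
        assert fit_linear_probe(emb, task, split) >= 0.999

    def test_permuted_labels_probe_to_chance(self):
        ids, emb, task = self._task_and_embeddings(n=1000)
        rng = np.random.default_rng(1)
        vals = list(task.labels.values())
        rng.shuffle(vals)
        task.labels = dict(zip(task.labels.keys(), vals))
        split = homology_split(ids, task.families, seed=0)
        assert abs(fit_linear_probe(emb, task, split)) < 0.1

    def test_separable_classification(self):
        ids, emb, task = self._task_and_embeddings(kind="classification")
        split = homology_split(ids, task.families, seed=0)
        assert fit_linear_probe(emb, task, split) >= 0.99

    def test_constant_labels_rejected(self):
        ids, emb, task = self._task_and_embeddings()
        task.labels = {t: 1.0 for t in task.labels}
        split = homology_split(ids, task.families, seed=0)
        with pytest.raises(ValueError):
            fit_linear_probe(emb, task, split)

    def test_overlapping_split_rejected(self):
        ids, emb, task = self._task_and_embeddings(n=30)
        with pytest.raises(ValueError):
            fit_linear_probe(emb, task, (ids[:20], ids[15:25], ids[25:]))

    def test_grid_has_seven_strengths(self):
        assert len(REGULARIZATION_GRID) == 7


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.71) == pytest.approx(0.8872, abs=1e-4)

    def test_odd_function(self):
        for r in (0.1, 0.5, 0.9):
            assert fisher_z(-r) == -fisher_z(r)

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestZScores:
    def test_hand_pooled_two_config_example(self):
        results = [
            ProbeResult("taskA", "cfg1", "classification", [0.6, 0.8]),
            ProbeResult("taskA", "cfg2", "classification", [0.2, 0.4]),
        ]
        table = zscore_normalize(results)
        assert table.task_mu["taskA"] == pytest.approx(0.5)
        assert table.task_sigma["taskA"] == pytest.approx(0.2236, abs=1e-4)
        assert table.per_config_task[("cfg1", "taskA")] == pytest.approx(0.8944, abs=1e-4)
        assert table.per_config_task[("cfg2", "taskA")] == pytest.approx(-0.8944, abs=1e-4)

    def test_pooled_reference_normalizes_to_standard(self):
        rng = np.random.default_rng(0)
        results = [
            ProbeResult("t", f"cfg{i}", "regression", list(rng.uniform(0.1, 0.9, 10)))
            for i in range(4)
        ]
        table = zscore_normalize(results)
        pooled = np.concatenate(
            [np.arctanh(np.array(r.scores)) for r in results]
        )
        z = (pooled - table.task_mu["t"]) / table.task_sigma["t"]
        assert abs(z.mean()) < 1e-9
        assert abs(z.var() - 1.0) < 1e-9

    def test_score_at_mean_and_one_sigma(self):
        results = [
            ProbeResult("t", "a", "classification", [0.3, 0.5]),
            ProbeResult("t", "b", "classification", [0.4, 0.4]),
        ]
        table = zscore_normalize(results)
        mu, sigma = table.task_mu["t"], table.task_sigma["t"]
        assert ((0.4 - mu) / sigma) == pytest.approx(0.0)

    def test_regression_scores_are_fisher_transformed_first(self):
        results = [
            ProbeResult("t", "a", "regression", [0.6, 0.8]),
            ProbeResult("t", "b", "regression", [0.2, 0.4]),
        ]
        table = zscore_normalize(results)
        pooled = np.arctanh([0.6, 0.8, 0.2, 0.4])
        assert table.task_mu["t"] == pytest.approx(pooled.mean())

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize([ProbeResult("t", "a", "classification", [0.5, 0.5])])
        same = [
            ProbeResult("t", "a", "classification", [0.5, 0.5]),
            ProbeResult("t", "b", "classification", [0.5, 0.5]),
        ]
        with pytest.raises(ValueError):
            zscore_normalize(same)


class TestWelch:
    def test_identical_samples_give_half(self):
        assert welch_one_sided([0.6, 0.8], [0.6, 0.8]) == pytest.approx(0.5)

    def test_clear_separation(self):
        rng = np.random.default_rng(0)
        ref = 1.0 + 0.01 * rng.normal(size=10)
        cand = 0.0 + 0.01 * rng.normal(size=10)
        assert welch_one_sided(ref, cand) < 1e-6

    def test_one_sided_direction(self):
        rng = np.random.default_rng(0)
        ref = 0.0 + 0.01 * rng.normal(size=10)
        cand = 1.0 + 0.01 * rng.normal(size=10)
        assert welch_one_sided(ref, cand) > 0.5

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            welch_one_sided([1.0], [0.0, 0.1])

    def test_top_tier_flags(self):
        rng = np.random.default_rng(2)
        results = [
            ProbeResult("t", "ref", "classification", list(0.8 + 0.01 * rng.normal(size=10))),
            ProbeResult("t", "good", "classification", list(0.8 + 0.01 * rng.normal(size=10))),
            ProbeResult("t", "bad", "classification", list(0.2 + 0.01 * rng.normal(size=10))),
        ]
        flags = top_tier_flags(results, "ref")
        assert flags[("ref", "t")] and flags[("good", "t")]
        assert not flags[("bad", "t")]
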