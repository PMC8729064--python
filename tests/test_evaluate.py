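"""Fold plans, confusion metrics, ROC/PR curves and the CV drivers."""

import numpy as np
import pytest
from scipy.stats import rankdata

from hetrwr import RunConfig, cross_validate, curves_and_areas, lambda_sweep, make_folds
from hetrwr.evaluate import (
    ScoredPairs,
    audit_no_leakage,
    confusion,
    metrics,
    novel_entity_protocol,
    run_fold,
)


def mann_whitney_auc(scores, labels):
    """Independent oracle: tie-corrected rank-sum normalization."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    ranks = rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


class TestFolds:
    def test_ten_singletons(self):
        pairs = np.c_[np.arange(10), np.arange(10)]
        plan = make_folds(pairs, 10, 0)
        assert sorted(len(f) for f in plan.folds) == [1] * 10

    def test_balanced_sizes_for_23_pairs(self):
        pairs = np.c_[np.arange(23), np.zeros(23, int)]
        plan = make_folds(pairs, 10, 0)
        assert sorted((len(f) for f in plan.folds), reverse=True) == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_partition_property(self):
        pairs = np.c_[np.arange(37), np.arange(37) % 5]
        plan = make_folds(pairs, 10, 3)
        seen = np.concatenate(plan.folds)
        assert sorted(seen) == list(range(37))

    def test_deterministic_under_seed(self):
        pairs = np.c_[np.arange(30), np.arange(30) % 4]
        a = make_folds(pairs, 10, 7)
        b = make_folds(pairs, 10, 7)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_errors(self):
        pairs = np.c_[np.arange(5), np.arange(5)]
        with pytest.raises(ValueError):
            make_folds(pairs, 10, 0)
        with pytest.raises(ValueError):
            make_folds(pairs, 1, 0)


class TestConfusionAndRates:
    scored = ScoredPairs(
        np.array([0, 1]), np.array([0, 0]), np.array([0.9, 0.4]), np.array([1, 0])
    )

    def test_threshold_between_scores(self):
        assert confusion(self.scored, 0.5) == (1, 0, 0, 1)

    def test_threshold_below_all(self):
        tp, fn, fp, tn = confusion(self.scored, 0.0)
        assert (fn, tn) == (0, 0) and (tp, fp) == (1, 1)

    def test_threshold_above_all(self):
        tp, fn, fp, tn = confusion(self.scored, 1.0)
        assert (tp, fp) == (0, 0) and (fn, tn) == (1, 1)

    def test_rates_arithmetic(self):
        r = metrics(3, 1, 2, 4)
        assert r.tpr == pytest.approx(0.75)
        assert r.fpr == pytest.approx(1 / 3)
        assert r.precision == pytest.approx(0.6)

    def test_perfect_point(self):
        r = metrics(5, 0, 0, 7)
        assert (r.tpr, r.fpr, r.precision) == (1.0, 0.0, 1.0)

    def test_undefined_rates_marked(self):
        r = metrics(0, 0, 1, 1)
        assert r.tpr is None and r.fpr == 0.5


class TestCurves:
    def test_perfect_separation(self):
        cp = curves_and_areas(np.array([0.9, 0.1]), np.array([1, 0]))
        assert cp.auc == 1.0 and cp.aupr == 1.0

    def test_interleaved_scores(self):
        cp = curves_and_areas(np.array([0.8, 0.7, 0.6, 0.5]), np.array([1, 0, 1, 0]))
        assert cp.auc == pytest.approx(0.75, abs=1e-12)

    def test_roc_endpoints(self):
        rng = np.random.default_rng(0)
        cp = curves_and_areas(rng.random(50), rng.integers(0, 2, 50))
        assert (cp.fpr[0], cp.tpr[0]) == (0.0, 0.0)
        assert (cp.fpr[-1], cp.tpr[-1]) == (1.0, 1.0)

    def test_equals_mann_whitney_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(10, 80)
            scores = rng.integers(0, 10, n) / 10  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            cp = curves_and_areas(scores, labels)
            assert cp.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            curves_and_areas(np.array([0.1, 0.2]), np.array([1, 1]))


class TestFoldRuns:
    def test_empty_fold_scores_full_data_with_no_positives(self, benchmark, builder, config):
        scored = run_fold(benchmark.data, np.empty((0, 2), int), config, builder)[config.lam]
        assert len(scored) == 0

    def test_within_community_heldout_beats_cross_community_unknowns(
        self, benchmark, builder, config
    ):
        data = benchmark.data
        plan = make_folds(data.positive_pairs, 10, config.seed)
        scored = run_fold(data, plan.fold_pairs(0), config, builder)[config.lam]
        l_comm = benchmark.communities["lncRNA"][scored.lnc_idx]
        d_comm = benchmark.communities["disease"][scored.dis_idx]
        within_pos = (scored.labels == 1) & (l_comm == d_comm)
        cross_unknown = (scored.labels == 0) & (l_comm != d_comm)
        assert scored.scores[within_pos].mean() > scored.scores[cross_unknown].mean()

    def test_no_leakage_audit(self, benchmark, config):
        plan = make_folds(benchmark.data.positive_pairs, 10, config.seed)
        assert audit_no_leakage(benchmark.data, plan) is True


class TestCVDrivers:
    def test_deterministic_and_consistent_with_sweep(self, benchmark, builder, config):
        data = benchmark.data
        a = cross_validate(data, config, k=4, seed=5, builder=builder)[config.lam]
        b = cross_validate(data, config, k=4, seed=5, builder=builder)[config.lam]
        assert a.mean_auc == pytest.approx(b.mean_auc, abs=1e-12)
        sweep = lambda_sweep(data, [config.lam], config, k=4, seed=5)
        assert len(sweep) == 1
        assert sweep["auc"].iloc[0] == pytest.approx(a.mean_auc, abs=1e-12)

    def test_sweep_one_row_per_grid_point(self, benchmark, builder, config):
        table = lambda_sweep(benchmark.data, [0.3, 0.7], config, k=3, seed=1)
        assert list(table["lambda"]) == [0.3, 0.7]
        assert (table["auc"] > 0.5).all()

    def test_sweep_rejects_bad_grid(self, benchmark, config):
        with pytest.raises(ValueError):
            lambda_sweep(benchmark.data, [0.0, 0.5], config)


class TestNovelEntity:
    def test_ranking_covers_opposite_layer_without_using_truth(
        self, benchmark, builder, config
    ):
        data = benchmark.data
        disease = data.registry("disease").ids[0]
        df = novel_entity_protocol(data, disease, "disease", config, builder)
        assert len(df) == data.n("lncRNA")
        assert set(df["lncRNA"]) == set(data.registry("lncRNA").ids)
        d_idx = data.registry("disease").index(disease)
        truth = {
            data.registry("lncRNA").ids[i] for i in np.flatnonzero(data.ld[:, d_idx])
        }
        flagged = set(df.loc[df.was_associated, "lncRNA"])
        assert flagged == truth  # ground-truth flags only; walk never saw them

    def test_lncrna_direction_ranks_diseases(self, benchmark, builder, config):
        data = benchmark.data
        lnc = data.registry("lncRNA").ids[3]
        df = novel_entity_protocol(data, lnc, "lncRNA", config, builder)
        assert len(df) == data.n("disease")
        assert (df["rank"] == np.arange(1, len(df) + 1)).all()

    def test_other_layers_rejected(self, benchmark, config):
        with pytest.raises(ValueError):
            novel_entity_protocol(benchmark.data, "GEN000", "gene", config)
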