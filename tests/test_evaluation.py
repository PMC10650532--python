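"""Metrics, cross-validation hygiene, Kruskal-Wallis, pipeline smoke runs."""

import math

import numpy as np
import pandas as pd
import pytest

from eegcrypt import (
    ConfusionCounts,
    PipelineConfig,
    compare_methods,
    compute_metrics,
    kruskal_wallis,
    run_pipeline,
    stratified_kfold,
)


def kw_oracle(groups):
    """Independent rank-sum Kruskal-Wallis (no ties in inputs used)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert all(v == 100.0 for v in m.values())

    def test_hand_computed_values(self):
        m = compute_metrics(ConfusionCounts(tp=40, fp=5, tn=45, fn=10))
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert m["precision"] == pytest.approx(100 * 40 / 45)
        assert m["f1"] == pytest.approx(100 * 2 * (40 / 45) * 0.8 / (40 / 45 + 0.8))

    def test_undefined_precision_flagged_nan(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert math.isnan(m["precision"])
        assert m["specificity"] == 100.0

    def test_f1_harmonic_identity_on_random_counts(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            expected = 2 * m["precision"] * m["sensitivity"] / (m["precision"] + m["sensitivity"])
            assert m["f1"] == pytest.approx(expected, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestStratifiedKfold:
    def test_partition_and_fold_sizes(self):
        labels = np.repeat(["a", "b"], 50)
        folds = stratified_kfold(labels, 10, seed=0)
        assert folds.shape == (100,)
        for f in range(10):
            assert np.sum(folds == f) == 10

    def test_stratification_within_one_sample(self):
        labels = np.repeat(["a", "b", "c"], 30)
        folds = stratified_kfold(labels, 5, seed=1)
        for f in range(5):
            sel = labels[folds == f]
            counts = [np.sum(sel == c) for c in "abc"]
            assert max(counts) - min(counts) <= 1

    def test_seeded_determinism(self):
        labels = np.repeat(["a", "b"], 20)
        assert np.array_equal(
            stratified_kfold(labels, 4, seed=9), stratified_kfold(labels, 4, seed=9)
        )

    def test_no_train_test_overlap(self):
        labels = np.repeat(["a", "b"], 25)
        folds = stratified_kfold(labels, 5, seed=2)
        for f in range(5):
            assert not set(np.flatnonzero(folds == f)) & set(np.flatnonzero(folds != f))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            stratified_kfold(["a"] * 20 + ["b"] * 3, 5)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_rank_sum_oracle_no_ties(self):
        groups = [np.array([1.0, 2, 3]), np.array([10.0, 11, 12])]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_oracle(groups), abs=1e-9)

    def test_matches_oracle_three_groups(self, rng):
        # distinct values so the tie correction is a no-op
        vals = rng.permutation(np.arange(1.0, 16.0))
        groups = [vals[:5], vals[5:10], vals[10:]]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_oracle(groups), abs=1e-9)

    def test_identical_singletons_convention(self):
        h, p = kruskal_wallis([[5.0], [5.0], [5.0]])
        assert (h, p) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


def tiny_pipeline_config(**overrides):
    base = dict(
        n_per_class=12,
        segment_lengths_s=(1.0,),
        image_side=16,
        baker_partition=(4, 8, 4),
        baker_iterations=1,
        arnold_iterations=2,
        n_members=1,
        epochs=2,
        k_folds=3,
        hso_m=4,
        hso_iterations=5,
        seed=0,
    )
    base.update(overrides)
    return PipelineConfig(**base)


class TestRunPipeline:
    def test_report_shape_and_ranges(self, tmp_path):
        res = run_pipeline(tiny_pipeline_config(), out_dir=tmp_path)[1.0]
        assert res.report.per_fold.shape == (3, 5)
        vals = res.report.per_fold.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert np.all((finite >= 0) & (finite <= 100))
        assert (tmp_path / "metrics_summary.csv").exists()
        assert list((tmp_path).glob("sample_*.png"))

    def test_mean_matches_per_fold_mean(self):
        res = run_pipeline(tiny_pipeline_config())[1.0]
        assert np.allclose(
            res.report.mean.to_numpy(), res.report.per_fold.mean().to_numpy(), atol=1e-9
        )

    def test_end_to_end_determinism(self):
        a = run_pipeline(tiny_pipeline_config())[1.0]
        b = run_pipeline(tiny_pipeline_config())[1.0]
        pd.testing.assert_frame_equal(a.report.per_fold, b.report.per_fold)

    def test_encryption_toggle_changes_inputs_not_protocol(self):
        enc = run_pipeline(tiny_pipeline_config())[1.0]
        plain = run_pipeline(tiny_pipeline_config(encrypt=False))[1.0]
        assert enc.report.per_fold.shape == plain.report.per_fold.shape
        assert enc.method != plain.method

    def test_folds_partition_dataset(self):
        res = run_pipeline(tiny_pipeline_config())[1.0]
        folds = res.fold_assignment
        assert folds.shape == (36,)
        assert set(np.unique(folds)) == {0, 1, 2}


class TestCompareMethods:
    @staticmethod
    def _result(values, method="m"):
        from eegcrypt.evaluation import METRIC_NAMES, CVResult, MetricsReport

        values = np.asarray(values, dtype=float)
        per_fold = pd.DataFrame(
            np.tile(values[:, None], (1, 5)), columns=list(METRIC_NAMES)
        )
        return CVResult(
            segment_length_s=4.0,
            method=method,
            fold_assignment=np.arange(len(values)),
            report=MetricsReport(per_fold),
        )

    def test_self_comparison_is_null(self):
        r = self._result(np.linspace(90, 95, 10))
        table = compare_methods([r, r])
        assert np.allclose(table["H"], 0.0)
        assert not table["significant"].any()

    def test_disjoint_ranges_significant(self):
        a = self._result(np.linspace(80, 84, 10), "a")
        b = self._result(np.linspace(95, 99, 10), "b")
        table = compare_methods([a, b])
        assert table["significant"].all()
        h, _ = kruskal_wallis([a.report.per_fold["accuracy"], b.report.per_fold["accuracy"]])
        assert np.allclose(table["H"], h)

    def test_mismatched_fold_counts_rejected(self):
        with pytest.raises(ValueError, match="fold count"):
            compare_methods([self._result(np.arange(10.0)), self._result(np.arange(8.0))])

    def test_single_result_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([self._result(np.full(10, 90.0))])
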