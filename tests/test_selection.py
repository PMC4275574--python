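import numpy as np
import pytest

import sparseconn as sc
from sparseconn.selection import (_snap_down, _snap_up, make_losgo_folds,
                                  mean_stability, pairwise_overlap,
                                  selection_distance)


class TestFoldPlan:
    @pytest.mark.parametrize("n_s", [2, 19, 30])
    def test_one_fold_per_subject_pair(self, n_s):
        labels = np.array([1] * n_s + [-1] * n_s)
        plan = make_losgo_folds(labels)
        assert plan.n_folds == n_s
        held_out = [i for p in plan.pairs for i in p]
        assert sorted(held_out) == list(range(2 * n_s))
        for p, c in plan.pairs:
            assert labels[p] == 1 and labels[c] == -1

    def test_pairing_follows_sorted_subject_ids(self):
        labels = [1, -1, 1, -1]
        ids = ["p2", "c1", "p1", "c2"]
        plan = make_losgo_folds(labels, ids)
        assert plan.pairs == [(2, 1), (0, 3)]  # p1<->c1, p2<->c2

    def test_unbalanced_groups_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            make_losgo_folds([1, 1, -1])


class TestOverlap:
    def test_identical_supports(self):
        I = np.arange(10)
        assert pairwise_overlap(I, I, 100) == pytest.approx(0.9)

    def test_disjoint_supports(self):
        assert pairwise_overlap(np.arange(5), np.arange(5, 10), 50) == \
            pytest.approx(-0.1)

    def test_empty_handling(self):
        assert pairwise_overlap(np.array([]), np.arange(3), 10) == 0.0
        with pytest.warns(UserWarning):
            assert pairwise_overlap(np.array([]), np.array([]), 10) == 0.0
        with pytest.raises(ValueError):
            pairwise_overlap(np.arange(2), np.arange(2), 0)

    def test_random_supports_are_chance_corrected(self):
        # expectation of the overlap of random supports is zero by design
        rng = np.random.default_rng(42)
        q, k = 100, 10
        vals = []
        for _ in range(10_000):
            a = rng.choice(q, k, replace=False)
            b = rng.choice(q, k, replace=False)
            vals.append(pairwise_overlap(a, b, q))
        assert abs(np.mean(vals)) < 0.01

    def test_mean_stability_identical_supports(self):
        sup = [np.arange(7)] * 4
        assert mean_stability(sup, 70) == pytest.approx(1 - 7 / 70)

    def test_mean_stability_two_folds_equals_pairwise(self, rng):
        a = rng.choice(50, 8, replace=False)
        b = rng.choice(50, 12, replace=False)
        assert mean_stability([a, b], 50) == \
            pytest.approx(pairwise_overlap(a, b, 50))

    def test_mean_stability_matches_double_loop(self, rng):
        sups = [rng.choice(40, rng.integers(3, 10), replace=False)
                for _ in range(5)]
        acc = n = 0
        for s in range(5):
            for t in range(5):
                if s != t:
                    acc += pairwise_overlap(sups[s], sups[t], 40)
                    n += 1
        assert mean_stability(sups, 40) == pytest.approx(acc / n)

    def test_needs_two_supports(self):
        with pytest.raises(ValueError):
            mean_stability([np.arange(3)], 10)


class TestSelectionDistance:
    @pytest.mark.parametrize("acc,stab,expect", [
        (1.0, 1.0, 0.0),
        (0.5, 0.5, np.sqrt(0.5)),
        (1.0, 0.0, 1.0),
    ])
    def test_worked_examples(self, acc, stab, expect):
        assert selection_distance(acc, stab) == pytest.approx(expect)


class TestSnapRules:
    def test_median_between_C_grid_points_snaps_down(self):
        assert _snap_down(5.5, (0.1, 1.0, 10.0)) == 1.0
        assert _snap_down(10.0, (0.1, 1.0, 10.0)) == 10.0
        assert _snap_down(0.01, (0.1, 1.0)) == 0.1  # below grid -> smallest

    def test_lambda_snaps_up_toward_sparser(self):
        assert _snap_up(0.055, (0.001, 0.01, 0.1)) == 0.1
        assert _snap_up(0.01, (0.001, 0.01, 0.1)) == 0.01


class TestNestedCV:
    def test_strong_signal_recovered(self, signal_study, fast_config):
        data, _ = signal_study
        report = sc.nested_cv(data, fast_config)
        assert report.accuracy >= 80.0
        assert report.confusion.n == data.n_subjects
        assert 0 <= report.sparsity_mean <= 1

    def test_shuffled_labels_fall_to_chance(self, signal_study, fast_config):
        data, _ = signal_study
        rng = np.random.default_rng(0)
        shuffled = data.with_labels(rng.permutation(data.labels))
        report = sc.nested_cv(shuffled, fast_config)
        assert 20.0 <= report.accuracy <= 80.0

    def test_single_point_C_grid_degenerates(self, signal_study):
        data, _ = signal_study
        cfg = sc.PipelineConfig(C_grid=(1.0,), lambda_grid=(0.01,),
                                svm_tol=1e-4)
        report = sc.nested_cv(data, cfg)
        assert all(f.chosen_C == 1.0 for f in report.folds)
        assert np.isfinite(report.accuracy)

    def test_no_leakage_into_inner_folds(self, signal_study, fast_config):
        data, _ = signal_study
        report = sc.nested_cv(data, fast_config)
        for f in report.folds:
            for inner in f.inner_train_sets:
                assert f.test_idx[0] not in inner
                assert f.test_idx[1] not in inner

    def test_deterministic_given_inputs(self, signal_study, fast_config):
        data, _ = signal_study
        a = sc.nested_cv(data, fast_config)
        b = sc.nested_cv(data, fast_config)
        assert a.chosen_Cs == b.chosen_Cs
        np.testing.assert_array_equal(a.y_pred, b.y_pred)
        assert a.accuracy == b.accuracy

    def test_identical_fold_models_give_one_minus_sparsity(self):
        # duplicate subjects: every fold trains on the same two distinct
        # patterns, so all fold models agree and outer stability = 1 - k/q
        rng = np.random.default_rng(5)
        q = 45
        proto = np.zeros(q)
        proto[:4] = [2.0, -2.0, 1.5, 1.0]
        X = np.vstack([proto + 0 for _ in range(4)]
                      + [-proto for _ in range(4)])
        labels = [1] * 4 + [-1] * 4
        data = sc.StudyData.from_features(X, labels)
        cfg = sc.PipelineConfig(C_grid=(10.0,), lambda_grid=(0.01,),
                                feature_kind="sparse_inverse_covariance")
        report = sc.nested_cv(data, cfg)
        k = report.folds[0].support.size
        assert k > 0
        assert report.outer_support_stability == pytest.approx(1 - k / q)

    def test_two_plus_two_subjects_well_formed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(4, 10))
        X[:2, 0] += 4.0
        data = sc.StudyData.from_features(X, [1, 1, -1, -1])
        cfg = sc.PipelineConfig(C_grid=(1.0, 10.0), lambda_grid=(0.01,))
        report = sc.nested_cv(data, cfg)
        assert len(report.folds) == 2
        assert np.isfinite(report.accuracy)


class TestRefit:
    def test_unanimous_parameters_kept(self, signal_study, fast_config):
        data, _ = signal_study
        report = sc.nested_cv(data, fast_config)
        model, lam = sc.refit_final(data, fast_config, report)
        assert model.C in fast_config.C_grid
        assert lam == 0.01
        assert model.penalty == "l1"

    def test_median_between_grid_points_snaps_sparser(self, signal_study,
                                                      fast_config):
        data, _ = signal_study
        report = sc.nested_cv(data, fast_config)
        # an even split of C choices {1, 10} has median 5.5, off the grid;
        # the refit must snap to the sparser value 1
        report.folds = report.folds[:4]
        for f, c in zip(report.folds, (1.0, 1.0, 10.0, 10.0)):
            f.chosen_C = c
        model, _ = sc.refit_final(data, fast_config, report)
        assert model.C == 1.0

    def test_empty_report_rejected(self, signal_study, fast_config):
        data, _ = signal_study
        report = sc.nested_cv(data, fast_config)
        report.folds = []
        with pytest.raises(ValueError):
            sc.refit_final(data, fast_config, report)
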