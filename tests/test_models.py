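"""Classifier layer: splitting, training, evaluation, sweep, importance."""

import warnings

import numpy as np
import pandas as pd
import pytest

from corneadic.features import FeatureMatrix, assemble_feature_matrix
from corneadic.models import (
    MODEL_NAMES,
    SplitSpec,
    cross_validate,
    evaluate_bundle,
    feature_importance,
    split_cohort,
    timepoint_sweep,
    train_models,
)


def blob_matrix(n=40, d=6, sep=6.0, seed=0):
    """Two well-separated Gaussian blobs."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n // 2, d))
    X1 = rng.normal(sep, 1.0, size=(n // 2, d))
    X = pd.DataFrame(
        np.vstack([X0, X1]),
        columns=[f"f@{i}" for i in range(d)],
        index=pd.Index([f"e{i}" for i in range(n)], name="exam_id"),
    )
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return FeatureMatrix(X=X, y=y, curve_subset=("f",), k=d)


@pytest.fixture(scope="module")
def cohort_matrix(frozen_cohort):
    return assemble_feature_matrix(frozen_cohort)


class TestSplitCohort:
    def test_eighty_twenty_split(self, cohort_matrix):
        train, val = split_cohort(cohort_matrix, SplitSpec(seed=0))
        assert train.n_samples == 80 and val.n_samples == 20

    def test_stratification_balances_classes(self, cohort_matrix):
        _, val = split_cohort(cohort_matrix, SplitSpec(seed=0))
        assert val.y.sum() == 10  # 10 of each class in the 20-exam validation set

    def test_deterministic_under_seed(self, cohort_matrix):
        a = split_cohort(cohort_matrix, SplitSpec(seed=3))
        b = split_cohort(cohort_matrix, SplitSpec(seed=3))
        assert list(a[0].X.index) == list(b[0].X.index)
        assert list(a[1].X.index) == list(b[1].X.index)

    def test_partition_is_disjoint_and_complete(self, cohort_matrix):
        train, val = split_cohort(cohort_matrix, SplitSpec(seed=1))
        ids = set(train.X.index) | set(val.X.index)
        assert len(ids) == 100 and not (set(train.X.index) & set(val.X.index))

    def test_too_small_class_rejected(self):
        fm = blob_matrix(n=40)
        fm.y[:] = 0
        fm.y[0] = 1
        with pytest.raises(ValueError):
            split_cohort(fm, SplitSpec(seed=0))


class TestTrainModels:
    def test_separable_blobs_rf_training_accuracy_one(self):
        fm = blob_matrix()
        bundle = train_models(fm, seed=0)
        rep = evaluate_bundle(bundle, fm, dataset="training")
        assert rep["random_forest"].accuracy == 1.0

    def test_training_twice_is_deterministic(self, cohort_matrix):
        train, val = split_cohort(cohort_matrix, SplitSpec(seed=0))
        pa = train_models(train, seed=5).predict_proba(val.X)
        pb = train_models(train, seed=5).predict_proba(val.X)
        for name in MODEL_NAMES:
            assert np.array_equal(pa[name], pb[name])

    def test_nb_invariant_under_row_duplication(self):
        """NB fits sufficient statistics, so duplicating every row changes
        nothing (the penalised models and the bootstrap forest do not share
        this invariance)."""
        fm = blob_matrix(n=30, sep=3.0, seed=4)
        dup = FeatureMatrix(
            X=pd.concat([fm.X, fm.X.set_index(fm.X.index + "_dup")]),
            y=np.r_[fm.y, fm.y],
            curve_subset=fm.curve_subset,
            k=fm.k,
        )
        probe = blob_matrix(n=20, sep=3.0, seed=9)
        pa = train_models(fm, seed=0).predict_proba(probe.X)
        pb = train_models(dup, seed=0).predict_proba(probe.X)
        assert np.allclose(pa["naive_bayes"], pb["naive_bayes"], atol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        fm = blob_matrix()
        fm.X["f@0"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            bundle = train_models(fm, seed=0)
        assert "f@0" in bundle.dropped_columns
        assert "f@0" not in bundle.columns

    def test_single_class_rejected(self):
        fm = blob_matrix()
        fm.y[:] = 1
        with pytest.raises(ValueError):
            train_models(fm, seed=0)

    def test_voting_is_exact_mean_of_members(self, cohort_matrix):
        train, val = split_cohort(cohort_matrix, SplitSpec(seed=0))
        p = train_models(train, seed=0).predict_proba(val.X)
        assert np.array_equal(p["voting"], 0.5 * (p["naive_bayes"] + p["random_forest"]))

    def test_no_leakage_scaler_fit_on_train_only(self, cohort_matrix):
        train, _ = split_cohort(cohort_matrix, SplitSpec(seed=0))
        bundle = train_models(train, seed=0)
        cols = bundle.columns
        assert np.allclose(bundle.scaler.mean_, train.X[cols].mean(axis=0), atol=1e-9)
        assert not np.allclose(bundle.scaler.mean_, cohort_matrix.X[cols].mean(axis=0))


class TestEvaluateBundle:
    def test_perfect_and_tied_probabilities(self):
        fm = blob_matrix(sep=8.0)
        bundle = train_models(fm, seed=0)
        rep = evaluate_bundle(bundle, fm, dataset="training")
        assert rep["random_forest"].auc == 1.0
        assert rep["random_forest"].accuracy == 1.0

    def test_single_class_data_reports_missing_auc(self):
        fm = blob_matrix()
        bundle = train_models(fm, seed=0)
        pos = FeatureMatrix(fm.X[fm.y == 1], fm.y[fm.y == 1], fm.curve_subset, fm.k)
        rep = evaluate_bundle(bundle, pos)
        assert rep["voting"].auc is None
        assert rep["voting"].recall is not None

    def test_report_fields_consistent_with_confusion(self, cohort_matrix):
        train, val = split_cohort(cohort_matrix, SplitSpec(seed=0))
        rep = evaluate_bundle(train_models(train, seed=0), val)["naive_bayes"]
        cm = rep.cm
        assert rep.accuracy == pytest.approx((cm.tp + cm.tn) / cm.total)
        assert rep.recall == rep.sensitivity
        if rep.precision and rep.recall:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            )


class TestCrossValidationAndSweep:
    def test_shuffled_labels_cv_auc_near_half(self, cohort_matrix):
        """Permuting labels destroys the signal: mean CV AUC inside the null band."""
        rng = np.random.default_rng(8)
        shuffled = FeatureMatrix(
            X=cohort_matrix.X,
            y=rng.permutation(cohort_matrix.y),
            curve_subset=cohort_matrix.curve_subset,
            k=cohort_matrix.k,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = cross_validate(shuffled, SplitSpec(seed=0))
        for name in MODEL_NAMES:
            assert 0.3 <= cv[name].mean() <= 0.7

    def test_no_signal_cohort_auc_near_half(self):
        """Identical class priors -> chance-level discrimination."""
        import corneadic.synthetic as syn

        priors = syn.CohortPriors(
            normal=syn.ClassPriors(), ffkc=syn.ClassPriors(), curve_noise_frac=0.15
        )
        cohort = syn.generate_cohort(50, 50, priors=priors, seed=42)
        fm = assemble_feature_matrix(cohort)
        cv = cross_validate(fm, SplitSpec(seed=0))
        for name in MODEL_NAMES:
            assert 0.3 <= cv[name].mean() <= 0.7

    def test_sweep_single_k_matches_standard_evaluation(self, frozen_cohort):
        table = timepoint_sweep(frozen_cohort, [140], seed=0)
        fm = assemble_feature_matrix(frozen_cohort, k=140)
        train, val = split_cohort(fm, SplitSpec(seed=0))
        rep = evaluate_bundle(train_models(train, seed=0), val)
        for name in MODEL_NAMES:
            assert table.loc[140, name] == pytest.approx(rep[name].auc)

    def test_empty_k_list_rejected(self, frozen_cohort):
        with pytest.raises(ValueError):
            timepoint_sweep(frozen_cohort, [], seed=0)


class TestFeatureImportance:
    def test_planted_signal_ranks_first(self, rng):
        n, d = 60, 8
        X = rng.normal(size=(n, d))
        y = (X[:, 3] > 0).astype(int)
        X[:, 3] += 2.0 * y  # make column 3 dominant
        fm = FeatureMatrix(
            X=pd.DataFrame(X, columns=[f"c@{i}" for i in range(d)],
                           index=pd.Index([f"e{i}" for i in range(n)], name="exam_id")),
            y=y,
            curve_subset=("c",),
            k=d,
        )
        bundle = train_models(fm, seed=0)
        ranking = feature_importance(bundle)
        assert ranking[0][0] == "c@3"
        assert sum(v for _, v in ranking) == pytest.approx(1.0)

    def test_repeat_run_identical_ranking(self, cohort_matrix):
        train, _ = split_cohort(cohort_matrix, SplitSpec(seed=0))
        a = feature_importance(train_models(train, seed=1))
        b = feature_importance(train_models(train, seed=1))
        assert a == b
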