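import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from somnocam.classify import (
    STAGES,
    Hypnogram,
    LabelError,
    Recording,
    aggregate_reports,
    cohens_kappa,
    confusion_counts,
    evaluate_fold,
    loocv,
    map_aasm_to_four,
    pca_projection,
    per_stage_metrics,
    predict,
    train,
)
from somnocam.features import FeatureMatrix, RAW_COLUMNS, Z_COLUMNS

STAGE_CENTERS = {"Wake": 6.0, "Light": 2.0, "Deep": -6.0, "REM": -2.0}


def separable_recording(rec_id, rng, n_epochs=120, age_group="group_0_2"):
    """Stages occupy disjoint boxes in feature space: trivially learnable."""
    stages = [STAGES[i % 4] for i in range(n_epochs)]
    rows = []
    for stage in stages:
        center = STAGE_CENTERS[stage]
        rows.append(center + rng.uniform(-0.5, 0.5, 6))
    df = pd.DataFrame(rows, columns=Z_COLUMNS)
    for col in RAW_COLUMNS:
        df[col] = df[col + "_z"]
    df.insert(0, "epoch_index", range(1, n_epochs + 1))
    return Recording(
        recording_id=rec_id,
        age_group=age_group,
        features=FeatureMatrix(df, recording_id=rec_id),
        hypnogram=Hypnogram(stages),
    )


@pytest.fixture
def cohort(rng):
    return [separable_recording(f"rec{i}", rng) for i in range(3)]


class TestStageMapping:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("W", "Wake"), ("N1", "Light"), ("N2", "Light"), ("N3", "Deep"),
            ("R", "REM"), ("n3", "Deep"), ("L", "Light"), ("rem", "REM"),
        ],
    )
    def test_aasm_collapse(self, token, expected):
        assert map_aasm_to_four(token) == expected

    def test_unknown_token_rejected(self):
        with pytest.raises(LabelError):
            map_aasm_to_four("N4")


class TestTrainPredict:
    def test_separable_stages_self_predict(self, cohort):
        model = train(cohort, seed=0)
        for rec in cohort:
            predicted = predict(model, rec.features)
            agreement = np.mean(np.array(predicted.stages) == np.array(rec.hypnogram.stages))
            assert agreement >= 0.99

    def test_deterministic_given_seed(self, cohort):
        p1 = predict(train(cohort, seed=7), cohort[0].features)
        p2 = predict(train(cohort, seed=7), cohort[0].features)
        assert p1.stages == p2.stages

    def test_two_stage_training_set_predicts_only_those(self, rng):
        rec = separable_recording("r", rng)
        mask = [s in ("Wake", "Deep") for s in rec.hypnogram.stages]
        df = rec.features.data[mask].reset_index(drop=True)
        rec2 = Recording(
            "r2", "group_0_2",
            FeatureMatrix(df, "r2"),
            Hypnogram([s for s in rec.hypnogram.stages if s in ("Wake", "Deep")]),
        )
        model = train([rec2], seed=0)
        predicted = predict(model, rec.features)
        assert set(predicted.stages) <= {"Wake", "Deep"}

    def test_prediction_is_row_wise(self, cohort):
        model = train(cohort, seed=0)
        features = cohort[0].features
        base = predict(model, features).stages
        perm = np.random.default_rng(0).permutation(len(features))
        shuffled = FeatureMatrix(
            features.data.iloc[perm].reset_index(drop=True), features.recording_id
        )
        assert predict(model, shuffled).stages == [base[i] for i in perm]

    def test_mixed_age_groups_rejected(self, rng):
        recs = [
            separable_recording("a", rng, age_group="group_0_2"),
            separable_recording("b", rng, age_group="group_3_6"),
        ]
        with pytest.raises(ValueError):
            train(recs)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([])


class TestMetrics:
    def test_diagonal_confusion_is_perfect(self):
        confusion = np.diag([10, 20, 30, 40])
        metrics = per_stage_metrics(confusion)
        for stage in STAGES:
            assert metrics[stage] == {
                "accuracy": 100.0, "sensitivity": 100.0, "specificity": 100.0,
            }
        assert cohens_kappa(confusion) == pytest.approx(1.0)

    def test_absent_reference_stage_flagged_nan(self):
        confusion = np.diag([10, 20, 0, 40])
        assert np.isnan(per_stage_metrics(confusion)["Deep"]["sensitivity"])

    def test_metrics_match_tally_oracle(self, rng):
        for _ in range(10):
            confusion = rng.integers(0, 50, (4, 4))
            metrics = per_stage_metrics(confusion)
            total = confusion.sum()
            for s, stage in enumerate(STAGES):
                tp = confusion[s, s]
                fn = sum(confusion[s, j] for j in range(4) if j != s)
                fp = sum(confusion[i, s] for i in range(4) if i != s)
                tn = total - tp - fn - fp
                assert metrics[stage]["accuracy"] == pytest.approx(100 * (tp + tn) / total)
                if tp + fn:
                    assert metrics[stage]["sensitivity"] == pytest.approx(100 * tp / (tp + fn))
                if tn + fp:
                    assert metrics[stage]["specificity"] == pytest.approx(100 * tn / (tn + fp))

    def test_negative_confusion_rejected(self):
        confusion = np.diag([1, 1, 1, -1])
        with pytest.raises(ValueError):
            per_stage_metrics(confusion)


class TestKappa:
    def test_independence_matrix_gives_zero(self):
        # outer product of marginals: observed agreement equals chance exactly
        confusion = np.outer([1, 2, 3, 4], [4, 3, 2, 1])
        assert cohens_kappa(confusion) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_on_random_labelings(self, rng):
        for _ in range(10):
            ref = rng.choice(STAGES, 200)
            est = rng.choice(STAGES, 200)
            confusion = confusion_counts(Hypnogram(list(ref)), Hypnogram(list(est)))
            assert cohens_kappa(confusion) == pytest.approx(
                cohen_kappa_score(ref, est), abs=1e-12
            )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.zeros((4, 4)))


class TestLoocv:
    def test_one_fold_per_recording_and_no_leakage(self, cohort):
        reports, aggregate = loocv(cohort, seed=0, n_trees=20)
        assert len(reports) == 3
        for report in reports:
            assert report.recording_id not in report.training_ids
            assert len(report.training_ids) == 2

    def test_separable_cohort_scores_high(self, cohort):
        reports, aggregate = loocv(cohort, seed=0, n_trees=20)
        for report in reports:
            assert report.total_accuracy >= 99.0

    def test_aggregate_equals_direct_recomputation(self, cohort):
        reports, aggregate = loocv(cohort, seed=0, n_trees=20)
        accs = [r.total_accuracy for r in reports]
        assert aggregate["total_accuracy"]["mean"] == pytest.approx(np.mean(accs))
        assert aggregate["total_accuracy"]["sd"] == pytest.approx(np.std(accs, ddof=1))
        assert aggregate == aggregate_reports(reports)

    def test_two_recordings_required(self, cohort):
        with pytest.raises(ValueError):
            loocv(cohort[:1])

    def test_confusion_conservation(self, cohort):
        reports, _ = loocv(cohort, seed=0, n_trees=20)
        for report, rec in zip(reports, cohort):
            assert report.confusion.sum() == len(rec.hypnogram)


class TestPca:
    def test_planar_data_fully_explained_by_two_components(self, rng):
        basis = rng.normal(size=(2, 6))
        data = rng.normal(size=(50, 2)) @ basis
        coords, explained = pca_projection(data)
        assert explained.sum() == pytest.approx(1.0)
        assert np.abs(coords.mean(axis=0)).max() < 1e-9

    def test_components_match_eigendecomposition_oracle(self, rng):
        data = rng.normal(size=(40, 6))
        coords, explained = pca_projection(data)
        centered = data - data.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(centered.T @ centered / len(data))
        order = np.argsort(eigvals)[::-1]
        np.testing.assert_allclose(
            explained, eigvals[order][:2] / eigvals.sum(), atol=1e-9
        )
        for j in range(2):
            oracle = centered @ eigvecs[:, order[j]]
            match = min(
                np.abs(coords[:, j] - oracle).max(),
                np.abs(coords[:, j] + oracle).max(),
            )
            assert match < 1e-9

    def test_rank_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_projection(np.ones((10, 6)))


class TestAlignment:
    def test_length_mismatch_trims_with_warning(self, rng):
        rec = separable_recording("r", rng, n_epochs=20)
        with pytest.warns(UserWarning, match="trimming"):
            trimmed = Recording(
                "r", "group_0_2", rec.features, Hypnogram(rec.hypnogram.stages[:15])
            )
        assert len(trimmed.features) == 15
        assert len(trimmed.hypnogram) == 15
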