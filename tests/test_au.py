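"""Two-step decoupling, feature preparation, classification, synthesis."""

import numpy as np
import pytest

from slcau import au
from slcau.au import (
    AUCoefficientRecord,
    FeaturePipeline,
    aggregate_coefficients,
    compute_au_prototype,
    fuse_features,
    loocv_evaluate,
    prepare_features,
    resample_neutral,
    synthesize_au,
    train_au_classifier,
)
from slcau.fitting import FitOptions
from slcau.meshio import RegisteredShape, delinearize
from slcau.synthetic import REGION_IDS, region_of_points, sample_identity


def make_records(rng, n_subjects=6, n_aus=3, dim=20, sep=4.0, noise=0.5):
    """Well-separated synthetic coefficient records (no fitting involved)."""
    centers = rng.normal(size=(n_aus, dim)) * sep
    records = []
    for s in range(n_subjects):
        for a in range(n_aus):
            vec = centers[a] + rng.normal(size=dim) * noise
            records.append(AUCoefficientRecord(f"s{s}", f"AU{a}", vec, 5, "m"))
    return records


class TestAggregation:
    def test_single_iteration_unchanged_under_every_strategy(self, rng):
        v = rng.normal(size=8)
        for strategy in ("mean", "max", "first", "threshold"):
            np.testing.assert_allclose(aggregate_coefficients([v], strategy), v)

    def test_opposite_vectors_cancel_under_mean(self, rng):
        v = rng.normal(size=8)
        np.testing.assert_allclose(aggregate_coefficients([v, -v], "mean"), 0.0, atol=1e-15)

    def test_mean_matches_arithmetic_oracle(self, rng):
        vs = [rng.normal(size=6) for _ in range(7)]
        np.testing.assert_allclose(
            aggregate_coefficients(vs, "mean"), np.mean(vs, axis=0), atol=1e-15
        )

    def test_max_keeps_sign_of_largest_magnitude(self):
        vs = [np.array([1.0, -3.0]), np.array([-2.0, 2.0])]
        np.testing.assert_array_equal(aggregate_coefficients(vs, "max"), [-2.0, -3.0])

    def test_threshold_zeroes_small_entries(self):
        vs = [np.array([0.0005, 1.0]), np.array([0.0004, 1.0])]
        out = aggregate_coefficients(vs, "threshold", threshold=1e-3)
        assert out[0] == 0.0 and out[1] == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_coefficients([])


class TestResampleNeutral:
    def test_identity_when_scan_equals_shape(self, rng):
        pts = rng.normal(size=(20, 3))
        s_n = RegisteredShape(pts.reshape(-1), "t")
        out = resample_neutral(s_n, pts)
        np.testing.assert_array_equal(out.vector, s_n.vector)

    def test_every_point_is_a_scan_vertex(self, rng):
        s_n = RegisteredShape(rng.normal(size=60), "t")
        scan = rng.normal(size=(100, 3))
        out = resample_neutral(s_n, scan)
        scan_set = {tuple(p) for p in scan}
        assert all(tuple(p) in scan_set for p in out.points)

    def test_empty_scan_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            resample_neutral(RegisteredShape(rng.normal(size=30), "t"), np.zeros((0, 3)))


class TestFeaturePipeline:
    def test_l2_normalization_unit_norm(self, rng):
        X = rng.normal(size=(10, 6)) * 5
        assert np.allclose(np.linalg.norm(FeaturePipeline._l2(X), axis=1), 1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            FeaturePipeline._l2(np.zeros((2, 4)))

    def test_training_features_standardized(self, rng):
        records = make_records(rng)
        X, pipe = prepare_features(records)
        Xs = pipe.scaler.transform(FeaturePipeline._l2(np.vstack([r.alpha_e for r in records])))
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Xs.var(axis=0), 1.0, atol=1e-8)

    def test_isotropic_gaussian_keeps_most_dimensions(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(400, 20))
        pipe = FeaturePipeline(0.95).fit(X)
        assert pipe.n_components >= 18
        assert pipe.explained_variance >= 0.95

    def test_mixed_model_ids_rejected(self, rng):
        records = make_records(rng)
        records[0].model_id = "other"
        with pytest.raises(ValueError, match="bases"):
            prepare_features(records)


class TestFusion:
    def test_dimensions_concatenate(self, rng):
        a = rng.normal(size=(8, 50))
        b = rng.normal(size=(8, 300))
        assert fuse_features(a, b).shape == (8, 350)

    def test_fusing_with_empty_returns_original(self, rng):
        a = rng.normal(size=(5, 7))
        np.testing.assert_array_equal(fuse_features(a, np.empty((5, 0))), a)

    def test_feature_order_irrelevant_for_rbf_predictions(self, rng):
        records = make_records(rng)
        y = [r.au_label for r in records]
        a = np.vstack([r.alpha_e for r in records])
        b = a[:, ::-1] * 2.0
        for first, second in [(a, b), (b, a)]:
            fused = fuse_features(first, second)
            bundle = train_au_classifier(fused, y, sigma=3.0)
            pred = bundle.predict(fused)
            if first is a:
                ref = pred
        np.testing.assert_array_equal(ref, pred)

    def test_record_sequence_mismatch_rejected(self, rng):
        records = make_records(rng)
        other = list(records)
        other[0], other[1] = other[1], other[0]
        a = rng.normal(size=(len(records), 3))
        with pytest.raises(ValueError, match="sequences"):
            fuse_features(a, a, records, other)


class TestClassifier:
    def test_separable_classes_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(size=(20, 4)) + 10, rng.normal(size=(20, 4)) - 10])
        y = ["a"] * 20 + ["b"] * 20
        bundle = train_au_classifier(X, y)
        assert np.mean(bundle.predict(X) == np.array(y, dtype=object)) == 1.0

    def test_one_binary_svm_per_class_even_for_two(self, rng):
        X = rng.normal(size=(30, 5))
        y = [f"c{i % 3}" for i in range(30)]
        assert len(train_au_classifier(X, y).svms) == 3
        y2 = ["a" if i % 2 else "b" for i in range(30)]
        assert len(train_au_classifier(X, y2).svms) == 2

    def test_rbf_kernel_unit_diagonal(self):
        # K(x, x) = exp(0) = 1 for the configured gamma
        sigma = 2.0
        gamma = 1.0 / (2 * sigma**2)
        x = np.array([1.0, 2.0])
        assert np.exp(-gamma * np.sum((x - x) ** 2)) == 1.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            train_au_classifier(rng.normal(size=(5, 3)), ["a"] * 5)


class TestLOOCV:
    def test_separable_records_classified_well(self, rng):
        report = loocv_evaluate(make_records(rng, n_subjects=8))
        assert report.mean_f1 > 0.9
        assert all(v > 0.95 for v in report.per_class_auc.values())

    def test_confusion_rows_sum_to_class_counts(self, rng):
        records = make_records(rng, n_subjects=6, n_aus=3)
        report = loocv_evaluate(records)
        counts = {c: sum(r.au_label == c for r in records) for c in report.classes}
        for i, c in enumerate(report.classes):
            assert report.confusion[i].sum() == counts[c]

    def test_shuffled_labels_collapse_to_chance(self, rng):
        records = make_records(rng, n_subjects=10, n_aus=4)
        labels = [r.au_label for r in records]
        shuffled = rng.permutation(labels)
        label_map = {id(r): s for r, s in zip(records, shuffled)}
        report = loocv_evaluate(records, label_map=label_map)
        n = len(records)
        p = 1.0 / 4
        ci = 3 * np.sqrt(p * (1 - p) / n)
        assert report.accuracy < p + ci + 0.05

    def test_no_leakage_training_stats_exclude_test_subject(self, rng):
        records = make_records(rng, n_subjects=5)
        report = loocv_evaluate(records)
        for fold in report.folds:
            train = [r for r in records if r.subject_id != fold["subject"]]
            X, pipe = prepare_features(train)
            np.testing.assert_array_equal(pipe.scaler.mean_, fold["scaler_mean"])
            np.testing.assert_array_equal(pipe.scaler.scale_, fold["scaler_scale"])
            assert fold["subject"] not in fold["train_subjects"]

    def test_single_subject_class_warns(self, rng):
        records = make_records(rng, n_subjects=4)
        records.append(AUCoefficientRecord("s0", "RARE", rng.normal(size=20), 3, "m"))
        with pytest.warns(UserWarning, match="RARE"):
            loocv_evaluate(records)


class TestPrototypesAndSynthesis:
    def test_single_record_prototype_is_itself(self, rng):
        rec = AUCoefficientRecord("s", "AU1", rng.normal(size=5), 3, "m")
        np.testing.assert_array_equal(compute_au_prototype([rec], "AU1"), rec.alpha_e)

    def test_opposite_records_cancel(self, rng):
        v = rng.normal(size=5)
        recs = [
            AUCoefficientRecord("a", "AU1", v, 3, "m"),
            AUCoefficientRecord("b", "AU1", -v, 3, "m"),
        ]
        np.testing.assert_allclose(compute_au_prototype(recs, "AU1"), 0.0, atol=1e-15)

    def test_missing_label_rejected(self, rng):
        rec = AUCoefficientRecord("s", "AU1", rng.normal(size=5), 3, "m")
        with pytest.raises(ValueError, match="AU9"):
            compute_au_prototype([rec], "AU9")

    def test_zero_prototype_leaves_base_unchanged(self, slc_model):
        base = slc_model.mean_shape
        mesh = synthesize_au(base, slc_model, np.zeros(slc_model.k))
        np.testing.assert_array_equal(mesh.vertices.reshape(-1), base.vector)

    def test_topology_mismatch_rejected(self, slc_model):
        base = RegisteredShape(np.zeros(slc_model.mean.size), "other")
        with pytest.raises(ValueError, match="topology"):
            synthesize_au(base, slc_model, np.zeros(slc_model.k))

    def test_combination_linearity(self, slc_model, rng):
        base = slc_model.mean_shape
        a = rng.normal(size=slc_model.k)
        b = rng.normal(size=slc_model.k)
        combined = synthesize_au(base, slc_model, [a, b])
        pre_averaged = synthesize_au(base, slc_model, (a + b) / 2)
        np.testing.assert_allclose(combined.vertices, pre_averaged.vertices, atol=1e-12)


class TestEndToEndDecoupling:
    """Properties of the full two-step extraction on the raw synthetic corpus."""

    def test_neutral_control_coefficients_near_zero(self, extraction):
        med = np.median([np.linalg.norm(r.alpha_e) for r in extraction["records"]])
        worst = max(np.linalg.norm(r.alpha_e) for r in extraction["controls"])
        assert worst < 0.1 * med

    def test_within_au_similarity_exceeds_within_subject(self, extraction):
        import itertools

        records = extraction["records"]

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        within_au, within_subject = [], []
        for r1, r2 in itertools.combinations(records, 2):
            c = cos(r1.alpha_e, r2.alpha_e)
            if r1.au_label == r2.au_label:
                within_au.append(c)
            elif r1.subject_id == r2.subject_id:
                within_subject.append(c)
        assert np.mean(within_au) > np.mean(within_subject)

    def test_extracted_deformation_concentrates_in_au_region(self, extraction, slc_model, test_corpus):
        """The field reconstructed from alpha_e loads the labelled AU region."""
        vr = region_of_points(test_corpus.template.vertices)
        spec_by = {s.au_id: s for s in test_corpus.config.au_specs}
        hits = 0
        for rec in extraction["records"]:
            rid = REGION_IDS.index(spec_by[rec.au_label].region_id)
            field = (rec.alpha_e @ slc_model.components).reshape(-1, 3)
            disp = np.linalg.norm(field, axis=1)
            ratio = disp[vr == rid].mean() / disp[vr != rid].mean()
            hits += ratio > 1.5
        assert hits >= 0.8 * len(extraction["records"])

    def test_same_au_across_subjects_more_similar_than_different_aus(self, extraction):
        import itertools

        records = extraction["records"]

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        same_au, diff_au = [], []
        for r1, r2 in itertools.combinations(records, 2):
            if r1.subject_id == r2.subject_id:
                continue
            (same_au if r1.au_label == r2.au_label else diff_au).append(
                cos(r1.alpha_e, r2.alpha_e)
            )
        assert np.mean(same_au) > np.mean(diff_au)


class TestIdentityFit:
    def test_mean_scan_yields_small_identity_coefficients(self, slc_model):
        scan = delinearize(slc_model.mean_shape)
        s_n, alpha_id, res = au.fit_identity(slc_model, scan, FitOptions(icp=False))
        assert np.linalg.norm(alpha_id) < 1e-6
        np.testing.assert_allclose(s_n.vector, slc_model.mean, atol=1e-9)

    def test_unseen_subject_fit_reduces_identity_gap(self, slc_model, test_corpus):
        """The fitted neutral is closer to the subject's ground truth than the
        mean face is, on the median subject (point-to-point NN fitting cannot
        pin tangential semantics on a smooth surface, so per-vertex accuracy
        saturates near the scan-sampling floor rather than at zero)."""
        fit_errs, base_errs = [], []
        for entry in test_corpus.scans:
            if entry.label != "neutral":
                continue
            s_n, _, res = au.fit_identity(slc_model, entry.raw, FitOptions())
            gt = entry.registered.points
            fit_errs.append(np.mean(np.linalg.norm(res.deformed_target_frame.points - gt, axis=1)))
            base_errs.append(np.mean(np.linalg.norm(slc_model.mean_shape.points - gt, axis=1)))
            if len(fit_errs) == 4:
                break
        assert np.median(fit_errs) < np.median(base_errs)
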