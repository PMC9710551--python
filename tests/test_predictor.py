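import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from savpath import fixtures
from savpath.embeddings import PositionalEncoding, mock_backend, encode_variant_positional
from savpath.go_encoding import FunctionEncoding
from savpath.homology import connected_components, assign_folds
from savpath.predictor import (
    DEFAULT_PCA_COMPONENTS,
    FeatureVector,
    PipelineConfig,
    TrainedPipeline,
    assemble_features,
    fit_pca,
    grid_search_cv,
    reliability_index,
    train,
)
from savpath.variant_data import Label, VariantRecord


def pos_encoding(rng, dims=(8, 4)):
    layout = []
    for i, d in enumerate(dims):
        layout += [(f"b{i}_variant", d), (f"b{i}_wildtype", d)]
    total = 2 * sum(dims)
    return PositionalEncoding(values=rng.normal(size=total), layout=layout)


def func_encoding(rng, dim=3):
    return FunctionEncoding(values=rng.normal(size=3 * dim), block_dim=dim)


class TestAssembleFeatures:
    def test_default_dims_give_5208(self, rng):
        seq = "MKVLYWSTNQACDEFGHIKL"
        v = VariantRecord("P1", 3, "V", "W", Label.BLB)
        pos = encode_variant_positional(
            seq, v, (mock_backend("esm", 1280, max_length=1024), mock_backend("t5", 1024))
        )
        func = FunctionEncoding(values=rng.normal(size=600), block_dim=200)
        fv = assemble_features(pos, func)
        assert len(fv) == 5208

    def test_mock_dims_arithmetic(self, rng):
        fv = assemble_features(pos_encoding(rng, (8, 4)), func_encoding(rng, 3))
        assert len(fv) == 2 * 8 + 2 * 4 + 3 * 3 == 33

    def test_layout_slicing_recovers_blocks(self, rng):
        pos = pos_encoding(rng, (8, 4))
        func = func_encoding(rng, 3)
        fv = assemble_features(pos, func)
        np.testing.assert_array_equal(fv.block("b0_variant"), pos.block("b0_variant"))
        np.testing.assert_array_equal(fv.block("b1_wildtype"), pos.block("b1_wildtype"))
        np.testing.assert_array_equal(fv.block("go_CC"), func.block("CC"))
        # reassembling every block in layout order reproduces the vector
        rebuilt = np.concatenate([fv.block(name) for name, _ in fv.layout])
        np.testing.assert_array_equal(rebuilt, fv.values)

    def test_non_finite_rejected_naming_block(self, rng):
        pos = pos_encoding(rng)
        pos.values[0] = np.nan
        with pytest.raises(ValueError, match="positional"):
            assemble_features(pos, func_encoding(rng))
        func = func_encoding(rng)
        func.values[1] = np.inf
        with pytest.raises(ValueError, match="function"):
            assemble_features(pos_encoding(rng), func)


class TestFitPca:
    def test_planar_data_concentrates_variance(self, rng):
        basis = rng.normal(size=(2, 10))
        X = rng.normal(size=(200, 2)) @ basis  # rank-2 data in 10-D
        pca = fit_pca(X, 5)
        assert pca.explained_variance_ratio_[:2].sum() > 0.999

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(30, 6))
        pca = fit_pca(X, 6)
        back = pca.inverse_transform(pca.transform(X))
        np.testing.assert_allclose(back, X, atol=1e-10)

    def test_explained_variance_monotone_and_bounded(self, rng):
        X = rng.normal(size=(50, 12))
        pca = fit_pca(X, 12)
        ratios = pca.explained_variance_ratio_
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1.0 + 1e-9

    def test_components_capped_by_rows(self, rng):
        pca = fit_pca(rng.normal(size=(5, 100)), 50)
        assert pca.n_components_ == 5

    def test_invalid_components(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(10, 4)), 0)

    def test_default_component_count(self):
        assert PipelineConfig().pca_components == DEFAULT_PCA_COMPONENTS == 2400


def separable_data(rng, n=200, d=12, separation=4.0):
    y01 = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, d))
    X[y01 == 1, 0] += separation
    y = [Label.PLP if b else Label.BLB for b in y01]
    folds = [f"F{i % 4}" for i in range(n)]
    return X, y, folds


class TestGridSearch:
    def test_single_point_returned(self, rng):
        X, y, folds = separable_data(rng)
        config = PipelineConfig(grid_pca_components=(4,), grid_C=(1.0,),
                                grid_gamma=("scale",))
        best, results = grid_search_cv(X, y, folds, config)
        assert (best.pca_components, best.svm_C, best.svm_gamma) == (4, 1.0, "scale")
        assert len(results) == 1

    def test_adequate_point_beats_degenerate(self, rng):
        X, y, folds = separable_data(rng, n=300)
        config = PipelineConfig(
            grid_pca_components=(6,),
            grid_C=(1e-6, 10.0),  # vanishing C cannot fit anything
            grid_gamma=("scale",),
        )
        best, results = grid_search_cv(X, y, folds, config)
        assert best.svm_C == 10.0
        by_c = {r["svm_C"]: r["mean_mcc"] for r in results}
        assert by_c[10.0] > by_c[1e-6]

    def test_reproducible(self, rng):
        X, y, folds = separable_data(rng)
        config = PipelineConfig(grid_pca_components=(4, 8), grid_C=(1.0, 10.0),
                                grid_gamma=("scale",))
        best1, res1 = grid_search_cv(X, y, folds, config)
        best2, res2 = grid_search_cv(X, y, folds, config)
        assert best1 == best2 and res1 == res2

    def test_tie_prefers_smaller_model(self, rng):
        X, y, folds = separable_data(rng, n=240, separation=8.0)
        config = PipelineConfig(grid_pca_components=(4, 12), grid_C=(1.0, 10.0),
                                grid_gamma=("scale",))
        best, results = grid_search_cv(X, y, folds, config)
        top = max(r["mean_mcc"] for r in results)
        tied = [r for r in results if r["mean_mcc"] == top]
        expected = min(tied, key=lambda r: (r["pca_components"], r["svm_C"]))
        assert best.pca_components == expected["pca_components"]
        assert best.svm_C == expected["svm_C"]

    def test_empty_grid_rejected(self, rng):
        X, y, folds = separable_data(rng)
        config = PipelineConfig(grid_pca_components=(), grid_C=(), grid_gamma=())
        with pytest.raises(ValueError, match="empty"):
            grid_search_cv(X, y, folds, config)


class TestTrain:
    @pytest.fixture
    def trained(self, rng):
        X, y, folds = separable_data(rng, n=400)
        config = PipelineConfig(pca_components=8, svm_C=10.0, seed=0)
        return train(X, y, folds, config), X, y

    def test_separable_clouds_high_training_accuracy(self, trained):
        pipeline, X, y = trained
        preds = pipeline.predict_batch(X)
        accuracy = np.mean([p.label is t for p, t in zip(preds, y)])
        assert accuracy > 0.95

    def test_serialization_roundtrip_bitwise(self, trained, tmp_path):
        pipeline, X, _ = trained
        path = tmp_path / "model.zip"
        pipeline.save(path)
        loaded = TrainedPipeline.load(path)
        np.testing.assert_array_equal(
            loaded.decision_scores(X[:50]), pipeline.decision_scores(X[:50])
        )
        probs_a = [p.probability for p in loaded.predict_batch(X[:50])]
        probs_b = [p.probability for p in pipeline.predict_batch(X[:50])]
        assert probs_a == probs_b

    def test_calibrator_bounded_and_monotone(self, trained):
        pipeline, _, _ = trained
        sweep = np.linspace(-5, 5, 201)
        probs = pipeline.calibrator.predict(sweep)
        assert probs.min() >= 0.0 and probs.max() <= 1.0
        assert np.all(np.diff(probs) >= -1e-12)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        y = [Label.PLP] * 20
        with pytest.raises(ValueError, match="single class"):
            train(X, y, ["F1", "F2"] * 10, PipelineConfig(pca_components=2))

    def test_tampered_archive_rejected(self, trained, tmp_path):
        import json, zipfile

        pipeline, _, _ = trained
        path = tmp_path / "model.zip"
        pipeline.save(path)
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            payload = zf.read("model.joblib")
        manifest["feature_layout"] = [["features", 9999]]
        bad = tmp_path / "bad.zip"
        with zipfile.ZipFile(bad, "w") as zf:
            zf.writestr("manifest.json", json.dumps(manifest))
            zf.writestr("model.joblib", payload)
        with pytest.raises(ValueError, match="checksum"):
            TrainedPipeline.load(bad)


class TestReliabilityIndex:
    @pytest.mark.parametrize("p,expected", [(0.5, 0), (1.0, 10), (0.0, 10), (0.8, 6)])
    def test_reference_points(self, p, expected):
        assert reliability_index(p) == expected

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_range(self, p):
        ri = reliability_index(p)
        assert 0 <= ri <= 10
        assert ri == reliability_index(1.0 - p)

    @pytest.mark.parametrize("p", [-0.01, 1.01, 2.0])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            reliability_index(p)

    def test_half_away_from_zero_rounding(self):
        # 20*|0.525-0.5| = 0.5 must round up to 1, not to banker's 0
        assert reliability_index(0.525) == 1
        assert reliability_index(0.475) == 1


class TestPredict:
    def test_score_zero_is_pathogenic(self, rng):
        X, y, folds = separable_data(rng, n=200)
        pipeline = train(X, y, folds, PipelineConfig(pca_components=6, seed=0))
        score = float(pipeline.decision_scores(X[:1])[0])
        # with the threshold set to an achieved score, >= keeps it pathogenic
        pipeline.config.decision_threshold = score
        assert pipeline.predict_batch(X[:1])[0].label is Label.PLP

    def test_repeatable(self, rng):
        X, y, folds = separable_data(rng, n=200)
        pipeline = train(X, y, folds, PipelineConfig(pca_components=6, seed=0))
        a = pipeline.predict_batch(X[:10])
        b = pipeline.predict_batch(X[:10])
        assert [(p.score, p.probability, p.label) for p in a] == [
            (p.score, p.probability, p.label) for p in b
        ]

    def test_labels_match_sign_threshold_oracle(self, rng):
        X, y, folds = separable_data(rng, n=300)
        pipeline = train(X, y, folds, PipelineConfig(pca_components=6, seed=0))
        preds = pipeline.predict_batch(X)
        scores = pipeline.decision_scores(X)  # independent recomputation
        for p, s in zip(preds, scores):
            assert p.label is (Label.PLP if s >= 0.0 else Label.BLB)

    def test_layout_mismatch_error_names_lengths(self, rng):
        X, y, folds = separable_data(rng, n=100, d=12)
        pipeline = train(X, y, folds, PipelineConfig(pca_components=4, seed=0))
        with pytest.raises(ValueError, match="12.*5"):
            pipeline.decision_scores(rng.normal(size=(3, 5)))


class TestNoLeakage:
    def test_permuted_labels_give_null_mcc(self):
        from savpath.evaluation import cross_validate

        bundle = fixtures.make_fixture(
            fixtures.FixtureSpec(
                n_proteins=100, n_variants=1000, embedding_separation=3.0,
                go_signal=0.0, seed=5,
            )
        )
        X, y, _ = fixtures.encode_bundle(bundle)
        rng = np.random.default_rng(5)
        y_perm = [y[i] for i in rng.permutation(len(y))]
        clusters = connected_components([p.accession for p in bundle.proteins], [])
        folds = assign_folds(clusters, bundle.variants, k=5, seed=5)
        fold_of = folds.fold_of_accession(clusters)
        fold_ids = [fold_of[v.protein_accession] for v in bundle.variants]
        config = PipelineConfig(pca_components=40, svm_C=10.0, seed=0)
        report = cross_validate(X, y_perm, fold_ids, config)
        assert abs(report.mcc) < 0.1
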