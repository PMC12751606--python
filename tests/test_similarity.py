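import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppinet.similarity import (
    FeatureMatchConfig,
    ModelConfig,
    PairTable,
    SimilarityModel,
    build_pair_table,
    classification_metrics,
    encode_pair,
    match_by_features,
    match_matrix,
    predict_pair,
    train_model,
    write_arff,
)

vectors = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=60, max_size=60
).map(np.array)


class TestMatchByFeatures:
    def test_identical_vectors_always_match(self, rng):
        v = rng.normal(size=60)
        assert match_by_features(v, v, FeatureMatchConfig(min_matches=60))

    def test_boundary_25_vs_24_matching_coordinates(self):
        a = np.zeros(60)
        b = np.full(60, 100.0)
        b[:25] = 1.0  # exactly tolerance away in 25 coordinates
        cfg = FeatureMatchConfig(min_matches=25, tolerance=1.0)
        assert match_by_features(a, b, cfg)
        b[24] = 100.0  # only 24 close coordinates left
        assert not match_by_features(a, b, cfg)

    def test_default_config_is_25_within_1(self):
        cfg = FeatureMatchConfig()
        assert (cfg.min_matches, cfg.tolerance) == (25, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(vectors, vectors)
    def test_symmetry(self, a, b):
        cfg = FeatureMatchConfig()
        assert match_by_features(a, b, cfg) == match_by_features(b, a, cfg)

    @settings(deadline=None, max_examples=50)
    @given(vectors, vectors, st.integers(1, 59), st.floats(0.1, 10))
    def test_loosening_never_unmatches(self, a, b, min_matches, tol):
        strict = FeatureMatchConfig(min_matches=min_matches + 1, tolerance=tol)
        loose_matches = FeatureMatchConfig(min_matches=min_matches, tolerance=tol)
        loose_tol = FeatureMatchConfig(min_matches=min_matches + 1, tolerance=tol * 2)
        if match_by_features(a, b, strict):
            assert match_by_features(a, b, loose_matches)
            assert match_by_features(a, b, loose_tol)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            match_by_features(np.zeros(59), np.zeros(60))

    def test_match_matrix_agrees_with_scalar_rule(self, rng):
        A = rng.normal(scale=2, size=(7, 60))
        B = rng.normal(scale=2, size=(5, 60))
        cfg = FeatureMatchConfig(min_matches=30, tolerance=2.0)
        m = match_matrix(A, B, cfg)
        for i in range(7):
            for j in range(5):
                assert m[i, j] == match_by_features(A[i], B[j], cfg)


class TestEncodePair:
    def test_self_encoding_is_zero(self, rng):
        v = rng.normal(size=60)
        assert np.all(encode_pair(v, v) == 0)

    @settings(deadline=None, max_examples=30)
    @given(vectors, vectors)
    def test_symmetric_by_construction(self, a, b):
        np.testing.assert_array_equal(encode_pair(a, b), encode_pair(b, a))

    def test_elementwise_absolute_difference(self):
        a = np.zeros(60)
        b = np.zeros(60)
        a[0], a[1] = 1, 3
        b[0], b[1] = 4, 1
        enc = encode_pair(a, b)
        assert (enc[0], enc[1]) == (3.0, 2.0)


def _labeled_pairs(n_pos, n_neg, rng, spread=30.0):
    """Separable synthetic pairs: positives differ little, negatives a lot."""
    pairs = []
    for _ in range(n_pos):
        a = rng.normal(size=60)
        pairs.append((a, a + rng.normal(scale=0.1, size=60), True))
    for _ in range(n_neg):
        a = rng.normal(size=60)
        pairs.append((a, a + rng.normal(loc=spread, scale=1.0, size=60), False))
    return pairs


class TestBuildPairTable:
    def test_ratio_downsampling_and_ordering(self, rng):
        table = build_pair_table(_labeled_pairs(10, 100, rng), ratio=3, seed=0)
        assert table.n_positive == 10
        assert table.n_negative == 30
        assert np.all(table.y[:30] == 0) and np.all(table.y[30:] == 1)

    def test_insufficient_negatives_kept_with_warning(self, rng, caplog):
        table = build_pair_table(_labeled_pairs(10, 5, rng), ratio=3, seed=0)
        assert table.n_negative == 5
        assert any("negatives" in r.message for r in caplog.records)

    def test_seeded_determinism(self, rng):
        pairs = _labeled_pairs(5, 50, rng)
        t1 = build_pair_table(pairs, ratio=2, seed=42)
        t2 = build_pair_table(pairs, ratio=2, seed=42)
        np.testing.assert_array_equal(t1.X, t2.X)

    def test_no_positives_raises(self, rng):
        with pytest.raises(ValueError, match="positive"):
            build_pair_table(_labeled_pairs(0, 5, rng), ratio=3)

    def test_bad_ratio_raises(self, rng):
        with pytest.raises(ValueError, match="ratio"):
            build_pair_table(_labeled_pairs(2, 5, rng), ratio=0)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="negatives before"):
            PairTable(X=np.zeros((2, 60)), y=np.array([1, 0]))


class TestTrainPredict:
    def test_default_forest_configuration(self, rng):
        table = build_pair_table(_labeled_pairs(8, 24, rng), ratio=3, seed=0)
        model = train_model(table, ModelConfig(seed=0))
        assert model.forest.n_estimators == 500
        assert model.forest.max_depth == 30
        assert model.forest.max_features == 10

    def test_separable_table_perfect_training_metrics(self, rng):
        table = build_pair_table(_labeled_pairs(10, 30, rng), ratio=3, seed=0)
        model = train_model(table, ModelConfig(n_tree=50, seed=0))
        pred = model.forest.predict(table.X)
        tp = int(np.sum((pred == 1) & (table.y == 1)))
        tn = int(np.sum((pred == 0) & (table.y == 0)))
        m = classification_metrics(tn, table.n_positive - tp, tp, table.n_negative - tn)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_single_class_table_raises(self, rng):
        X = rng.normal(size=(5, 60))
        with pytest.raises(ValueError, match="class"):
            train_model(PairTable(X=X, y=np.zeros(5, dtype=int)))

    def test_prediction_symmetry_and_zero_pair_positive(self, rng):
        table = build_pair_table(_labeled_pairs(10, 30, rng), ratio=3, seed=0)
        model = train_model(table, ModelConfig(n_tree=50, seed=0))
        v = rng.normal(size=60)
        label, score = predict_pair(model, v, v)
        assert label  # zero-difference pairs were positives in training
        a, b = rng.normal(size=60), rng.normal(size=60)
        assert predict_pair(model, a, b) == predict_pair(model, b, a)

    def test_layout_mismatch_raises(self, rng):
        table = build_pair_table(_labeled_pairs(5, 15, rng), ratio=3, seed=0)
        model = train_model(table, ModelConfig(n_tree=10, seed=0))
        model.feature_layout_version = "stale/v0"
        with pytest.raises(ValueError, match="layout"):
            predict_pair(model, np.zeros(60), np.zeros(60))

    def test_save_load_round_trip(self, rng, tmp_path):
        table = build_pair_table(_labeled_pairs(5, 15, rng), ratio=3, seed=0)
        model = train_model(table, ModelConfig(n_tree=10, seed=0))
        path = tmp_path / "model.dat"
        model.save(path)
        loaded = SimilarityModel.load(path)
        v1, v2 = rng.normal(size=60), rng.normal(size=60)
        assert predict_pair(model, v1, v2) == predict_pair(loaded, v1, v2)
        assert loaded.config == model.config


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "tn,fn,tp,fp,sens,spec,f1",
        [
            (1713, 14, 26, 35, 0.6500, 0.9800, 0.5149),
            (320, 9, 13, 7, 0.5909, 0.9786, 0.6190),
            (130, 9, 19, 13, 0.6786, 0.9091, 0.6333),
        ],
    )
    def test_published_confusion_rows(self, tn, fn, tp, fp, sens, spec, f1):
        m = classification_metrics(tn, fn, tp, fp)
        assert m.rounded() == (sens, spec, f1)

    def test_degenerate_denominators_flagged(self):
        m = classification_metrics(0, 0, 5, 0)
        assert m.sensitivity == 1.0
        assert m.specificity_undefined and np.isnan(m.specificity)

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            classification_metrics(-1, 0, 0, 0)


class TestArffWriter:
    def test_format_and_row_order(self, rng, tmp_path):
        table = build_pair_table(_labeled_pairs(2, 6, rng), ratio=3, seed=0)
        path = tmp_path / "pairs.arff"
        write_arff(table, path)
        text = path.read_text()
        assert text.count("@attribute") == 61
        assert "@attribute class {negative,positive}" in text
        data = [ln for ln in text.splitlines() if ln and not ln.startswith("@")]
        labels = [ln.rsplit(",", 1)[1] for ln in data]
        assert labels == ["negative"] * 6 + ["positive"] * 2
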