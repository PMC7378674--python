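import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zonelvq import (
    LVQConfig,
    LVQModel,
    TrainingSet,
    fit,
    init_model,
    load_model,
    predict,
    save_model,
    train,
)
from zonelvq.errors import DimensionMismatchError, MissingClassError, ModelFormatError
from zonelvq.lvq import distance


def two_class_set(samples_labels):
    X = np.array([s for s, _ in samples_labels], dtype=float)
    y = [lab for _, lab in samples_labels]
    return TrainingSet(samples=X, labels=y)


class TestInit:
    def test_first_sample_per_class_becomes_prototype(self):
        ts = two_class_set([([0.1], "normal"), ([0.9], "suspected"), ([0.2], "normal")])
        model, rest = init_model(ts)
        assert model.prototypes["normal"][0] == 0.1
        assert model.prototypes["suspected"][0] == 0.9
        assert len(rest) == 1 and rest.labels == ["normal"]

    def test_missing_class_raises(self):
        ts = two_class_set([([0.1], "normal"), ([0.2], "normal")])
        with pytest.raises(MissingClassError):
            init_model(ts)

    def test_duplicate_first_samples_allowed(self):
        ts = two_class_set([([0.5, 0.5], "normal"), ([0.5, 0.5], "suspected")])
        model, rest = init_model(ts)
        np.testing.assert_array_equal(
            model.prototypes["normal"], model.prototypes["suspected"]
        )
        assert len(rest) == 0


class TestDistance:
    @pytest.mark.parametrize(
        "x,w,expected",
        [([1.0, 0.0], [0.0, 0.0], 1.0), ([0.3, 0.4], [0.0, 0.0], 0.5), ([2.0], [2.0], 0.0)],
    )
    def test_euclidean(self, x, w, expected):
        assert distance(np.array(x), np.array(w)) == pytest.approx(expected)

    def test_symmetry_and_mismatch(self):
        a, b = np.array([1.0, 2.0]), np.array([4.0, 6.0])
        assert distance(a, b) == distance(b, a) == 5.0
        with pytest.raises(DimensionMismatchError):
            distance(a, np.array([1.0, 2.0, 3.0]))


class TestTrain:
    def make_model(self, protos, config):
        return LVQModel(
            class_labels=("normal", "suspected"),
            prototypes={k: np.array(v, dtype=float) for k, v in protos.items()},
            feature_dim=len(next(iter(protos.values()))),
            config=config,
        )

    def test_hand_computed_one_epoch(self):
        """1-D prototypes 0.0/1.0 attract to 0.1/0.9 at alpha=0.1 -> 0.01/0.99."""
        cfg = LVQConfig(alpha=0.1, dec_alpha=0.5, max_epoch=1, eps=1e-6)
        model = self.make_model({"normal": [0.0], "suspected": [1.0]}, cfg)
        ts = two_class_set([([0.1], "normal"), ([0.9], "suspected")])
        trained, log = train(model, ts)
        assert trained.prototypes["normal"][0] == pytest.approx(0.01)
        assert trained.prototypes["suspected"][0] == pytest.approx(0.99)
        assert log[0]["errors"] == 0

    def test_matched_update_is_midpoint_at_half_alpha(self):
        cfg = LVQConfig(alpha=0.5, dec_alpha=0.5, max_epoch=1, eps=0.3)
        model = self.make_model({"normal": [0.0, 0.0], "suspected": [5.0, 5.0]}, cfg)
        ts = two_class_set([([1.0, 1.0], "normal")])
        trained, _ = train(model, ts)
        np.testing.assert_allclose(trained.prototypes["normal"], [0.5, 0.5])

    def test_mismatch_repels(self):
        cfg = LVQConfig(alpha=0.1, dec_alpha=0.5, max_epoch=1, eps=1e-6)
        model = self.make_model({"normal": [0.0], "suspected": [1.0]}, cfg)
        ts = two_class_set([([0.1], "suspected")])  # nearest is the normal prototype
        trained, log = train(model, ts)
        assert trained.prototypes["normal"][0] == pytest.approx(-0.01)
        assert log[0]["errors"] == 1

    def test_training_stops_once_alpha_decays_to_floor(self):
        # alpha halves to 0.025 <= eps after epoch 1, so only one epoch runs
        cfg = LVQConfig(alpha=0.05, dec_alpha=0.5, max_epoch=10, eps=0.04)
        model = self.make_model({"normal": [0.0], "suspected": [1.0]}, cfg)
        ts = two_class_set([([0.4], "normal")])
        trained, log = train(model, ts)
        assert len(log) == 1
        assert trained.prototypes["normal"][0] == pytest.approx(0.02)

    def test_input_model_unmodified(self):
        cfg = LVQConfig(alpha=0.3, dec_alpha=0.5, max_epoch=3, eps=1e-6)
        model = self.make_model({"normal": [0.0], "suspected": [1.0]}, cfg)
        ts = two_class_set([([0.2], "normal")])
        train(model, ts)
        assert model.prototypes["normal"][0] == 0.0

    def test_empty_iteration_set_warns(self):
        cfg = LVQConfig()
        model = self.make_model({"normal": [0.0], "suspected": [1.0]}, cfg)
        trained, log = train(model, TrainingSet(np.empty((0, 1)), []))
        assert trained.prototypes["normal"][0] == 0.0
        assert "warning" in log[0]

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.01, 0.9))
    def test_contraction_identity(self, seed, alpha):
        """A matched update shrinks the distance by exactly (1 - alpha)."""
        rng = np.random.default_rng(seed)
        x, w = rng.normal(size=5), rng.normal(size=5)
        d_old = distance(x, w)
        w_new = w + alpha * (x - w)
        assert distance(x, w_new) == pytest.approx((1 - alpha) * d_old, rel=1e-12)

    def test_deterministic(self):
        ts = two_class_set(
            [([0.1, 0.2], "normal"), ([0.9, 0.8], "suspected"),
             ([0.15, 0.25], "normal"), ([0.85, 0.7], "suspected")]
        )
        m1 = fit(ts, LVQConfig(alpha=0.2, dec_alpha=0.8, max_epoch=20, eps=1e-5))
        m2 = fit(ts, LVQConfig(alpha=0.2, dec_alpha=0.8, max_epoch=20, eps=1e-5))
        for lab in m1.class_labels:
            np.testing.assert_array_equal(m1.prototypes[lab], m2.prototypes[lab])


class TestPredict:
    def make_model(self):
        return LVQModel(
            class_labels=("normal", "suspected"),
            prototypes={"normal": np.array([0.0, 0.0]), "suspected": np.array([1.0, 1.0])},
            feature_dim=2,
        )

    def test_smaller_distance_wins(self):
        """The class at smaller prototype distance is reported, as in a
        per-image results row where distances (3.49, 2.97) yield suspected."""
        model = self.make_model()
        label, dists = predict(model, np.array([0.9, 0.8]))
        assert label == "suspected"
        assert dists["suspected"] < dists["normal"]

    def test_exact_prototype_match(self):
        model = self.make_model()
        label, dists = predict(model, np.array([0.0, 0.0]))
        assert label == "normal" and dists["normal"] == 0.0

    def test_tie_goes_to_first_listed_class(self):
        model = self.make_model()
        label, _ = predict(model, np.array([0.5, 0.5]))
        assert label == "normal"

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            predict(self.make_model(), np.array([0.1, 0.2, 0.3]))

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        model = LVQModel(
            class_labels=("a", "b", "c"),
            prototypes={lab: rng.normal(size=8) for lab in ("a", "b", "c")},
            feature_dim=8,
        )
        x = rng.normal(size=8)
        label, dists = predict(model, x)
        brute = min(
            ("a", "b", "c"),
            key=lambda lab: (np.sqrt(((x - model.prototypes[lab]) ** 2).sum()), 0),
        )
        assert label == brute
        for lab in ("a", "b", "c"):
            assert dists[lab] == pytest.approx(np.linalg.norm(x - model.prototypes[lab]))


class TestConvergence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_cluster_recovery(self, seed):
        """Well-separated Gaussian clusters: training error hits 0 and the
        prototypes land within one cluster SD of the cluster means."""
        rng = np.random.default_rng(seed)
        sd = 0.05
        mu = {"normal": np.array([0.2, 0.2]), "suspected": np.array([0.8, 0.8])}
        samples, labels = [], []
        for lab in ("normal", "suspected"):
            for _ in range(20):
                samples.append(mu[lab] + rng.normal(0, sd, size=2))
                labels.append(lab)
        order = rng.permutation(len(labels))
        ts = TrainingSet(np.array(samples)[order], [labels[i] for i in order])
        cfg = LVQConfig(alpha=0.1, dec_alpha=0.9, max_epoch=50, eps=1e-5)
        model, rest = init_model(ts, cfg)
        trained, log = train(model, rest)
        assert log[-1]["errors"] == 0
        for lab in ("normal", "suspected"):
            assert np.linalg.norm(trained.prototypes[lab] - mu[lab]) < sd


class TestPersistence:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(5)
        model = LVQModel(
            class_labels=("normal", "suspected"),
            prototypes={
                "normal": rng.random(64),
                "suspected": rng.random(64),
            },
            feature_dim=64,
            config=LVQConfig(alpha=0.07, dec_alpha=0.85, max_epoch=40, eps=1e-3),
            training_log=[{"epoch": 1, "alpha": 0.07, "errors": 2}],
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.class_labels == model.class_labels
        assert back.config == model.config
        for lab in model.class_labels:
            np.testing.assert_array_equal(back.prototypes[lab], model.prototypes[lab])

    def test_file_lists_one_value_per_feature(self, tmp_path):
        import json

        model = LVQModel(
            class_labels=("normal", "suspected"),
            prototypes={"normal": np.zeros(64), "suspected": np.ones(64)},
            feature_dim=64,
        )
        path = tmp_path / "m.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        assert len(doc["prototypes"]["normal"]) == 64

    def test_missing_prototype_field_raises(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"classes": ["normal"], "feature_dim": 2, "config": {}}')
        with pytest.raises(ModelFormatError, match="prototypes"):
            load_model(path)

    def test_invalid_json_reports_line(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"classes": [,]}')
        with pytest.raises(ModelFormatError, match="line"):
            load_model(path)
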