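"""Tests of displacement scoring, prediction and class evolution."""

import numpy as np
import pytest

from mdem.classifier import MDEMModel, fit
from mdem.synthetic import ClassSpec, GeneratorSpec, generate, oracle_displacements


@pytest.fixture
def ab_model():
    """Classes A = {0.0, 0.2} and B = {0.9} in one attribute."""
    X = np.array([[0.0], [0.2], [0.9]])
    y = np.array(["A", "A", "B"])
    return fit(X, y, order=1, evolve=False)


class TestFit:
    def test_worked_example_third_moment(self):
        X = np.array([[5.0], [10.0], [15.0], [8.0], [20.0]])
        y = np.array(["c2"] * 5)
        model = fit(X, y, order=3)
        np.testing.assert_allclose(model.states_[0].central_moment, [58.752])
        np.testing.assert_allclose(model.states_[0].mean, [11.6])

    def test_singleton_classes_have_zero_moments(self):
        model = fit(np.array([[0.1], [0.9]]), np.array(["a", "b"]), order=2)
        for s in model.states_:
            np.testing.assert_allclose(s.central_moment, 0.0, atol=1e-15)
        # degenerate scoring still picks a class deterministically
        assert model.predict_one([0.5]) in ("a", "b")

    def test_empty_declared_class_errors(self):
        with pytest.raises(ValueError, match="no training rows"):
            MDEMModel().fit(np.array([[1.0]]), np.array(["a"]), classes=["a", "b"])

    def test_class_means_recover_generator_means(self):
        df = generate(GeneratorSpec(classes=(
            ClassSpec("a", 400, (0.0, 1.0), (1.0, 1.0)),
            ClassSpec("b", 400, (3.0, -1.0), (1.0, 1.0)),
        ), seed=5))
        X = df[["x1", "x2"]].to_numpy()
        model = fit(X, df["class"].to_numpy(), order=1)
        se = 1.0 / np.sqrt(400)
        np.testing.assert_allclose(model.states_[0].mean, [0.0, 1.0], atol=3 * se)
        np.testing.assert_allclose(model.states_[1].mean, [3.0, -1.0], atol=3 * se)


class TestScoring:
    def test_enumerated_two_class_example(self, ab_model):
        r = ab_model.score_displacements([0.5])
        np.testing.assert_allclose(r.raw, [0.4 / 3, 0.2])
        np.testing.assert_allclose(r.weighted, [0.8 / 3, 0.2])
        assert ab_model.classes_[r.chosen] == "B"
        assert r.margin == pytest.approx(0.8 / 3 - 0.2)

    def test_point_at_a_class_mean_has_zero_raw_displacement(self):
        model = fit(
            np.array([[0.1], [0.3], [0.9]]), np.array(["a", "a", "b"]),
            order=1, evolve=False,
        )
        r = model.score_displacements([0.2])  # mean of class a
        assert r.raw[0] == pytest.approx(0.0, abs=1e-15)
        assert model.classes_[r.chosen] == "a"

    def test_small_class_can_win_despite_larger_raw_displacement(self):
        """Cardinality weighting rescues a small class near a big one."""
        rng = np.random.default_rng(3)
        big = rng.normal([0.3, 0.3], 0.05, size=(46, 2))
        small = rng.normal([0.8, 0.8], 0.05, size=(2, 2))
        X = np.vstack([big, small])
        y = np.array(["big"] * 46 + ["small"] * 2)
        model = fit(X, y, order=1, evolve=False)
        r = model.score_displacements([0.7, 0.7])
        assert r.raw[0] < r.raw[1]  # the big class barely moves...
        assert model.classes_[r.chosen] == "small"  # ...but still loses

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for trial in range(200):
            d = int(rng.integers(1, 4))
            M = int(rng.integers(2, 5))
            sets, X, y = [], [], []
            for j in range(M):
                size = int(rng.integers(2, 12))
                pts = rng.random((size, d))
                sets.append(pts)
                X.append(pts)
                y += [j] * size
            order = int(rng.integers(1, 5))
            model = fit(np.vstack(X), np.array(y), order=order, evolve=False)
            x = rng.random(d)
            r = model.score_displacements(x)
            np.testing.assert_allclose(
                r.weighted, oracle_displacements(sets, x, order), atol=1e-9
            )

    def test_dimension_mismatch_errors(self, ab_model):
        with pytest.raises(ValueError, match="mismatch"):
            ab_model.score_displacements([0.5, 0.5])


class TestPrediction:
    def test_single_class_model_always_returns_it(self):
        model = fit(np.array([[0.0], [1.0]]), np.array(["only", "only"]), order=1)
        assert model.predict_one([5.0]) == "only"

    def test_evolve_commits_to_chosen_class(self):
        X = np.array([[0.0], [0.2], [0.9]])
        model = fit(X, np.array(["A", "A", "B"]), order=1, evolve=True)
        assert model.predict_one([0.5]) == "B"
        b = model.states_[1]
        assert b.count == 2
        np.testing.assert_allclose(b.mean, [0.7])
        assert model.states_[0].count == 2  # A untouched

    def test_frozen_model_is_permutation_invariant(self):
        rng = np.random.default_rng(9)
        X = rng.random((60, 3))
        y = np.array(["a", "b", "c"] * 20)
        model = fit(X, y, order=2, evolve=False)
        batch = rng.random((25, 3))
        base = model.predict_batch(batch)
        perm = rng.permutation(25)
        shuffled = model.predict_batch(batch[perm])
        np.testing.assert_array_equal(shuffled, base[perm])

    def test_empty_batch(self, ab_model):
        assert len(ab_model.predict_batch(np.empty((0, 1)))) == 0

    def test_evolving_on_a_class_mean_grows_it(self):
        X = np.array([[0.1], [0.3], [0.9]])
        model = fit(X, np.array(["a", "a", "b"]), order=1, evolve=True)
        batch = np.full((5, 1), 0.2)  # class a's mean
        labels = model.predict_batch(batch)
        assert all(v == "a" for v in labels)
        assert model.states_[0].count == 7

    def test_evolve_and_frozen_diverge_under_drift(self):
        """A cluster drifting away is tracked only by the evolving model."""
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(0.0, 0.05, (20, 1)), rng.normal(1.0, 0.05, (20, 1))])
        y = np.array(["lo"] * 20 + ["hi"] * 20)
        drift = np.linspace(1.0, -0.3, 40).reshape(-1, 1)  # hi cluster walks toward lo
        evolving = fit(X, y, order=1, evolve=True).predict_batch(drift)
        frozen = fit(X, y, order=1, evolve=False).predict_batch(drift)
        assert list(evolving) != list(frozen)

    def test_separation_consistency_six_sigma(self):
        """Well-separated equal Gaussian classes are classified >= 0.99."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Xa = rng.normal(0.0, 1.0, (100, 2))
            Xb = rng.normal(6.0, 1.0, (100, 2))
            X = np.vstack([Xa, Xb])
            y = np.array(["a"] * 100 + ["b"] * 100)
            model = fit(X, y, order=1, evolve=True)
            test = np.vstack([rng.normal(0.0, 1.0, (100, 2)), rng.normal(6.0, 1.0, (100, 2))])
            truth = np.array(["a"] * 100 + ["b"] * 100)
            acc = (model.predict_batch(test) == truth).mean()
            assert acc >= 0.99


class TestMarginAndInvariances:
    def test_identical_classes_have_zero_margin(self):
        X = np.array([[0.1], [0.5], [0.1], [0.5]])
        y = np.array(["a", "a", "b", "b"])
        model = fit(X, y, order=1, evolve=False)
        assert model.margin_diagnostic([0.8]) == pytest.approx(0.0, abs=1e-15)

    def test_single_class_margin_errors(self):
        model = fit(np.array([[0.0]]), np.array(["x"]), order=1)
        with pytest.raises(ValueError, match="2 classes"):
            model.margin_diagnostic([0.5])

    def test_margin_from_enumerated_example(self, ab_model):
        assert ab_model.margin_diagnostic([0.5]) == pytest.approx(0.8 / 3 - 0.2)

    def test_margin_invariant_to_class_ordering(self):
        X = np.array([[0.0], [0.2], [0.9]])
        y = np.array(["A", "A", "B"])
        m1 = fit(X, y, order=1, evolve=False, classes=["A", "B"])
        m2 = fit(X, y, order=1, evolve=False, classes=["B", "A"])
        assert m1.margin_diagnostic([0.5]) == pytest.approx(m2.margin_diagnostic([0.5]))

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_argmin_scale_invariance(self, order):
        """Rescaling all attributes by c > 0 never changes predictions."""
        rng = np.random.default_rng(order)
        X = rng.random((40, 2))
        y = np.array(["a", "b"] * 20)
        probe = rng.random((15, 2))
        base = fit(X, y, order=order, evolve=False).predict_batch(probe)
        for c in (0.25, 3.0):
            scaled = fit(c * X, y, order=order, evolve=False).predict_batch(c * probe)
            np.testing.assert_array_equal(scaled, base)

    def test_class_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        X = rng.random((30, 2))
        y = np.array(["a", "b", "c"] * 10)
        probe = rng.random((10, 2))
        p1 = fit(X, y, order=2, evolve=False, classes=["a", "b", "c"]).predict_batch(probe)
        p2 = fit(X, y, order=2, evolve=False, classes=["c", "b", "a"]).predict_batch(probe)
        np.testing.assert_array_equal(p1, p2)


class TestSerialization:
    def test_round_trip_preserves_predictions_bitwise(self, tmp_path):
        from mdem.io import load_model, save_model

        rng = np.random.default_rng(4)
        X = rng.random((30, 3))
        y = np.array(["a", "b", "c"] * 10)
        model = fit(X, y, order=3, evolve=True)
        path = tmp_path / "model.json"
        save_model(model, path)
        clone = load_model(path)
        batch = rng.random((20, 3))
        np.testing.assert_array_equal(model.predict_batch(batch), clone.predict_batch(batch))
        assert [s.count for s in model.states_] == [s.count for s in clone.states_]
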