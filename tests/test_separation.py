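import json

import numpy as np
import pytest
from sklearn.base import clone

from svmpsp import classify, sample_grid
from svmpsp.embedding import Trajectory
from svmpsp.separation import (
    DegenerateBiasError,
    Hyperplane,
    SVMPSPClassifier,
    SynapticWeights,
    candidate_margin,
    negative_margin,
    normalized_margin,
    signed_distance,
    to_synaptic_weights,
    train_single_target,
)
from .conftest import make_task


class TestDistances:
    def test_signed_distance_by_hand(self):
        h = Hyperplane(np.array([3.0, 4.0]), 5.0)
        assert signed_distance(h, [1.0, 1.0]) == pytest.approx(0.4)

    def test_point_on_plane(self):
        h = Hyperplane(np.array([0.0, 1.0]), 1.0)
        assert signed_distance(h, [5.0, 1.0]) == 0.0
        assert signed_distance(h, [0.0, 0.0]) == pytest.approx(-1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            signed_distance(Hyperplane(np.zeros(2), 1.0), [1.0, 1.0])

    def test_negative_margin_sign_convention(self):
        h = Hyperplane(np.array([0.0, 1.0]), 0.0)
        assert negative_margin(h, [[0.0, -2.0], [1.0, -3.0]]) == pytest.approx(2.0)
        assert negative_margin(h, [[0.0, 0.1], [0.0, -5.0]]) == pytest.approx(-0.1)
        assert negative_margin(h, [[0.0, 0.0]]) == 0.0
        with pytest.raises(ValueError):
            negative_margin(h, np.empty((0, 2)))

    def test_candidate_margin_is_worst_side(self):
        h = Hyperplane(np.array([0.0, 1.0]), 0.0)
        assert candidate_margin(h, [0, 0.3], [[0, -0.5]]) == pytest.approx(0.3)
        assert candidate_margin(h, [0, 0.5], [[0, 0.1]]) == pytest.approx(-0.1)

    def test_normalized_margin(self):
        n = 9
        assert normalized_margin(np.sqrt(n) / 2, n) == pytest.approx(1.0)
        assert normalized_margin(0.0, 5) == 0.0
        assert normalized_margin(0.5, 4) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            normalized_margin(1.0, 0)


class TestTrainSingleTarget:
    def test_one_dimensional_analytic_solution(self):
        target = Trajectory([1.0], [[1.0]])
        bg = Trajectory([1.0, 2.0], [[0.0], [0.2]])
        res = train_single_target(target, [bg])
        assert res.margin == pytest.approx(0.4, abs=1e-2)
        assert res.separating

    def test_candidate_equal_to_negative_is_non_separating(self):
        target = Trajectory([1.0], [[0.5, 0.5]])
        bg = Trajectory([1.0, 2.0], [[0.5, 0.5], [0.1, 0.1]])
        res = train_single_target(target, [bg])
        assert res.margin <= 0
        assert not res.separating

    def test_trace_matches_pruned_sweep(self, rng):
        target = Trajectory(np.arange(3.0), rng.random((3, 2)) + 0.8)
        bg = Trajectory(np.arange(8.0), rng.random((8, 2)) * 0.4)
        fast = train_single_target(target, [bg])
        full = train_single_target(target, [bg], record_trace=True)
        assert fast.margin == full.margin
        assert fast.best_index == full.best_index
        assert full.candidate_margins.size == 3
        assert full.margin == pytest.approx(np.max(full.candidate_margins))

    def test_validation(self):
        t = Trajectory([1.0], [[1.0]])
        with pytest.raises(ValueError):
            train_single_target(t, [])
        with pytest.raises(ValueError):
            train_single_target(t, [Trajectory([1.0], [[1.0, 2.0]])])


class TestSynapticWeights:
    def test_theta_equal_bias_is_identity(self):
        h = Hyperplane(np.array([1.0, 2.0]), 3.0)
        w = to_synaptic_weights(h, theta=3.0)
        assert np.allclose(w.w, h.W)

    def test_scalar_conversion(self):
        w = to_synaptic_weights(Hyperplane(np.array([2.0, 4.0]), 2.0), theta=1.0)
        assert np.allclose(w.w, [1.0, 2.0])

    def test_degenerate_bias(self):
        with pytest.raises(DegenerateBiasError):
            to_synaptic_weights(Hyperplane(np.array([1.0]), 0.0))
        with pytest.raises(DegenerateBiasError):
            to_synaptic_weights(Hyperplane(np.array([1.0]), -1.0))

    def test_json_round_trip(self):
        w = SynapticWeights(np.array([0.5, -0.5]), theta=1.0)
        again = SynapticWeights.from_json(json.loads(json.dumps(w.to_json())))
        assert np.allclose(again.w, w.w)


class TestSVMPSPClassifier:
    def test_fit_separates_and_classifies_training_set(self, task_1v5):
        est = SVMPSPClassifier().fit(task_1v5)
        assert est.separating_
        assert 0 < est.margin_normalized_ <= 1
        assert est.margin_normalized_ == pytest.approx(
            2 * est.margin_ / np.sqrt(10)
        )
        pred = est.predict(task_1v5)
        assert pred[0] == 1 and not pred[1:].any()
        t_fire = est.fire_times(task_1v5)
        assert t_fire[0] <= est.best_time_
        assert np.isnan(t_fire[1:]).all()

    def test_lif_weight_export_agrees_with_decision(self, task_1v5):
        est = SVMPSPClassifier().fit(task_1v5)
        times = sample_grid(0, 40, 0.1)
        for p in task_1v5:
            fired, _ = classify(p, est.weights_, est.spec_, times)
            assert fired == bool(est.predict([p])[0])

    def test_best_time_is_a_threshold_crossing(self, task_1v5):
        est = SVMPSPClassifier().fit(task_1v5)
        fired, t = classify(
            task_1v5[0], est.weights_, est.spec_, sample_grid(0, 40, 0.1)
        )
        assert fired and t <= est.best_time_ + 1e-9

    def test_kink_sampling_with_rc_kernel(self, task_1v5):
        est = SVMPSPClassifier(kernel="rc", tau=13.0, sampling="kink").fit(task_1v5)
        assert est.separating_
        assert est.predict(task_1v5)[0] == 1

    def test_requires_exactly_one_target(self, task_1v5):
        with pytest.raises(ValueError, match="exactly one target"):
            SVMPSPClassifier().fit(task_1v5, y=[1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="background"):
            SVMPSPClassifier().fit([task_1v5[0]])

    def test_sklearn_protocol(self, task_1v5):
        est = SVMPSPClassifier(tau=2.0)
        cloned = clone(est)
        assert cloned.get_params()["tau"] == 2.0
        cloned.set_params(tau=1.5).fit(task_1v5)
        assert cloned.score(task_1v5, [1, 0, 0, 0, 0, 0]) == 1.0

    def test_weight_file_round_trip(self, task_1v5, tmp_path):
        est = SVMPSPClassifier().fit(task_1v5)
        path = tmp_path / "weights.json"
        est.save_weights(path)
        record = json.loads(path.read_text())
        w = SynapticWeights.from_json(record)
        fired, _ = classify(task_1v5[0], w, est.spec_, sample_grid(0, 40, 0.1))
        assert fired
        assert record["n_neurons"] == 10

    def test_reproducibility(self, task_1v5):
        a = SVMPSPClassifier().fit(task_1v5)
        b = SVMPSPClassifier().fit(task_1v5)
        assert a.margin_ == b.margin_
        assert np.array_equal(a.hyperplane_.W, b.hyperplane_.W)


def test_training_consistency_over_seeds():
    """Separating fits fire on their target and stay silent on backgrounds."""
    for seed in range(10):
        pats = make_task(seed=seed)
        est = SVMPSPClassifier().fit(pats)
        if est.separating_:
            pred = est.predict(pats)
            assert pred[0] == 1 and not pred[1:].any()
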