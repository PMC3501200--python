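import numpy as np
import pytest

from svmpsp import KernelSpec, sample_grid
from svmpsp.embedding import embed
from svmpsp.patterns import SpikePattern
from svmpsp.separation import classify
from svmpsp.tempotron import (
    TempotronClassifier,
    TempotronConfig,
    VoltageMarginTempotronClassifier,
    _run_cycles,
    membrane_voltage,
    tempotron_train,
    tempotron_update,
    vm_tempotron_train,
)
from .conftest import make_task

GRID = sample_grid(0.0, 40.0, 0.1)


class TestVoltage:
    def test_zero_weights_rest_potential(self, de_kernel, rng):
        p = SpikePattern([[10.0], [12.0]])
        from svmpsp.separation import SynapticWeights

        w = SynapticWeights(np.zeros(2), theta=1.0, v_rest=-0.07)
        v = membrane_voltage(p, w, de_kernel, GRID)
        assert np.allclose(v, -0.07)

    def test_single_spike_is_kernel(self, de_kernel):
        p = SpikePattern([[10.0]])
        v = membrane_voltage(p, np.array([1.0]), de_kernel, GRID)
        assert np.allclose(v, de_kernel(GRID - 10.0), atol=1e-12)

    def test_matches_embedding_dot_product(self, de_kernel, rng):
        p = SpikePattern([np.sort(rng.uniform(5, 25, 2)) for _ in range(6)])
        w = rng.normal(size=6)
        traj = embed(p, de_kernel, GRID)
        assert np.allclose(
            membrane_voltage(p, w, de_kernel, GRID), traj.points @ w, atol=1e-12
        )


class TestUpdate:
    def test_zero_rate_is_identity(self, rng):
        w = rng.normal(size=4)
        assert np.array_equal(tempotron_update(w, rng.random(4), +1, 0.0), w)

    def test_exact_vector_step(self, rng):
        w = rng.normal(size=4)
        f = rng.random(4)
        assert np.array_equal(tempotron_update(w, f, -1, 0.1), w - 0.1 * f)

    def test_opposite_updates_cancel(self, rng):
        w = rng.normal(size=4)
        f = rng.random(4)
        w2 = tempotron_update(tempotron_update(w, f, +1, 0.1), f, -1, 0.1)
        assert np.allclose(w2, w, atol=1e-15)


class TestOriginalRule:
    def test_convergence_satisfies_stop_condition(self, de_kernel):
        pats = make_task(seed=3)
        res = tempotron_train(pats[:1], pats[1:], de_kernel, times=GRID)
        assert res.converged
        v_t = membrane_voltage(pats[0], res.weights, de_kernel, GRID).max()
        assert v_t >= 1.0
        for p in pats[1:]:
            assert membrane_voltage(p, res.weights, de_kernel, GRID).max() < 1.0

    def test_separating_weights_do_nothing(self, de_kernel):
        pats = make_task(seed=3)
        res = tempotron_train(pats[:1], pats[1:], de_kernel, times=GRID)
        tmats = [embed(pats[0], de_kernel, GRID).points]
        bmats = [embed(p, de_kernel, GRID).points for p in pats[1:]]
        w, converged, cycles, updates = _run_cycles(
            res.weights.w.copy(), tmats, bmats, 1.0, 1.0, 0.1, 0.0, 100
        )
        assert converged and cycles == 1 and updates == 0
        assert np.array_equal(w, res.weights.w)

    def test_two_neuron_toy_uses_only_positive_updates(self, de_kernel):
        target = SpikePattern([[10.0], []], label="target")
        background = SpikePattern([[], [10.0]], label="background")
        res = tempotron_train([target], [background], de_kernel, times=GRID)
        assert res.converged
        assert res.weights.w[0] > 0  # driven up to threshold
        assert res.weights.w[1] == 0  # background neuron never touched

    def test_hyperplane_count_is_updates_plus_initial(self, de_kernel):
        pats = make_task(seed=3)
        res = tempotron_train(pats[:1], pats[1:], de_kernel, times=GRID)
        assert res.n_hyperplanes >= res.n_cycles  # >=1 update per non-final cycle


class TestVoltageMarginRule:
    def test_margin_is_step_multiple_within_bounds(self, de_kernel):
        pats = make_task(seed=4)
        res = vm_tempotron_train(pats[:1], pats[1:], de_kernel, times=GRID)
        assert res.converged
        assert 0.0 <= res.margin <= 1.0
        assert res.margin / 0.01 == pytest.approx(round(res.margin / 0.01), abs=1e-9)

    def test_margin_conditions_hold_at_return(self, de_kernel):
        pats = make_task(seed=4)
        res = vm_tempotron_train(pats[:1], pats[1:], de_kernel, times=GRID)
        v_t = membrane_voltage(pats[0], res.weights, de_kernel, GRID).max()
        assert v_t >= 1.0 + res.margin
        for p in pats[1:]:
            v_b = membrane_voltage(p, res.weights, de_kernel, GRID).max()
            assert v_b < 1.0 - res.margin

    def test_non_separable_instance_reports_failure(self, de_kernel):
        p = SpikePattern([[10.0], [12.0]], label="target")
        cfg = TempotronConfig(max_cycles=50)
        res = vm_tempotron_train([p], [p.copy(label="background")], de_kernel, cfg, GRID)
        assert not res.converged
        assert res.margin == 0.0

    def test_beats_original_margin(self, de_kernel):
        """The widened margin dominates the stop-at-first-separation rule."""
        pats = make_task(seed=4)
        vm = vm_tempotron_train(pats[:1], pats[1:], de_kernel, times=GRID)
        assert vm.margin > 0
        assert vm.n_hyperplanes > 1


class TestEstimators:
    def test_tempotron_classifier(self):
        pats = make_task(seed=5)
        est = TempotronClassifier().fit(pats)
        assert est.converged_
        pred = est.predict(pats)
        assert pred[0] == 1 and not pred[1:].any()

    def test_classification_agrees_with_lif_readout(self):
        """Converged weights classify identically through the shared LIF rule."""
        pats = make_task(seed=5)
        est = TempotronClassifier().fit(pats)
        for p in pats:
            fired, _ = classify(p, est.weights_, est.spec_, est.times_)
            assert fired == bool(est.predict([p])[0])

    def test_vm_estimator_exposes_budget(self):
        pats = make_task(seed=5)
        est = VoltageMarginTempotronClassifier().fit(pats)
        assert est.converged_
        assert est.n_hyperplanes_ > 1
        assert est.margin_ >= 0
        pred = est.predict(pats)
        assert pred[0] == 1 and not pred[1:].any()


def test_config_validation():
    with pytest.raises(ValueError):
        TempotronConfig(lambda_=0.0)
    with pytest.raises(ValueError):
        TempotronConfig(margin_step=0.0)
    with pytest.raises(ValueError):
        TempotronConfig(patience=0)
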