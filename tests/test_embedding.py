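import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svmpsp import KernelSpec, membrane_voltage, rc_kernel
from svmpsp.embedding import (
    Rescaler,
    Trajectory,
    embed,
    fit_rescaler,
    kink_trajectory,
    sample_grid,
)
from svmpsp.patterns import SpikePattern, generate_constant_isi


@pytest.mark.parametrize(
    "start, end, dt, expected_n",
    [(0.0, 40.0, 0.1, 401), (0.0, 1.0, 1.0, 2), (0.0, 0.05, 0.1, 1)],
)
def test_sample_grid_counts(start, end, dt, expected_n):
    grid = sample_grid(start, end, dt)
    assert grid.size == expected_n
    assert grid[0] == start
    assert grid[-1] <= end + 1e-12


def test_sample_grid_validation():
    with pytest.raises(ValueError):
        sample_grid(0, 10, 0)
    with pytest.raises(ValueError):
        sample_grid(10, 0, 0.1)


class TestEmbed:
    def test_no_spikes_gives_zero_trajectory(self, de_kernel):
        p = SpikePattern([[], []])
        traj = embed(p, de_kernel, sample_grid(0, 10, 1.0))
        assert traj.points.shape == (11, 2)
        assert np.all(traj.points == 0)

    def test_single_spike_is_shifted_kernel(self, de_kernel):
        p = SpikePattern([[10.0]])
        t = sample_grid(0, 40, 0.1)
        traj = embed(p, de_kernel, t)
        assert np.allclose(traj.points[:, 0], de_kernel(t - 10.0))

    def test_two_spike_hand_sum(self):
        spec = KernelSpec("single_exp", tau=2.0)
        p = SpikePattern([[10.0, 12.0]])
        traj = embed(p, spec, np.array([12.0]))
        assert traj.points[0, 0] == pytest.approx(np.exp(-1.0) + 1.0, abs=1e-12)

    def test_linearity_in_spikes(self, de_kernel, rng):
        t = sample_grid(0, 30, 0.5)
        s1 = [np.sort(rng.uniform(1, 20, 3)), np.sort(rng.uniform(1, 20, 2))]
        s2 = [np.sort(rng.uniform(1, 20, 2)), np.sort(rng.uniform(1, 20, 3))]
        union = [np.concatenate([a, b]) for a, b in zip(s1, s2)]
        f = lambda s: embed(SpikePattern(s), de_kernel, t).points
        assert np.allclose(f(union), f(s1) + f(s2), atol=1e-12)

    def test_voltage_identity_with_lif(self, de_kernel, rng):
        """<w, f(t)> from the embedding equals the LIF voltage minus V_rest."""
        p = generate_constant_isi(10, 10, 20, rng)
        t = sample_grid(0, 40, 0.1)
        w = rng.normal(size=10)
        traj = embed(p, de_kernel, t)
        assert np.allclose(
            traj.points @ w, membrane_voltage(p, w, de_kernel, t), atol=1e-12
        )


class TestKinkTrajectory:
    def test_sample_count_bound(self, rng):
        spec = rc_kernel(13.0)
        p = generate_constant_isi(10, 10, 20, rng)
        traj = kink_trajectory(p, spec)
        assert len(traj) <= 2 * p.n_spikes + 1  # + t=0 start sample

    def test_empty_pattern(self):
        traj = kink_trajectory(SpikePattern([[], []]), rc_kernel(13.0))
        assert len(traj) == 1  # only the t=0 start point
        assert np.all(traj.points == 0)

    @pytest.mark.parametrize("family", ["rc", "single_exp", "triangular", "square"])
    def test_linear_functional_max_attained_at_kinks(self, family, rng):
        """Piecewise-linear kernels: a dense grid never beats the kink set."""
        spec = (
            rc_kernel(13.0) if family == "rc" else KernelSpec(family, tau=5.0)
        )
        for seed in range(5):
            r = np.random.default_rng(seed)
            p = generate_constant_isi(6, 10, 20, r)
            w = r.random(6)
            kink = kink_trajectory(p, spec)
            dense = embed(p, spec, sample_grid(0.0, 40.0, 0.002))
            m_kink = (kink.points @ w).max()
            m_dense = (dense.points @ w).max()
            assert m_kink >= m_dense - 1e-9
            assert m_dense == pytest.approx(m_kink, rel=1e-3)

    def test_curved_kernel_rejected(self, de_kernel):
        with pytest.raises(ValueError, match="curved"):
            kink_trajectory(SpikePattern([[1.0]]), de_kernel)


class TestRescaler:
    def test_reference_maps_to_unit_range(self, rng):
        X = rng.random((50, 4)) * np.array([1, 5, 0.1, 2.0]) + 3
        r = Rescaler().fit(X)
        Y = r.transform(X)
        assert np.allclose(Y.min(axis=0), 0.0)
        assert np.allclose(Y.max(axis=0), 1.0)

    def test_constant_dimension_maps_to_zero(self):
        r = fit_rescaler(np.array([[0.0, 5.0], [2.0, 5.0]]))
        Y = r.transform(np.array([[0.0, 5.0], [2.0, 5.0]]))
        assert np.allclose(Y, [[0.0, 0.0], [1.0, 0.0]])

    def test_held_out_point_can_leave_unit_box(self):
        r = fit_rescaler(np.array([[1.0], [3.0]]))
        assert r.transform(np.array([[0.0]]))[0, 0] < 0
        assert r.transform(np.array([[4.0]]))[0, 0] > 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            fit_rescaler(np.empty((0, 3)))

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, c):
        """Global feature rescaling by c > 0 is absorbed by the rescaler."""
        X = np.random.default_rng(4).random((20, 3))
        a = fit_rescaler(X).transform(X)
        b = fit_rescaler(c * X).transform(c * X)
        assert np.allclose(a, b, atol=1e-9)


def test_trajectory_validation():
    with pytest.raises(ValueError):
        Trajectory(np.array([1.0, 1.0]), np.zeros((2, 3)))  # not increasing
    with pytest.raises(ValueError):
        Trajectory(np.array([1.0]), np.zeros((2, 3)))  # length mismatch


def test_trajectory_frame_export(de_kernel):
    traj = embed(SpikePattern([[5.0], [7.0]]), de_kernel, sample_grid(0, 10, 1))
    df = traj.to_frame()
    assert list(df.columns) == ["time_ms", "f0", "f1"]
    assert len(df) == 11
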